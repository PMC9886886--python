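"""Tests of co-expression edge construction, PPI intersection, gene
categorization and Venn region counting, including a full brute-force
re-implementation of the all-pairs filter."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from immunet.data_io import ExpressionMatrix, canonical_edge
from immunet.network import (
    build_coexpression_edges,
    categorize,
    intersect_with_ppi,
    log2_transform,
    venn_counts,
)
from immunet.stats import ConstantInputError, bh_adjust, pearson_with_p
from immunet.synthetic import SyntheticConfig, generate_dataset


class TestLog2:
    def _em(self, rows):
        df = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                          columns=["a", "b", "c"][: len(rows[0])])
        return ExpressionMatrix(df)

    def test_examples(self):
        em = self._em([[1.0, 8.0, 7.0]])
        out = log2_transform(em)
        assert out.values.iloc[0, 0] == 0.0 and out.values.iloc[0, 1] == 3.0
        out1 = log2_transform(em, pseudocount=1.0)
        assert out1.values.iloc[0, 2] == pytest.approx(3.0)

    def test_monotone(self, rng):
        em = self._em([list(rng.uniform(0.5, 100, 3)), list(rng.uniform(0.5, 100, 3))])
        out = log2_transform(em)
        a, b = em.values.to_numpy().ravel(), out.values.to_numpy().ravel()
        assert np.array_equal(np.argsort(a), np.argsort(b))

    def test_nonpositive_rejected_without_pseudocount(self):
        with pytest.raises(ValueError):
            log2_transform(self._em([[0.0, 1.0, 2.0]]))


def brute_force_edges(em, r_min=0.7, q_max=0.05):
    """Independent O(n²) reimplementation of the co-expression filter."""
    genes = [g for g in em.gene_ids if em.values.loc[g].std() > 0]
    pairs, ps, rs = [], [], []
    for a, b in itertools.combinations(genes, 2):
        r, p = pearson_with_p(em.values.loc[a], em.values.loc[b])
        pairs.append(canonical_edge(a, b))
        rs.append(r)
        ps.append(p)
    qs = bh_adjust(ps)
    return {
        pair: (r, q)
        for pair, r, q in zip(pairs, rs, qs)
        if abs(r) > r_min and q < q_max
    }


def test_matches_brute_force_oracle():
    cfg = SyntheticConfig(n_genes=30, n_modules=3, module_size=6, loading=2.0, seed=21)
    em, _, _, _ = generate_dataset(cfg)
    df = build_coexpression_edges(em)
    got = {(r.gene_a, r.gene_b): (r.r, r.q) for r in df.itertuples()}
    expected = brute_force_edges(em)
    assert set(got) == set(expected)
    for pair in expected:
        assert got[pair][0] == pytest.approx(expected[pair][0], abs=1e-10)
        assert got[pair][1] == pytest.approx(expected[pair][1], abs=1e-10)


def test_noise_free_limit_keeps_all_within_module_pairs():
    """As σ→0 every within-module pair approaches r=1 and must be retained.

    Pairs involving out-of-module genes are pure noise; their sample r is
    scale-invariant, so a rare chance correlation can still pass the filter
    — retained edges are a superset of the planted pairs with few extras.
    """
    cfg = SyntheticConfig(
        n_genes=30, n_modules=3, module_size=6, loading=1.0, noise_sd=1e-7, seed=3
    )
    em, _, _, truth = generate_dataset(cfg)
    df = build_coexpression_edges(em)
    got = {(r.gene_a, r.gene_b) for r in df.itertuples()}
    expected = {
        canonical_edge(a, b)
        for m in range(3)
        for a, b in itertools.combinations(sorted(truth.module_genes(m)), 2)
    }
    assert got >= expected
    assert len(got - expected) <= 3  # chance noise correlations only


def test_strict_r_threshold_of_one_yields_no_edges():
    em, _, _, _ = generate_dataset(SyntheticConfig(seed=4))
    assert build_coexpression_edges(em, r_min=1.0).empty


def test_threshold_monotonicity():
    em, _, _, _ = generate_dataset(SyntheticConfig(n_genes=30, n_modules=3,
                                                   module_size=6, seed=8))
    base = build_coexpression_edges(em, r_min=0.5, q_max=0.1)
    tighter_r = build_coexpression_edges(em, r_min=0.7, q_max=0.1)
    tighter_q = build_coexpression_edges(em, r_min=0.5, q_max=0.01)
    base_set = {(r.gene_a, r.gene_b) for r in base.itertuples()}
    for df in (tighter_r, tighter_q):
        assert {(r.gene_a, r.gene_b) for r in df.itertuples()} <= base_set


def test_constant_genes_excluded_not_fatal():
    df = pd.DataFrame(
        {"s1": [1.0, 5.0, 2.0], "s2": [1.0, 6.0, 4.0], "s3": [1.0, 7.0, 6.0],
         "s4": [1.0, 8.0, 8.0]},
        index=["const", "a", "b"],
    )
    em = ExpressionMatrix(df)
    out = build_coexpression_edges(em, r_min=0.5, q_max=0.9)
    assert "const" not in set(out.gene_a) | set(out.gene_b)
    assert ("a", "b") in {(r.gene_a, r.gene_b) for r in out.itertuples()}


def test_too_few_samples_rejected():
    df = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 1.0]}, index=["a", "b"])
    with pytest.raises(ValueError, match="3 samples"):
        build_coexpression_edges(ExpressionMatrix(df))


class TestIntersection:
    def _coexpr(self, pairs):
        return pd.DataFrame(
            [(a, b, 0.9, 1e-6, 1e-4) for a, b in pairs],
            columns=["gene_a", "gene_b", "r", "p", "q"],
        )

    def test_set_intersection_semantics(self):
        net = intersect_with_ppi(self._coexpr([("A", "B"), ("B", "C")]),
                                 [("B", "C"), ("C", "D")])
        assert set(net.nodes) == {"B", "C"}
        assert net.number_of_edges() == 1
        assert net.edges["B", "C"]["r"] == pytest.approx(0.9)

    def test_identity_on_equal_edge_sets(self):
        pairs = [("A", "B"), ("C", "D")]
        net = intersect_with_ppi(self._coexpr(pairs), pairs)
        assert net.number_of_edges() == 2

    def test_orientation_invariance(self):
        net = intersect_with_ppi(self._coexpr([("A", "B")]), [("B", "A")])
        assert net.number_of_edges() == 1

    def test_planted_full_ppi_preserves_coexpression_edges(self):
        cfg = SyntheticConfig(n_genes=20, n_modules=2, module_size=6,
                              loading=3.0, ppi_within_prob=1.0,
                              ppi_background_prob=0.0, seed=6)
        em, ppi, _, truth = generate_dataset(cfg)
        coexpr = build_coexpression_edges(em)
        within = {
            (r.gene_a, r.gene_b) for r in coexpr.itertuples()
            if truth.module_membership[r.gene_a] == truth.module_membership[r.gene_b]
        }
        net = intersect_with_ppi(coexpr, ppi)
        assert set(map(canonical_edge, *zip(*net.edges))) >= within


class TestCategorize:
    def test_four_way_partition(self):
        cats, counts = categorize(
            ["A", "B", "C", "D"], pd_genes={"A", "B"}, immune_genes={"B", "C"}
        )
        assert cats == {"A": "PD", "B": "immune-PD", "C": "immune", "D": "other"}
        assert sum(counts.values()) == 4

    def test_empty_lists_give_all_other(self):
        cats, counts = categorize(["A", "B"], set(), set())
        assert set(cats.values()) == {"other"} and counts["other"] == 2


class TestVenn:
    def test_two_set_regions(self):
        out = venn_counts({"X": {"A", "B"}, "Y": {"B", "C"}})
        assert out[frozenset({"X"})] == 1
        assert out[frozenset({"Y"})] == 1
        assert out[frozenset({"X", "Y"})] == 1

    def test_disjoint_sets_have_zero_triple_overlap(self):
        out = venn_counts({"X": {1}, "Y": {2}, "Z": {3}})
        assert out[frozenset({"X", "Y", "Z"})] == 0

    def test_matches_direct_membership_oracle(self, rng):
        sets = {n: set(rng.integers(0, 30, size=15).tolist()) for n in "XYZ"}
        out = venn_counts(sets)
        union = set().union(*sets.values())
        assert sum(out.values()) == len(union)
        for e in union:
            inside = frozenset(n for n in sets if e in sets[n])
            direct = sum(
                1 for u in union if frozenset(n for n in sets if u in sets[n]) == inside
            )
            assert out[inside] == direct

    def test_more_than_three_sets_unsupported(self):
        with pytest.raises(ValueError):
            venn_counts({str(i): {i} for i in range(4)})
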