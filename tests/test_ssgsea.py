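"""Tests of the single-sample enrichment score against an independently
coded running-sum oracle, rank-invariance properties, and the differential
infiltration pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest

from immunet.data_io import ExpressionMatrix
from immunet.ssgsea import differential_scores, gene_score_correlation, ssgsea, ssgsea_sample
from immunet.synthetic import SyntheticConfig, generate_signature_dataset


def oracle_score(values, gene_ids, members, alpha):
    """Literal re-derivation of the running sum, written independently:
    explicit python loops over the descending walk."""
    n = len(gene_ids)
    # bottom-up mid-ranks
    order_asc = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order_asc[j + 1]] == values[order_asc[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order_asc[t]] = mid
        i = j + 1
    walk = sorted(range(n), key=lambda i: (-values[i], gene_ids[i]))
    denom_in = sum(ranks[i] ** alpha for i in walk if gene_ids[i] in members)
    n_out = sum(1 for i in walk if gene_ids[i] not in members)
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for i in walk:
        if gene_ids[i] in members:
            cum_in += ranks[i] ** alpha
        else:
            cum_out += 1
        es += cum_in / denom_in - cum_out / n_out
    return es


FIVE_GENES = ["A", "B", "C", "D", "E"]
FIVE_VALUES = np.array([5.0, 4.0, 3.0, 2.0, 1.0])


def test_top_gene_singleton_set_walked_by_hand():
    # P_in jumps to 1 at the first step; P_out climbs 0, .25, .5, .75, 1:
    # ES = 1 + .75 + .5 + .25 + 0 = 2.5, independent of alpha
    for alpha in (0.0, 0.25, 1.0):
        es = ssgsea_sample(FIVE_VALUES, FIVE_GENES, {"A"}, alpha=alpha)
        assert es == pytest.approx(2.5)


def test_matches_independent_oracle_on_small_instances(rng):
    for trial in range(30):
        n = int(rng.integers(4, 12))
        values = np.round(rng.normal(0, 1, n), 1)  # rounding forces ties
        gene_ids = [f"g{i}" for i in range(n)]
        size = int(rng.integers(1, n - 1))
        members = set(rng.choice(gene_ids, size=size, replace=False))
        for alpha in (0.0, 0.25, 1.0):
            mine = ssgsea_sample(values, gene_ids, members, alpha)
            ref = oracle_score(values, gene_ids, members, alpha)
            assert mine == pytest.approx(ref, abs=1e-10)


def test_matrix_path_matches_per_sample_path(rng):
    df = pd.DataFrame(
        rng.normal(7, 1, (8, 5)),
        index=[f"g{i}" for i in range(8)],
        columns=[f"s{i}" for i in range(5)],
    )
    em = ExpressionMatrix(df)
    sets = {"S1": {"g0", "g3"}, "S2": {"g2", "g5", "g7"}}
    scores = ssgsea(em, sets)
    for s in df.columns:
        for name, members in sets.items():
            ref = ssgsea_sample(df[s].to_numpy(), list(df.index), members)
            assert scores.loc[s, name] == pytest.approx(ref, abs=1e-10)


def test_invariant_under_strictly_increasing_transforms(rng):
    df = pd.DataFrame(
        rng.normal(7, 1, (20, 4)),
        index=[f"g{i}" for i in range(20)],
        columns=list("wxyz"),
    )
    sets = {"S": {f"g{i}" for i in range(0, 20, 3)}}
    base = ssgsea(ExpressionMatrix(df), sets)
    doubled = ssgsea(ExpressionMatrix(2.0 * df), sets)
    curved = ssgsea(ExpressionMatrix(np.exp(df / 10.0)), sets)
    assert np.allclose(base.to_numpy(), doubled.to_numpy())
    assert np.allclose(base.to_numpy(), curved.to_numpy())


def test_top_placement_maximizes_score_over_all_permutations():
    gene_ids = [f"g{i}" for i in range(6)]
    members = {"g0", "g1"}
    scores = {}
    for perm in itertools.permutations([6.0, 5.0, 4.0, 3.0, 2.0, 1.0]):
        es = ssgsea_sample(np.array(perm), gene_ids, members, alpha=0.25)
        top_two = {g for g, v in zip(gene_ids, perm) if v >= 5.0}
        scores.setdefault(top_two == members, []).append(es)
    assert max(scores[True]) == pytest.approx(max(max(scores[True]), max(scores[False])))
    assert min(scores[True]) > max(scores[False])


def test_alpha_zero_reduces_to_unweighted_cdf_difference(rng):
    values = rng.normal(0, 1, 15)
    gene_ids = [f"g{i}" for i in range(15)]
    members = {"g1", "g5", "g9"}
    # Kolmogorov-style unweighted running sum
    walk = sorted(range(15), key=lambda i: (-values[i], gene_ids[i]))
    hits = np.cumsum([gene_ids[i] in members for i in walk]) / 3
    misses = np.cumsum([gene_ids[i] not in members for i in walk]) / 12
    assert ssgsea_sample(values, gene_ids, members, alpha=0.0) == pytest.approx(
        float(np.sum(hits - misses))
    )


def test_degenerate_sets_rejected():
    df = pd.DataFrame(np.eye(3) + 1.0, index=list("abc"), columns=list("xyz"))
    em = ExpressionMatrix(df)
    with pytest.raises(ValueError, match="no genes"):
        ssgsea(em, {"S": {"zz"}})
    with pytest.raises(ValueError, match="all genes"):
        ssgsea(em, {"S": {"a", "b", "c"}})


def test_normalization_preserves_ordering(rng):
    df = pd.DataFrame(rng.normal(7, 1, (30, 6)),
                      index=[f"g{i}" for i in range(30)],
                      columns=[f"s{i}" for i in range(6)])
    em = ExpressionMatrix(df)
    sets = {"A": {"g0", "g1", "g2"}, "B": {"g9", "g10"}}
    raw = ssgsea(em, sets, normalize=False).to_numpy()
    norm = ssgsea(em, sets, normalize=True).to_numpy()
    assert np.array_equal(np.argsort(raw, axis=None), np.argsort(norm, axis=None))


class TestDifferential:
    def test_identical_group_scores_give_p_one(self):
        scores = pd.DataFrame(
            {"S": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
            index=[f"s{i}" for i in range(6)],
        )
        groups = {f"s{i}": ("control" if i < 3 else "disease") for i in range(6)}
        diff = differential_scores(scores, groups)
        assert diff.loc["S", "p"] == 1.0

    def test_planted_shift_flagged_direction_up(self):
        cfg = SyntheticConfig(n_genes=400, n_modules=0, module_size=0,
                              n_control=12, n_disease=12, disease_shift=2.0, seed=8)
        em, sets, truth = generate_signature_dataset(cfg, 8, 20, 2)
        diff = differential_scores(ssgsea(em, sets), em.groups)
        for name in truth.shifted_sets:
            assert diff.loc[name, "q"] < 0.05
            assert diff.loc[name, "direction"] == 1.0

    def test_matches_exact_enumeration_at_small_n(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame({"S": rng.permutation(12).astype(float)},
                              index=[f"s{i}" for i in range(12)])
        groups = {f"s{i}": ("control" if i < 6 else "disease") for i in range(12)}
        diff = differential_scores(scores, groups)
        from immunet.stats import wilcoxon_rank_sum
        ref = wilcoxon_rank_sum(scores.iloc[6:, 0], scores.iloc[:6, 0], mode="exact")
        assert diff.loc["S", "p"] == pytest.approx(ref.p_value)

    def test_empty_group_rejected(self):
        scores = pd.DataFrame({"S": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            differential_scores(scores, {"a": "control", "b": "control"})


class TestGeneScoreCorrelation:
    def test_shape_and_in_set_gene_positive(self):
        cfg = SyntheticConfig(n_genes=300, n_modules=0, module_size=0,
                              n_control=15, n_disease=15, disease_shift=2.0, seed=4)
        em, sets, truth = generate_signature_dataset(cfg, 6, 15, 2)
        scores = ssgsea(em, sets)
        shifted = sorted(truth.shifted_sets)[0]
        member = sorted(sets[shifted])[0]
        sub = em.subset_genes([member])
        r, p, tier = gene_score_correlation(sub, scores[[shifted]])
        assert r.shape == (1, 1) and tier.shape == (1, 1)
        assert r.iloc[0, 0] > 0

    def test_constant_gene_yields_missing_not_error(self):
        df = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [0.2, 0.9, 0.1, 0.5]],
            index=["const", "var"], columns=list("abcd"),
        )
        scores = pd.DataFrame({"S": [0.3, 0.1, 0.8, 0.2]}, index=list("abcd"))
        r, p, tier = gene_score_correlation(ExpressionMatrix(df), scores)
        assert np.isnan(r.loc["const", "S"])
        assert tier.loc["const", "S"] == "na"
        assert np.isfinite(r.loc["var", "S"])
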