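"""Recovery and calibration studies on synthetic ground truth.

Each study fixes a generative condition (documented on the constant that
holds it), runs the relevant pipeline stage across seeds, and returns the
summary quantity: Jaccard recovery of planted modules by the thresholded
co-expression ∩ PPI network, Jaccard recovery of the top-5 core-gene
modules, adjusted Rand index of consensus classification against the true
groups (and its null), flag/false-positive rates of differential
infiltration, and worst-case errors of the analytic test approximations
against exhaustive oracles.  The analysis drivers, the test suite and the
acceptance script all call these functions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import replace
from typing import Sequence

import networkx as nx
import numpy as np

from .consensus import assign_and_validate, consensus_cluster, consensus_cdf_delta
from .modules import mcl_cluster, score_modules, select_top
from .network import build_coexpression_edges, intersect_with_ppi
from .stats import hypergeom_tail, wilcoxon_rank_sum
from .synthetic import SyntheticConfig, generate_dataset, generate_signature_dataset
from .ssgsea import differential_scores, ssgsea

__all__ = [
    "jaccard",
    "mean_best_jaccard",
    "NETWORK_STUDY",
    "MODULE_STUDY",
    "MODULE_STUDY_PLAN",
    "CLASSIFICATION_STUDY",
    "INFILTRATION_STUDY",
    "network_recovery_study",
    "module_selection_study",
    "consensus_separation_study",
    "classification_validation_study",
    "infiltration_power_study",
    "infiltration_null_study",
    "wilcoxon_approximation_error",
    "hypergeom_bruteforce_error",
]

#: Network-recovery condition: population within-module correlation
#: β²/(β²+σ²) = 0.9 (β=3, σ=1) and the 8-control / 14-disease cohort size of
#: the motivating study; PPI edges cover modules densely (0.8) over a thin
#: background (0.02).
NETWORK_STUDY = SyntheticConfig(
    n_genes=60, n_modules=5, module_size=10, n_control=8, n_disease=14,
    loading=3.0, noise_sd=1.0, ppi_within_prob=0.8, ppi_background_prob=0.02,
)

#: Module-selection condition: eight modules, of which five are core-rich
#: (70% PD genes) and three carry no core genes, so top-5 selection has an
#: unambiguous planted answer.
MODULE_STUDY_PLAN = {m: {"PD": 0.7} for m in range(5)} | {m: {} for m in range(5, 8)}
MODULE_STUDY = replace(
    NETWORK_STUDY, n_genes=90, n_modules=8, category_plan=MODULE_STUDY_PLAN
)

#: Classification-power condition: ten modules of ten genes with moderate
#: co-expression (β=1, within-module r = 0.5), a δ=2 disease shift on half
#:  the modules, and balanced 15/15 cohorts.  The inner clusterer is
#: Euclidean k-means: the planted group effect is a mean shift, which
#: correlation distance partially cancels (see docs/methods.md).
CLASSIFICATION_STUDY = SyntheticConfig(
    n_genes=110, n_modules=10, module_size=10, n_control=15, n_disease=15,
    loading=1.0, noise_sd=1.0, disease_shift=2.0,
)

#: Infiltration condition: 24 disjoint 20-gene signature sets in a
#: 2000-gene universe, 4 sets shifted by 2σ in the 15 disease samples.
INFILTRATION_STUDY = SyntheticConfig(
    n_genes=2000, n_modules=0, module_size=0, n_control=15, n_disease=15,
    disease_shift=2.0,
)
INFILTRATION_SETS = dict(n_sets=24, set_size=20, n_shifted_sets=4)


def jaccard(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b| (1.0 for two empty sets)."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def mean_best_jaccard(planted: Sequence[set], recovered: Sequence[set]) -> float:
    """Mean over planted sets of the best Jaccard against any recovered set."""
    if not planted:
        raise ValueError("no planted sets")
    if not recovered:
        return 0.0
    return float(np.mean([max(jaccard(p, r) for r in recovered) for p in planted]))


def _seeds(base_seed: int, n: int, stream: int) -> list[int]:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(stream,))
    return [int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64)]


def network_recovery_study(base_seed: int, n_seeds: int = 20) -> dict:
    """Planted-module recovery by the |r|>0.7 & FDR<0.05 ∩ PPI pipeline.

    Recovered modules are the connected components of the common network;
    returns the per-seed mean Jaccard against the planted modules and its
    average over seeds.
    """
    per_seed = []
    for seed in _seeds(base_seed, n_seeds, stream=1):
        cfg = replace(NETWORK_STUDY, seed=seed)
        em, ppi, _, truth = generate_dataset(cfg)
        net = intersect_with_ppi(build_coexpression_edges(em), ppi)
        components = [set(c) for c in nx.connected_components(net)]
        planted = [truth.module_genes(m) for m in range(cfg.n_modules)]
        per_seed.append(mean_best_jaccard(planted, components))
    return {"mean_jaccard": float(np.mean(per_seed)), "per_seed": per_seed}


def module_selection_study(base_seed: int, n_seeds: int = 20) -> dict:
    """Recovery of the five planted core-rich modules by MCL + top-5 scoring."""
    per_seed = []
    for seed in _seeds(base_seed, n_seeds, stream=2):
        cfg = replace(MODULE_STUDY, seed=seed)
        em, ppi, categories, truth = generate_dataset(cfg)
        net = intersect_with_ppi(build_coexpression_edges(em), ppi)
        clusters = mcl_cluster(net) if net.number_of_nodes() else []
        mods = score_modules(clusters, categories, net, min_core=6)
        top, _ = select_top(mods, k=5)
        planted = [truth.module_genes(m) for m in range(5)]
        per_seed.append(mean_best_jaccard(planted, [set(m.members) for m in top]))
    return {"mean_jaccard": float(np.mean(per_seed)), "per_seed": per_seed}


def consensus_separation_study(seed: int, n_resamples: int = 100) -> dict:
    """Consensus structure on two well-separated planted sample groups.

    Separation is ≥ 10σ, so every inner run splits the samples identically:
    at K=2 the consensus matrix must be exactly binary (1 within the true
    groups, 0 between), and the delta-area curve must peak at K=2.
    """
    cfg = replace(CLASSIFICATION_STUDY, disease_shift=20.0, seed=seed, loading=0.5)
    em, _, _, _ = generate_dataset(cfg)
    genes = em.gene_ids[: cfg.n_modules * cfg.module_size]
    res = consensus_cluster(
        em.subset_genes(genes), [2, 3, 4, 5], n_resamples=n_resamples, seed=seed
    )
    consensus_cdf_delta(res)
    m = res.matrices[2]
    truth = np.array([em.groups[s] == "disease" for s in res.sample_ids])
    same = truth[:, None] == truth[None, :]
    deviation = float(np.max(np.abs(m - same.astype(float))))
    peak_k = max(res.delta_areas, key=res.delta_areas.get)
    return {"binary_deviation": deviation, "delta_area_argmax": int(peak_k), "result": res}


def classification_validation_study(
    base_seed: int, n_seeds: int = 20, delta: float = 2.0, n_resamples: int = 100
) -> dict:
    """Cross-cohort consensus classification against the true groups.

    Independent train/test cohorts from the same condition (δ on half the
    modules); reports the mean test-cohort adjusted Rand index.  δ=0 gives
    the null behaviour (ARI fluctuating around zero).
    """
    seeds = _seeds(base_seed, 2 * n_seeds, stream=3)
    aris = []
    genes = [f"G{i + 1:06d}" for i in range(100)]
    for i in range(n_seeds):
        cfg = replace(CLASSIFICATION_STUDY, disease_shift=delta)
        train, _, _, _ = generate_dataset(replace(cfg, seed=seeds[2 * i]))
        test, _, _, _ = generate_dataset(replace(cfg, seed=seeds[2 * i + 1]))
        val = assign_and_validate(
            train, test, genes, k=2, n_resamples=n_resamples,
            seed=seeds[2 * i], inner="kmeans",
        )
        aris.append(val["cohorts"]["test"]["ari"])
    return {"mean_ari": float(np.mean(aris)), "per_seed": aris}


def infiltration_power_study(base_seed: int, n_seeds: int = 50) -> dict:
    """Detection of planted infiltration shifts by ssGSEA + rank-sum + BH.

    Returns the fraction of (seed, shifted set) pairs flagged at q<0.05,
    the per-seed all-four-flagged rate, and the raw p<0.05 rate on the
    unshifted sets of the same runs.
    """
    flag_hits = 0
    all_flagged = 0
    stray = 0
    n_null = 0
    for seed in _seeds(base_seed, n_seeds, stream=4):
        cfg = replace(INFILTRATION_STUDY, seed=seed)
        em, sets, truth = generate_signature_dataset(cfg, **INFILTRATION_SETS)
        diff = differential_scores(ssgsea(em, sets), em.groups)
        flagged = set(diff.index[diff["q"] < 0.05])
        flag_hits += len(flagged & truth.shifted_sets)
        all_flagged += flagged >= truth.shifted_sets
        null_sets = [s for s in diff.index if s not in truth.shifted_sets]
        stray += int((diff.loc[null_sets, "p"] < 0.05).sum())
        n_null += len(null_sets)
    n_shifted = INFILTRATION_SETS["n_shifted_sets"]
    return {
        "flag_rate": flag_hits / (n_seeds * n_shifted),
        "all_flagged_rate": all_flagged / n_seeds,
        "shifted_config_null_p_rate": stray / n_null,
    }


def infiltration_null_study(base_seed: int, n_seeds: int = 25) -> dict:
    """False-positive calibration with no planted shifts (δ=0)."""
    fp = 0
    total = 0
    for seed in _seeds(base_seed, n_seeds, stream=5):
        cfg = replace(INFILTRATION_STUDY, disease_shift=0.0, seed=seed)
        em, sets, _ = generate_signature_dataset(
            cfg, INFILTRATION_SETS["n_sets"], INFILTRATION_SETS["set_size"], 0
        )
        diff = differential_scores(ssgsea(em, sets), em.groups)
        fp += int((diff["p"] < 0.05).sum())
        total += len(diff)
    return {"fpr": fp / total, "n_tests": total}


def wilcoxon_approximation_error(max_total: int = 12) -> dict:
    """Worst |normal-approximation p − exact p| over all tie-free rank splits.

    Enumerates every subset split of ranks 1..n for all n1+n2 ≤ max_total
    (n1, n2 ≥ 1) and compares the two-sided p-values of the two modes.
    """
    worst = 0.0
    worst_case = None
    n_cases = 0
    for n in range(2, max_total + 1):
        ranks = list(range(1, n + 1))
        for n1 in range(1, n):
            for subset in itertools.combinations(ranks, n1):
                x = np.array(subset, dtype=float)
                y = np.array(sorted(set(ranks) - set(subset)), dtype=float)
                p_exact = wilcoxon_rank_sum(x, y, mode="exact").p_value
                p_approx = wilcoxon_rank_sum(x, y, mode="normal_approx").p_value
                err = abs(p_exact - p_approx)
                n_cases += 1
                if err > worst:
                    worst, worst_case = err, (n1, n - n1, int(sum(subset)))
    return {"max_abs_error": worst, "worst_case": worst_case, "n_cases": n_cases}


def hypergeom_bruteforce_error(max_n: int = 30) -> dict:
    """Worst |log-space tail − direct mass summation| over all N ≤ max_n."""

    def pmf(i: int, K: int, n: int, N: int) -> float:
        return (
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
            if 0 <= n - i <= N - K
            else 0.0
        )

    worst = 0.0
    n_cases = 0
    for N in range(1, max_n + 1):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    direct = sum(pmf(i, K, n, N) for i in range(k, min(K, n) + 1))
                    err = abs(hypergeom_tail(k, K, n, N) - min(1.0, direct))
                    n_cases += 1
                    worst = max(worst, err)
    return {"max_abs_error": worst, "n_cases": n_cases}
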