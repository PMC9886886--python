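"""Monti-style consensus clustering of samples with CDF/delta-area K choice.

For each candidate K, samples are repeatedly subsampled (80% by default)
and clustered; the consensus matrix records, for each sample pair, the
fraction of co-sampled runs in which the pair co-clustered.  A clean
cluster structure yields a near-binary consensus matrix; the area under
the CDF of consensus entries, and its relative increase with K
(delta-area), guide the choice of K.  An external cohort is validated by
rerunning the identical procedure and scoring agreement with the known
groups via the adjusted Rand index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .data_io import ExpressionMatrix
from .stats import empirical_cdf

log = logging.getLogger(__name__)

__all__ = [
    "ConsensusResult",
    "consensus_cluster",
    "consensus_cdf_delta",
    "assign_and_validate",
]


@dataclass
class ConsensusResult:
    """Per-K consensus matrices, assignments and CDF/delta-area summaries."""

    sample_ids: list[str]
    matrices: dict[int, np.ndarray]
    assignments: dict[int, np.ndarray]
    areas: dict[int, float] = field(default_factory=dict)
    delta_areas: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None

    def __post_init__(self) -> None:
        for k, m in self.matrices.items():
            if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 1.0):
                raise ValueError(f"consensus matrix for K={k} not symmetric/unit-diagonal")
            if m.min() < -1e-12 or m.max() > 1 + 1e-12:
                raise ValueError(f"consensus entries for K={k} outside [0,1]")


def _pearson_distance(x: np.ndarray) -> np.ndarray:
    """1 − Pearson correlation between columns (samples)."""
    d = 1.0 - np.corrcoef(x.T)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _inner_cluster(x: np.ndarray, k: int, inner: str, rng: np.random.Generator) -> np.ndarray:
    """Cluster the columns of x into k groups; returns integer labels."""
    if inner == "hierarchical_average_pearson":
        d = _pearson_distance(x)
        z = linkage(squareform(d, checks=False), method="average")
        return fcluster(z, t=k, criterion="maxclust")
    if inner == "kmeans":
        km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31)))
        return km.fit_predict(x.T)
    raise ValueError(f"unknown inner method {inner!r}")


def consensus_cluster(
    expr_sub: ExpressionMatrix | pd.DataFrame,
    k_range: Sequence[int] = (2, 3, 4, 5, 6),
    n_resamples: int = 1000,
    item_frac: float = 0.8,
    seed: int | None = None,
    inner: str = "hierarchical_average_pearson",
) -> ConsensusResult:
    """Consensus clustering of samples on a module-gene expression matrix.

    For each K: draw ``n_resamples`` subsamples of ⌈item_frac·n⌉ samples
    without replacement, cluster each with the inner method, and set
    consensus(i,j) = co-cluster count / co-sample count (0, with a warning,
    for pairs never co-sampled).  The final per-K assignment hierarchically
    clusters 1 − consensus into K groups.
    """
    values = expr_sub.values if isinstance(expr_sub, ExpressionMatrix) else expr_sub
    samples = list(values.columns)
    x = values.to_numpy(dtype=float)
    if x.shape[0] == 0:
        raise ValueError("module gene set is empty")
    k_range = sorted(set(int(k) for k in k_range))
    if min(k_range) < 2:
        raise ValueError("k_range minimum must be >= 2")
    n = len(samples)
    if n < max(k_range) + 1:
        raise ValueError(f"need at least {max(k_range) + 1} samples, got {n}")
    sub_n = int(np.ceil(item_frac * n))
    rng = np.random.default_rng(seed)
    matrices: dict[int, np.ndarray] = {}
    assignments: dict[int, np.ndarray] = {}
    for k in k_range:
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = np.sort(rng.choice(n, size=sub_n, replace=False))
            labels = _inner_cluster(x[:, idx], k, inner, rng)
            ind = np.zeros((n,), dtype=int)
            co_sample[np.ix_(idx, idx)] += 1
            same = labels[:, None] == labels[None, :]
            co_cluster[np.ix_(idx, idx)] += same
        never = (co_sample == 0) & ~np.eye(n, dtype=bool)
        if never.any():
            log.warning("K=%d: %d sample pairs never co-sampled", k, int(never.sum() // 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2.0
        z = linkage(squareform(1.0 - consensus, checks=False), method="average")
        assignments[k] = fcluster(z, t=k, criterion="maxclust")
        matrices[k] = consensus
    result = ConsensusResult(samples, matrices, assignments)
    consensus_cdf_delta(result)
    return result


def consensus_cdf_delta(result: ConsensusResult, threshold: float = 0.1) -> ConsensusResult:
    """Per-K CDF area over off-diagonal consensus entries and delta-area.

    area(K) integrates the empirical CDF of the upper-triangle consensus
    entries over [0, 1] by the lower step sum A = Σ (x_i − x_{i−1})·F(x_{i−1}),
    which is the exact integral of the right-continuous step CDF (a
    degenerate all-ones matrix therefore has area 0).  delta-area is
    the relative increase (A_K − A_{K−1})/A_{K−1}, with the first K keeping
    its raw area.  chosen_k is the smallest K whose next delta-area drops
    below ``threshold`` (the largest K otherwise).
    """
    ks = sorted(result.matrices)
    if len(ks) < 1:
        raise ValueError("no consensus matrices present")
    areas: dict[int, float] = {}
    for k in ks:
        m = result.matrices[k]
        iu = np.triu_indices(m.shape[0], k=1)
        entries = m[iu]
        cdf = empirical_cdf(entries)
        xs = np.unique(np.concatenate([[0.0], cdf.support, [1.0]]))
        ys = cdf(xs)
        areas[k] = float(np.sum(np.diff(xs) * ys[:-1]))
    deltas: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else float("inf")
    chosen = ks[-1]
    for i, k in enumerate(ks[:-1]):
        if deltas[ks[i + 1]] < threshold:
            chosen = k
            break
    result.areas = areas
    result.delta_areas = deltas
    result.chosen_k = chosen
    return result


def assign_and_validate(
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    module_genes: Sequence[str],
    k: int,
    n_resamples: int = 1000,
    item_frac: float = 0.8,
    seed: int | None = None,
    inner: str = "hierarchical_average_pearson",
) -> dict:
    """Cluster two cohorts independently on shared module genes and score
    agreement of the clusters with the control/disease labels (ARI).

    Module genes missing from either cohort are dropped (logged); fewer
    than 50% surviving in the test cohort is an error.
    """
    module_genes = sorted(set(module_genes))
    present_train = [g for g in module_genes if g in train.values.index]
    present_test = [g for g in module_genes if g in test.values.index]
    shared = sorted(set(present_train) & set(present_test))
    dropped = sorted(set(module_genes) - set(shared))
    if dropped:
        log.info("dropping %d module genes missing from a cohort: %s", len(dropped), dropped[:10])
    if len(present_test) < 0.5 * len(module_genes):
        raise ValueError(
            f"only {len(present_test)}/{len(module_genes)} module genes present in the test cohort"
        )
    out: dict = {"genes_used": shared, "cohorts": {}}
    for name, em in (("train", train), ("test", test)):
        res = consensus_cluster(
            em.subset_genes(shared), [k], n_resamples=n_resamples,
            item_frac=item_frac, seed=seed, inner=inner,
        )
        labels = res.assignments[k]
        truth = [em.groups.get(s, "") for s in res.sample_ids]
        crosstab = pd.crosstab(
            pd.Series(labels, name="cluster"), pd.Series(truth, name="group")
        )
        ari = float(adjusted_rand_score(truth, labels))
        out["cohorts"][name] = {
            "labels": dict(zip(res.sample_ids, labels.tolist())),
            "crosstab": crosstab,
            "ari": ari,
            "consensus": res,
        }
    return out
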