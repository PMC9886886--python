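"""Single-sample GSEA immune infiltration scoring and differential analysis.

Per sample, genes are ranked by expression; a signature set's enrichment
score is the integrated difference between the weighted in-set running sum
(weights are bottom-up rank positions raised to α, so the top gene weighs
N^α) and the uniform out-of-set running sum.  Scores depend on ranks only,
so they are invariant under any strictly increasing transform of a
sample's expression values.  Between-group differences per cell type use
the Wilcoxon rank-sum test with BH correction across cell types;
module-gene/cell-score associations are Pearson correlations with
significance tiers at p < 0.05 and p < 0.01.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import CONTROL, DISEASE, ExpressionMatrix
from .stats import ConstantInputError, bh_adjust, pearson_with_p, wilcoxon_rank_sum

log = logging.getLogger(__name__)

__all__ = ["ssgsea", "ssgsea_sample", "differential_scores", "gene_score_correlation"]


def ssgsea_sample(
    values: np.ndarray,
    gene_ids: Sequence[str],
    members: set[str],
    alpha: float = 0.25,
) -> float:
    """Enrichment score of one signature set in one sample.

    ``values`` are the sample's expression values aligned with ``gene_ids``.
    Genes are walked in descending expression order (ties broken by gene
    symbol for determinism); rank weights use mid-ranks counted from the
    bottom so the weighting, like the walk, is a pure function of ranks.
    """
    n = len(gene_ids)
    in_set = np.array([g in members for g in gene_ids])
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("signature set shares no genes with the expression matrix")
    if n_in == n:
        raise ValueError("signature set covers every gene; P_out is undefined")
    weights = rankdata(values)  # bottom-up mid-ranks: top gene ~ n
    order = sorted(range(n), key=lambda i: (-values[i], gene_ids[i]))
    w = weights[order] ** alpha
    in_ord = in_set[order]
    p_in = np.cumsum(np.where(in_ord, w, 0.0))
    p_in /= p_in[-1]
    p_out = np.cumsum(~in_ord) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea(
    em: ExpressionMatrix,
    sets: Mapping[str, set[str]],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Samples × signature-sets enrichment score matrix.

    Sets are intersected with the matrix's genes first (reductions logged;
    an empty post-intersection set is an error).  With ``normalize`` the
    whole matrix is divided by its global max − min, preserving every
    ordering of scores.
    """
    genes = list(em.values.index)
    gene_set = set(genes)
    reduced: dict[str, set[str]] = {}
    for name, members in sets.items():
        inter = set(members) & gene_set
        if not inter:
            raise ValueError(f"signature set {name!r} has no genes in the expression matrix")
        if len(inter) < len(members):
            log.info("set %s reduced from %d to %d genes", name, len(members), len(inter))
        if len(inter) == len(gene_set):
            raise ValueError(f"signature set {name!r} covers all genes")
        reduced[name] = inter
    mat = em.values.to_numpy(dtype=float)
    names = sorted(reduced)
    n = len(genes)
    gene_rank_key = np.argsort(np.array(genes))  # lexicographic tie-break
    tie_break = np.empty(n)
    tie_break[gene_rank_key] = np.arange(n)
    masks = {name: np.array([g in reduced[name] for g in genes]) for name in names}
    out = np.empty((len(em.values.columns), len(names)))
    for j, _sample in enumerate(em.values.columns):
        col = mat[:, j]
        # descending expression, ties by gene symbol (matches ssgsea_sample)
        order = np.lexsort((tie_break, -col))
        w = rankdata(col)[order] ** alpha
        for s, name in enumerate(names):
            in_ord = masks[name][order]
            p_in = np.cumsum(np.where(in_ord, w, 0.0))
            p_in /= p_in[-1]
            p_out = np.cumsum(~in_ord) / (n - int(in_ord.sum()))
            out[j, s] = float(np.sum(p_in - p_out))
    df = pd.DataFrame(out, index=list(em.values.columns), columns=names)
    if normalize:
        span = float(df.to_numpy().max() - df.to_numpy().min())
        if span > 0:
            df = df / span
    return df


def differential_scores(
    scores: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-set group comparison of infiltration scores.

    Wilcoxon rank-sum (disease vs control) per signature set, BH across
    sets; direction is the sign of (disease median − control median).
    """
    control = [s for s in scores.index if groups.get(s) == CONTROL]
    disease = [s for s in scores.index if groups.get(s) == DISEASE]
    if not control or not disease:
        raise ValueError("both control and disease groups must be non-empty")
    rows = []
    for name in scores.columns:
        x = scores.loc[disease, name].to_numpy()
        y = scores.loc[control, name].to_numpy()
        res = wilcoxon_rank_sum(x, y)
        direction = float(np.sign(np.median(x) - np.median(y)))
        rows.append((name, direction, res.statistic, res.p_value))
    df = pd.DataFrame(rows, columns=["set", "direction", "statistic", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df.set_index("set")


def _tier(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def gene_score_correlation(
    em: ExpressionMatrix,
    scores: pd.DataFrame,
    adjust: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Module-gene expression vs cell-type score Pearson correlations.

    Returns (r, p, tier) DataFrames of shape genes × sets; tiers are
    ``**`` (p < 0.01), ``*`` (p < 0.05) and ``ns``.  Constant genes yield
    missing entries (logged) rather than an error.  ``adjust`` applies BH
    over all finite p-values before tiering.
    """
    if list(scores.index) != list(em.values.columns):
        if set(scores.index) != set(em.values.columns):
            raise ValueError("samples of the score matrix and expression matrix differ")
        scores = scores.loc[list(em.values.columns)]
    genes = list(em.values.index)
    sets = list(scores.columns)
    r = pd.DataFrame(np.nan, index=genes, columns=sets)
    p = pd.DataFrame(np.nan, index=genes, columns=sets)
    for g in genes:
        x = em.values.loc[g].to_numpy()
        for s in sets:
            try:
                rv, pv = pearson_with_p(x, scores[s].to_numpy())
            except ConstantInputError:
                log.info("constant input for gene %s vs set %s; entry left missing", g, s)
                continue
            r.loc[g, s] = rv
            p.loc[g, s] = pv
    if adjust:
        flat = p.to_numpy().ravel()
        finite = np.isfinite(flat)
        adj = flat.copy()
        adj[finite] = bh_adjust(flat[finite])
        p = pd.DataFrame(adj.reshape(p.shape), index=genes, columns=sets)
    tier = p.map(lambda v: "na" if not np.isfinite(v) else _tier(float(v)))
    return r, p, tier
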