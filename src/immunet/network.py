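"""Co-expression network construction and PPI intersection.

The common ("immune- or PD-directed neighbor co-expressed") network is the
set intersection of (i) all gene pairs whose expression correlates with
|r| > 0.7 at Benjamini–Hochberg FDR < 0.05 (both strict, BH applied jointly
over every computed pair) and (ii) a protein–protein interaction edge list.
Nodes of the resulting graph are labelled PD / immune-PD / immune / other
from user-supplied disease and immune gene lists.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .data_io import ExpressionMatrix, canonical_edge
from .stats import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "log2_transform",
    "build_coexpression_edges",
    "intersect_with_ppi",
    "categorize",
    "annotate_categories",
    "venn_counts",
]


def log2_transform(em: ExpressionMatrix, pseudocount: float = 0.0) -> ExpressionMatrix:
    """log2(value + pseudocount), elementwise and monotone."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    v = em.values.to_numpy(dtype=float)
    if pseudocount == 0 and (v <= 0).any():
        raise ValueError("non-positive expression values require a pseudocount > 0")
    if (v + pseudocount <= 0).any():
        raise ValueError("values + pseudocount must be positive")
    out = pd.DataFrame(
        np.log2(v + pseudocount), index=em.values.index, columns=em.values.columns
    )
    return ExpressionMatrix(out, dict(em.groups))


def _allpairs_correlation(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r matrix and two-sided t-approximation p-values.

    Vectorised equivalent of stats.pearson_with_p over every gene pair.
    """
    n = values.shape[1]
    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * t_dist.sf(np.abs(tstat), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, np.minimum(p, 1.0)


def build_coexpression_edges(
    em: ExpressionMatrix, r_min: float = 0.7, q_max: float = 0.05
) -> pd.DataFrame:
    """All-pairs co-expression edges passing |r| > r_min and BH q < q_max.

    Constant genes are excluded before correlation (their r is undefined)
    with a logged count.  BH runs jointly over all computed pairs.  Both
    thresholds are strict inequalities.  Returns a DataFrame with columns
    gene_a, gene_b (canonical order), r, p, q, sorted by (gene_a, gene_b).
    """
    if em.values.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    values = em.values.to_numpy(dtype=float)
    keep = values.std(axis=1) > 0
    n_const = int((~keep).sum())
    if n_const:
        log.info("dropping %d constant genes before correlation", n_const)
    genes = [g for g, k in zip(em.values.index, keep) if k]
    values = values[keep]
    m = len(genes)
    if m < 2:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r", "p", "q"])
    r_mat, p_mat = _allpairs_correlation(values)
    iu, ju = np.triu_indices(m, k=1)
    r_flat, p_flat = r_mat[iu, ju], p_mat[iu, ju]
    q_flat = bh_adjust(p_flat)
    mask = (np.abs(r_flat) > r_min) & (q_flat < q_max)
    rows = []
    for i, j, r, p, q in zip(iu[mask], ju[mask], r_flat[mask], p_flat[mask], q_flat[mask]):
        a, b = canonical_edge(genes[i], genes[j])
        rows.append((a, b, float(r), float(p), float(q)))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "q"])
    return df.sort_values(["gene_a", "gene_b"], ignore_index=True)


def intersect_with_ppi(
    coexpr: pd.DataFrame, ppi: Iterable[tuple[str, str]]
) -> nx.Graph:
    """Common network: co-expression edges that are also PPI edges.

    Nodes are the endpoints of surviving edges (isolated genes are not
    retained); each edge carries the co-expression r and q.
    """
    ppi_set = {canonical_edge(a, b) for a, b in ppi}
    g = nx.Graph()
    for row in coexpr.itertuples(index=False):
        e = canonical_edge(row.gene_a, row.gene_b)
        if e in ppi_set:
            g.add_edge(*e, r=float(row.r), q=float(row.q))
    if g.number_of_edges() == 0:
        log.info("co-expression / PPI intersection is empty")
    return g


def categorize(
    nodes: Iterable[str], pd_genes: set[str], immune_genes: set[str]
) -> tuple[dict[str, str], Counter]:
    """Partition genes into PD / immune-PD / immune / other.

    A gene present in both the disease and the immune list is immune-PD;
    in exactly one list, PD or immune respectively; otherwise other.
    """
    categories: dict[str, str] = {}
    for gene in nodes:
        in_pd = gene in pd_genes
        in_imm = gene in immune_genes
        if in_pd and in_imm:
            categories[gene] = "immune-PD"
        elif in_pd:
            categories[gene] = "PD"
        elif in_imm:
            categories[gene] = "immune"
        else:
            categories[gene] = "other"
    return categories, Counter(categories.values())


def annotate_categories(network: nx.Graph, categories: Mapping[str, str]) -> nx.Graph:
    """Attach the category label as a node attribute (in place)."""
    for n in network.nodes:
        network.nodes[n]["category"] = categories.get(n, "other")
    return network


def venn_counts(sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Counts of the 2^k − 1 disjoint Venn regions of 2 or 3 named sets.

    Keys are frozensets of the names whose sets contain the region's
    elements (exclusively); values sum to the size of the union.
    """
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn_counts supports 2 or 3 sets")
    out: dict[frozenset, int] = {}
    for k in range(1, len(names) + 1):
        for inside in itertools.combinations(names, k):
            region = set.intersection(*(set(sets[n]) for n in inside))
            for n in names:
                if n not in inside:
                    region -= set(sets[n])
            out[frozenset(inside)] = len(region)
    return out
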