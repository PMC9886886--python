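"""Module detection on the common network via Markov clustering.

Markov clustering (MCL) simulates flow on the graph: starting from the
column-stochastic adjacency matrix (with self-loops), it alternates
expansion (matrix squaring, spreading flow) and inflation (elementwise
powering + renormalisation, sharpening flow) until the matrix stops
changing; clusters are read from the non-zero structure of the limit.
MCL is deterministic and parameter-light, which makes it a reproducible
stand-in for web-service module detection whose algorithm is undocumented.

Detected clusters are then filtered to those containing at least six core
(PD or immune-PD) genes and ranked by a functional score defined here as
core-gene count × edge density — the ranking notion is this package's own,
prominently so, since no standard definition exists for "functional score".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

log = logging.getLogger(__name__)

__all__ = ["Module", "mcl_cluster", "score_modules", "select_top"]

CORE_CATEGORIES = ("PD", "immune-PD")


@dataclass(frozen=True)
class Module:
    """A detected gene module with its core content and ranking score."""

    members: tuple[str, ...]
    core_count: int
    density: float
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0,1]")


def mcl_cluster(
    network: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 200,
    tol: float = 1e-8,
    prune_threshold: float = 1e-6,
) -> list[set[str]]:
    """Markov clustering of an undirected graph into disjoint clusters.

    Self-loops of weight 1 are added, columns are normalised to sum 1, then
    expansion (matrix power) and inflation (elementwise power, renormalise)
    alternate until the max absolute change falls below ``tol``.  Entries
    below ``prune_threshold`` are zeroed each round (the column maximum is
    always kept).  Clusters are the connected components of the non-zero
    structure of the limit matrix, so every node lands in exactly one
    cluster and node ordering cannot affect membership.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    nodes = sorted(network.nodes)
    a = nx.to_numpy_array(network, nodelist=nodes, weight=None)
    np.fill_diagonal(a, 1.0)
    m = a / a.sum(axis=0, keepdims=True)
    for it in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m /= m.sum(axis=0, keepdims=True)
        # prune tiny flow, always keeping each column's maximum
        keep = (m >= prune_threshold) | (m == m.max(axis=0, keepdims=True))
        m = np.where(keep, m, 0.0)
        col_sums = m.sum(axis=0, keepdims=True)
        m /= col_sums
        residual = float(np.abs(m - prev).max())
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"MCL did not converge in {max_iter} iterations (residual {residual:.3g})"
        )
    support = nx.Graph()
    support.add_nodes_from(range(len(nodes)))
    rows, cols = np.nonzero(m)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    clusters = [
        {nodes[i] for i in comp} for comp in nx.connected_components(support)
    ]
    return sorted(clusters, key=lambda c: (-len(c), min(c)))


def score_modules(
    clusters: Iterable[set[str]],
    categories: Mapping[str, str],
    network: nx.Graph,
    min_core: int = 6,
    core_categories: Sequence[str] = CORE_CATEGORIES,
) -> list[Module]:
    """Filter clusters by core-gene content and rank by functional score.

    Core genes are members whose category is PD or immune-PD.  Clusters with
    fewer than ``min_core`` cores are dropped.  score = core_count × density
    where density is the edge density of the cluster's induced subgraph
    (0 for singletons).  Sorted descending by score, ties broken by size
    then by lexicographically first member, so ranking is independent of
    input order.
    """
    core_categories = set(core_categories)
    out: list[Module] = []
    for cluster in clusters:
        members = tuple(sorted(cluster))
        cores = sum(1 for g in members if categories.get(g, "other") in core_categories)
        if cores < min_core:
            continue
        k = len(members)
        possible = k * (k - 1) / 2
        sub = network.subgraph(members)
        density = sub.number_of_edges() / possible if possible else 0.0
        out.append(Module(members, cores, density, cores * density))
    out.sort(key=lambda mod: (-mod.score, -len(mod.members), mod.members[0]))
    return out


def select_top(modules: Sequence[Module], k: int = 5) -> tuple[list[Module], set[str]]:
    """Top-k modules by score plus the pooled union of their members."""
    if len(modules) < k:
        log.warning("only %d modules available for top-%d selection", len(modules), k)
    top = list(modules[:k])
    pooled: set[str] = set()
    for mod in top:
        pooled.update(mod.members)
    return top, pooled
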