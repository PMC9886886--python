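"""Directed-neighbor sub-networks and category-wise co-expression structure.

From the common network, a neighbor network keeps the "core" genes (by
default the PD and immune-PD categories) together with every gene directly
connected to a core.  Edge correlation values are then grouped by gene
category, compared pairwise by Wilcoxon rank-sum with BH correction, and
summarised as empirical CDF curves; a cores × neighbors Pearson matrix
flags pairs with |r| above the network threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .stats import ECDF, bh_adjust, empirical_cdf, pearson_with_p, wilcoxon_rank_sum

__all__ = [
    "NeighborNetwork",
    "extract_neighbor_network",
    "group_coexpression_values",
    "compare_groups",
    "core_neighbor_matrix",
]


@dataclass
class NeighborNetwork:
    """Core genes, their direct neighbors, and the induced edges."""

    core_nodes: set[str]
    neighbor_nodes: set[str]
    graph: nx.Graph
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.core_nodes & self.neighbor_nodes:
            raise ValueError("core and neighbor sets must be disjoint")


def extract_neighbor_network(
    network: nx.Graph,
    categories: Mapping[str, str],
    core_categories: Iterable[str],
) -> NeighborNetwork:
    """Sub-network of core-category genes plus their direct neighbors.

    Cores are the nodes whose category is in ``core_categories``; neighbors
    are non-core nodes adjacent to at least one core; the edge set keeps
    every parent edge with at least one core endpoint.
    """
    core_categories = set(core_categories)
    if not core_categories:
        raise ValueError("core_categories must be non-empty")
    cores = {n for n in network.nodes if categories.get(n, "other") in core_categories}
    edges = [(a, b) for a, b in network.edges if a in cores or b in cores]
    neighbors = {n for e in edges for n in e} - cores
    g = nx.Graph()
    g.add_nodes_from(cores)
    for a, b in edges:
        g.add_edge(a, b, **network.edges[a, b])
    member_cats = {n: categories.get(n, "other") for n in g.nodes}
    return NeighborNetwork(cores, neighbors, g, member_cats)


def group_coexpression_values(nn: NeighborNetwork) -> dict[str, np.ndarray]:
    """Edge r-values grouped by gene category.

    Each edge contributes its r exactly once: to the category of its
    non-core endpoint, or — for core–core edges — to the category of the
    second endpoint in canonical order (a fixed, documented tie-break).
    """
    groups: dict[str, list[float]] = {}
    for a, b in nn.graph.edges:
        r = nn.graph.edges[a, b].get("r")
        if r is None:
            raise ValueError(f"edge {a}–{b} lacks an r attribute")
        if a in nn.core_nodes and b in nn.core_nodes:
            target = max(a, b)
        elif a in nn.core_nodes:
            target = b
        else:
            target = a
        cat = nn.categories.get(target, "other")
        groups.setdefault(cat, []).append(float(r))
    return {c: np.asarray(v) for c, v in groups.items()}


def compare_groups(
    groups: Mapping[str, Sequence[float]], absolute: bool = False
) -> tuple[pd.DataFrame, dict[str, ECDF]]:
    """Pairwise Wilcoxon rank-sum tests between category r-value groups.

    Signed r values are compared by default (``absolute=True`` switches to
    |r|).  BH correction runs across the pairwise family.  Returns the test
    table and the per-group empirical CDFs of the compared values.
    """
    cleaned = {
        c: (np.abs(np.asarray(v, dtype=float)) if absolute else np.asarray(v, dtype=float))
        for c, v in groups.items()
        if len(v) > 0
    }
    if len(cleaned) == 0:
        raise ValueError("all groups are empty")
    rows = []
    for a, b in itertools.combinations(sorted(cleaned), 2):
        res = wilcoxon_rank_sum(cleaned[a], cleaned[b])
        rows.append((a, b, res.statistic, res.p_value, res.n1, res.n2))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p", "n1", "n2"])
    if not df.empty:
        df["q"] = bh_adjust(df["p"].to_numpy())
    cdfs = {c: empirical_cdf(v) for c, v in cleaned.items()}
    return df, cdfs


def core_neighbor_matrix(
    em: ExpressionMatrix,
    cores: Iterable[str],
    neighbors: Iterable[str],
    r_min: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cores × neighbors Pearson r matrix plus a strict |r| > r_min flag."""
    cores = sorted(set(cores))
    neighbors = sorted(set(neighbors))
    for g in itertools.chain(cores, neighbors):
        if g not in em.values.index:
            raise KeyError(f"gene {g!r} missing from the expression matrix")
    r = pd.DataFrame(index=cores, columns=neighbors, dtype=float)
    for c in cores:
        xc = em.values.loc[c].to_numpy()
        for u in neighbors:
            if u == c:
                r.loc[c, u] = 1.0
                continue
            r.loc[c, u] = pearson_with_p(xc, em.values.loc[u].to_numpy())[0]
    flags = r.abs() > r_min
    return r, flags
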