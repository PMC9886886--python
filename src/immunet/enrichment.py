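"""Hypergeometric over-representation analysis of gene lists.

Annotations are always user-supplied (GMT or two-column TSV); term p-values
come from the hypergeometric upper tail against an explicit gene universe,
BH-adjusted within each namespace (BP/CC/MF/pathway families are corrected
separately).  Retained rows satisfy p < p_max strictly and overlap k >=
min_overlap, mirroring a p-and-count filter.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .stats import bh_adjust, hypergeom_tail

log = logging.getLogger(__name__)

__all__ = ["ora"]


def ora(
    query: Iterable[str],
    annotation: Mapping[str, set[str]],
    universe: Iterable[str],
    p_max: float = 0.05,
    min_overlap: int = 2,
    namespaces: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Over-representation of ``query`` genes in each annotation term.

    Query genes outside the universe are dropped (logged); each term is
    restricted to the universe.  ``namespaces`` optionally maps term ->
    family (e.g. BP/CC/MF/pathway); BH correction runs within each family.
    Returns rows sorted by p with columns term, namespace, k, K, n, N, p,
    q, genes.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    outside = query - universe
    if outside:
        log.info("dropping %d query genes outside the universe", len(outside))
    query &= universe
    if not query:
        raise ValueError("query is empty after intersection with the universe")
    n = len(query)
    big_n = len(universe)
    rows = []
    for term in sorted(annotation):
        members = set(annotation[term]) & universe
        if not members:
            continue
        overlap = sorted(query & members)
        k, big_k = len(overlap), len(members)
        p = hypergeom_tail(k, big_k, n, big_n)
        ns = (namespaces or {}).get(term, "term")
        rows.append((term, ns, k, big_k, n, big_n, p, ",".join(overlap)))
    df = pd.DataFrame(
        rows, columns=["term", "namespace", "k", "K", "n", "N", "p", "genes"]
    )
    if df.empty:
        df["q"] = pd.Series(dtype=float)
        return df
    df["q"] = np.nan
    for ns, idx in df.groupby("namespace").groups.items():
        df.loc[idx, "q"] = bh_adjust(df.loc[idx, "p"].to_numpy())
    kept = df[(df["p"] < p_max) & (df["k"] >= min_overlap)]
    return kept.sort_values(["p", "term"], ignore_index=True)
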