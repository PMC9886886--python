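"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices, PPI edge lists and gene category tables travel as TSV;
signature collections as GMT; networks as GraphML (via networkx) or SIF so
they load directly into Cytoscape.  All writers emit rows in a stable sorted
order so outputs are diffable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CONTROL = "control"
DISEASE = "disease"

__all__ = [
    "ExpressionMatrix",
    "canonical_edge",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_groups_tsv",
    "write_groups_tsv",
    "read_edge_list",
    "write_edge_list",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_category_tsv",
    "write_category_tsv",
    "write_network",
    "read_network",
]


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with per-sample group labels.

    ``values`` is a DataFrame indexed by gene symbol with sample IDs as
    columns; ``groups`` maps every sample to ``control`` or ``disease``.
    """

    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene IDs: {list(dups)[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        for s in self.values.columns:
            if self.groups and s not in self.groups:
                raise ValueError(f"sample {s!r} missing from group assignment")
            if self.groups and self.groups[s] not in (CONTROL, DISEASE):
                raise ValueError(f"unknown group {self.groups[s]!r} for {s!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == group]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[keep].copy(), dict(self.groups))


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Undirected edge key: endpoints in sorted order."""
    return (a, b) if a <= b else (b, a)


def _check_nonempty(path: Path, lines: Sequence[str]) -> None:
    if not lines:
        raise ValueError(f"{path}: empty file")


def read_expression_tsv(
    path: str | Path,
    group_assignment: Mapping[str, str] | None = None,
    collapse: str = "max_mean",
    uppercase: bool = True,
) -> ExpressionMatrix:
    """Load a genes × samples TSV (first column gene symbol, header row).

    Duplicate gene symbols are collapsed by ``collapse``: ``max_mean`` keeps
    the row with the highest mean (the default probe-collapse rule),
    ``mean`` averages the rows, ``first`` keeps the first on disk.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression file")
    try:
        df = df.astype(float)
    except ValueError as exc:
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.argmax()]
                raise ValueError(
                    f"{path}: non-numeric value at gene {row!r}, sample {col!r}"
                ) from exc
        raise
    df.index = df.index.astype(str)
    df.index.name = None
    if uppercase:
        df.index = df.index.str.upper()
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        log.info("collapsing %d duplicate gene rows by %s", n_dup, collapse)
        if collapse == "max_mean":
            means = df.mean(axis=1)
            order = np.argsort(-means.to_numpy(), kind="mergesort")
            df = df.iloc[order]
            df = df[~df.index.duplicated(keep="first")]
            df = df.sort_index()
        elif collapse == "mean":
            df = df.groupby(level=0).mean()
        elif collapse == "first":
            df = df[~df.index.duplicated(keep="first")]
        else:
            raise ValueError(f"unknown collapse rule {collapse!r}")
    groups: dict[str, str] = {}
    if group_assignment is not None:
        missing = [s for s in df.columns if s not in group_assignment]
        if missing:
            raise ValueError(f"{path}: samples missing from group assignment: {missing}")
        groups = {s: group_assignment[s] for s in df.columns}
    return ExpressionMatrix(df, groups)


def write_expression_tsv(em: ExpressionMatrix, path: str | Path) -> None:
    em.values.to_csv(Path(path), sep="\t", index_label="gene")


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    """Two-column sample→group TSV (no header)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    _check_nonempty(path, lines)
    groups: dict[str, str] = {}
    for i, ln in enumerate(lines, 1):
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i}: expected 2 tab-separated fields")
        groups[parts[0]] = parts[1]
    return groups


def write_groups_tsv(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sorted(groups):
            fh.write(f"{s}\t{groups[s]}\n")


def read_edge_list(
    path: str | Path, dialect: str = "tsv", uppercase: bool = True
) -> list[tuple[str, str]]:
    """Read an undirected edge list (two-column TSV, or SIF ``node rel node``).

    Edges are canonicalized; duplicates and self-loops are dropped with a
    logged count.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    _check_nonempty(path, lines)
    edges: set[tuple[str, str]] = set()
    ordered: list[tuple[str, str]] = []
    n_self = n_dup = 0
    for i, ln in enumerate(lines, 1):
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if dialect == "tsv":
            if len(parts) < 2:
                raise ValueError(f"{path}:{i}: expected 2 columns")
            a, b = parts[0], parts[1]
        elif dialect == "sif":
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: SIF needs 'node relation node'")
            a, b = parts[0], parts[2]
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        if uppercase:
            a, b = a.upper(), b.upper()
        if a == b:
            n_self += 1
            continue
        e = canonical_edge(a, b)
        if e in edges:
            n_dup += 1
            continue
        edges.add(e)
        ordered.append(e)
    if n_self or n_dup:
        log.info("%s: dropped %d self-loops, %d duplicate edges", path, n_self, n_dup)
    return ordered


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(canonical_edge(*e) for e in edges):
            fh.write(f"{a}\t{b}\n")


def read_gene_list(path: str | Path, uppercase: bool = True) -> set[str]:
    """One-symbol-per-line gene list."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    _check_nonempty(path, lines)
    return {ln.upper() if uppercase else ln for ln in lines}


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gmt(path: str | Path, uppercase: bool = True) -> dict[str, set[str]]:
    """Read signature sets in GMT format (name, description, members...)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    _check_nonempty(path, lines)
    sets: dict[str, set[str]] = {}
    for i, ln in enumerate(lines, 1):
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{i}: GMT line needs >= 3 fields")
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}:{i}: duplicate set name {name!r}")
        members = {m.upper() if uppercase else m for m in parts[2:] if m}
        if not members:
            raise ValueError(f"{path}:{i}: set {name!r} has no members")
        sets[name] = members
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            desc = (descriptions or {}).get(name, "na")
            members = "\t".join(sorted(set(sets[name])))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_category_tsv(path: str | Path, uppercase: bool = True) -> dict[str, str]:
    """Two-column gene→category TSV."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    _check_nonempty(path, lines)
    out: dict[str, str] = {}
    for i, ln in enumerate(lines, 1):
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i}: expected 2 tab-separated fields")
        g = parts[0].upper() if uppercase else parts[0]
        out[g] = parts[1]
    return out


def write_category_tsv(categories: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(categories):
            fh.write(f"{g}\t{categories[g]}\n")


def write_network(network: nx.Graph, path: str | Path, dialect: str = "graphml") -> None:
    """Write a network for Cytoscape: GraphML with node ``category`` and edge
    ``r``/``q`` attributes, or SIF with relation ``co``."""
    path = Path(path)
    if dialect == "graphml":
        g = nx.Graph()
        for n in sorted(network.nodes):
            g.add_node(n, **network.nodes[n])
        for a, b in sorted(canonical_edge(a, b) for a, b in network.edges):
            g.add_edge(a, b, **network.edges[a, b])
        nx.write_graphml(g, path)
    elif dialect == "sif":
        with open(path, "w") as fh:
            seen: set[str] = set()
            for a, b in sorted(canonical_edge(a, b) for a, b in network.edges):
                fh.write(f"{a}\tco\t{b}\n")
                seen.update((a, b))
            for n in sorted(set(network.nodes) - seen):
                fh.write(f"{n}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(Path(path))
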