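#!/usr/bin/env python
"""Extract the disease-directed neighbor network and compare co-expression
across gene categories.

Cores are the PD and immune-PD genes of the common network; edge r-values
are grouped by the neighbor's category, compared pairwise by Wilcoxon
rank-sum with BH correction, and summarised as empirical CDF curves; a
cores × neighbors correlation heatmap matrix flags |r| > 0.7 pairs.
Outputs land under results/neighbors/.
"""

from pathlib import Path

import pandas as pd

from immunet import data_io
from immunet.neighbors import compare_groups, core_neighbor_matrix, extract_neighbor_network, group_coexpression_values

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"
OUT = ROOT / "neighbors"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    net = data_io.read_network(ROOT / "network" / "common_network.graphml")
    categories = data_io.read_category_tsv(ROOT / "network" / "categories.tsv")
    groups = data_io.read_groups_tsv(DATA / "discovery_groups.tsv")
    em = data_io.read_expression_tsv(DATA / "discovery_expression.tsv", groups)

    nn = extract_neighbor_network(net, categories, {"PD", "immune-PD"})
    data_io.write_network(nn.graph, OUT / "pdnc.graphml", "graphml")
    print(f"neighbor network: {len(nn.core_nodes)} cores, "
          f"{len(nn.neighbor_nodes)} neighbors, {nn.graph.number_of_edges()} edges")

    grouped = group_coexpression_values(nn)
    print("r-values per category:", {c: len(v) for c, v in grouped.items()})
    if len(grouped) >= 2:
        table, cdfs = compare_groups(grouped)
        table.to_csv(OUT / "group_tests.tsv", sep="\t", index=False)
        rows = [(c, float(x), float(f)) for c, e in cdfs.items()
                for x, f in zip(e.support, e.fractions)]
        pd.DataFrame(rows, columns=["category", "r", "cdf"]).to_csv(
            OUT / "cdf_points.tsv", sep="\t", index=False)
        for row in table.itertuples(index=False):
            verdict = "differs" if row.q < 0.05 else "no difference"
            print(f"  {row.group_a} vs {row.group_b}: p={row.p:.3g} q={row.q:.3g} ({verdict})")

    cores = sorted(nn.core_nodes)
    neighbors = sorted(nn.neighbor_nodes)
    if cores and neighbors:
        r, flags = core_neighbor_matrix(em, cores, neighbors)
        r.to_csv(OUT / "core_neighbor_r.tsv", sep="\t")
        flags.to_csv(OUT / "core_neighbor_flags.tsv", sep="\t")
        print(f"heatmap matrix {r.shape[0]}x{r.shape[1]}; "
              f"{int(flags.to_numpy().sum())} pairs flagged at |r|>0.7")


if __name__ == "__main__":
    main()
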