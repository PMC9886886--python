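#!/usr/bin/env python
"""Build the common (co-expression ∩ PPI) network of the discovery cohort.

Thresholds are |r| > 0.7 with BH FDR < 0.05 over all gene pairs.  Writes
the retained correlation edges, the annotated network (GraphML + SIF), the
four-way category counts and the Venn region counts under results/network/.
"""

from pathlib import Path

import pandas as pd

from immunet import data_io
from immunet.network import annotate_categories, build_coexpression_edges, categorize, intersect_with_ppi, venn_counts

DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"
OUT = Path(__file__).resolve().parents[1] / "results" / "network"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    groups = data_io.read_groups_tsv(DATA / "discovery_groups.tsv")
    em = data_io.read_expression_tsv(DATA / "discovery_expression.tsv", groups)
    ppi = data_io.read_edge_list(DATA / "discovery_ppi.tsv")
    pd_genes = data_io.read_gene_list(DATA / "discovery_pd_genes.txt")
    immune = data_io.read_gene_list(DATA / "discovery_immune_genes.txt")

    coexpr = build_coexpression_edges(em, r_min=0.7, q_max=0.05)
    coexpr.to_csv(OUT / "coexpression_edges.tsv", sep="\t", index=False)
    net = intersect_with_ppi(coexpr, ppi)
    categories, counts = categorize(net.nodes, pd_genes, immune)
    annotate_categories(net, categories)
    data_io.write_network(net, OUT / "common_network.graphml", "graphml")
    data_io.write_network(net, OUT / "common_network.sif", "sif")
    data_io.write_category_tsv(categories, OUT / "categories.tsv")

    print(f"co-expression pairs retained: {len(coexpr)}")
    print(f"common network: {net.number_of_nodes()} nodes, "
          f"{net.number_of_edges()} edges")
    print("category counts:",
          {c: counts.get(c, 0) for c in ("PD", "immune-PD", "immune", "other")})

    venn = venn_counts({
        "network": set(net.nodes), "PD": pd_genes, "immune": immune,
    })
    rows = [("&".join(sorted(k)), v) for k, v in sorted(venn.items(), key=lambda x: sorted(x[0]))]
    pd.DataFrame(rows, columns=["region", "count"]).to_csv(
        OUT / "venn_counts.tsv", sep="\t", index=False
    )
    triple = venn[frozenset({"network", "PD", "immune"})]
    print(f"triple-overlap (network ∩ PD ∩ immune): {triple} genes")


if __name__ == "__main__":
    main()
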