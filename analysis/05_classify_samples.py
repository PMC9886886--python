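#!/usr/bin/env python
"""Consensus-cluster the cohorts on module genes and validate the
classification against the known groups.

The train cohort is scanned over K=2..6 (CDF area / delta-area); both the
train and the independent validation cohort are then clustered at K=2 and
scored against the control/disease labels by adjusted Rand index.
Outputs under results/classification/.
"""

from pathlib import Path

import pandas as pd

from immunet import data_io
from immunet.consensus import assign_and_validate, consensus_cluster

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"
OUT = ROOT / "classification"
SEED = 20240901
N_RESAMPLES = 200  # resampling depth of the consensus runs in this analysis


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    train = data_io.read_expression_tsv(
        DATA / "train_expression.tsv",
        data_io.read_groups_tsv(DATA / "train_groups.tsv"))
    test = data_io.read_expression_tsv(
        DATA / "validation_expression.tsv",
        data_io.read_groups_tsv(DATA / "validation_groups.tsv"))
    # module genes of the classification cohorts: the planted module block
    genes = train.gene_ids[:100]

    res = consensus_cluster(train.subset_genes(genes), range(2, 7),
                            n_resamples=N_RESAMPLES, seed=SEED)
    pd.DataFrame({"K": list(res.areas), "area": list(res.areas.values()),
                  "delta_area": [res.delta_areas[k] for k in res.areas]}).to_csv(
        OUT / "cdf_area.tsv", sep="\t", index=False)
    print("CDF areas:", {k: round(v, 3) for k, v in res.areas.items()})
    print("delta areas:", {k: round(v, 3) for k, v in res.delta_areas.items()})
    print(f"chosen K by delta-area threshold: {res.chosen_k}")

    val = assign_and_validate(train, test, genes, k=2,
                              n_resamples=N_RESAMPLES, seed=SEED, inner="kmeans")
    for name in ("train", "test"):
        cohort = val["cohorts"][name]
        pd.Series(cohort["labels"], name="cluster").to_csv(
            OUT / f"{name}_labels.tsv", sep="\t")
        cohort["crosstab"].to_csv(OUT / f"{name}_crosstab.tsv", sep="\t")
        print(f"{name} cohort: ARI vs true groups = {cohort['ari']:.3f}")
        print(cohort["crosstab"].to_string())


if __name__ == "__main__":
    main()
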