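#!/usr/bin/env python
"""Generate the synthetic study cohorts used by the downstream analyses.

Writes a discovery cohort (8 control / 14 disease, five planted modules,
within-module r = 0.9) with its PPI graph and category lists, an
independent validation cohort for the classification analysis, and a
signature-study cohort (24 immune-cell sets, 4 with a planted 2σ
infiltration shift) under results/data/.
"""

from dataclasses import replace
from pathlib import Path

from immunet import data_io
from immunet.evaluate import CLASSIFICATION_STUDY, INFILTRATION_STUDY, INFILTRATION_SETS, NETWORK_STUDY
from immunet.synthetic import generate_dataset, generate_signature_dataset

SEED = 20240901
OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"


def write_cohort(cfg, prefix: str):
    em, ppi, categories, truth = generate_dataset(cfg)
    data_io.write_expression_tsv(em, OUT / f"{prefix}_expression.tsv")
    data_io.write_groups_tsv(em.groups, OUT / f"{prefix}_groups.tsv")
    data_io.write_edge_list(ppi, OUT / f"{prefix}_ppi.tsv")
    data_io.write_category_tsv(categories, OUT / f"{prefix}_categories.tsv")
    pd_genes = {g for g, c in categories.items() if c in ("PD", "immune-PD")}
    immune = {g for g, c in categories.items() if c in ("immune", "immune-PD")}
    data_io.write_gene_list(pd_genes, OUT / f"{prefix}_pd_genes.txt")
    data_io.write_gene_list(immune, OUT / f"{prefix}_immune_genes.txt")
    print(f"{prefix}: {len(em.gene_ids)} genes x {len(em.sample_ids)} samples, "
          f"{len(ppi)} PPI edges, {len(pd_genes)} disease-list genes")
    return em, truth


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    write_cohort(replace(NETWORK_STUDY, seed=SEED), "discovery")
    write_cohort(replace(CLASSIFICATION_STUDY, seed=SEED + 1), "train")
    write_cohort(replace(CLASSIFICATION_STUDY, seed=SEED + 2), "validation")

    em, sets, truth = generate_signature_dataset(
        replace(INFILTRATION_STUDY, seed=SEED + 3), **INFILTRATION_SETS
    )
    data_io.write_expression_tsv(em, OUT / "signature_expression.tsv")
    data_io.write_groups_tsv(em.groups, OUT / "signature_groups.tsv")
    data_io.write_gmt(sets, OUT / "immune_signatures.gmt")
    data_io.write_gene_list(sorted(truth.shifted_sets), OUT / "shifted_sets.txt")
    print(f"signatures: {len(sets)} sets of {INFILTRATION_SETS['set_size']} genes, "
          f"{len(truth.shifted_sets)} with a planted disease shift")


if __name__ == "__main__":
    main()
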