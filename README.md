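# immunet

Immune-directed co-expression network analysis for two-group expression
cohorts, built around the workflow used to dissect immune involvement in
Parkinson's disease from post-mortem brain expression profiles: find gene
pairs that are both strongly co-expressed and physically interacting,
label them by disease/immune annotation, pull out the modules anchored by
disease genes, ask whether those modules classify patients, and score
immune-cell infiltration per sample.

## What it computes

Given a genes × samples expression matrix with control/disease labels, a
protein–protein interaction (PPI) edge list, disease- and immune-gene
lists, and immune-cell signature sets (GMT):

1. **Common network** — all-pairs Pearson correlation; keep pairs with
   |r| > 0.7 and Benjamini–Hochberg FDR < 0.05 (BH applied jointly over
   every computed pair), intersect with the PPI edge list, and label each
   node PD / immune-PD / immune / other (immune-PD = present in both
   lists).
2. **Neighbor network** — the core (PD + immune-PD) genes and their direct
   neighbors; edge correlations are grouped by the neighbor's category and
   compared pairwise by the Wilcoxon rank-sum test (exact enumeration at
   small n, normal approximation with tie/continuity correction otherwise),
   with empirical-CDF summaries per category.
3. **Modules** — Markov clustering (MCL, inflation 2.0) of the common
   network; clusters with ≥ 6 core genes are ranked by a functional score
   defined here as *core count × edge density*, and the top 5 are kept.
4. **Classification** — Monti-style consensus clustering of samples on the
   module genes (resampled co-clustering proportions; CDF area and
   delta-area guide the choice of K), validated on an external cohort via
   the adjusted Rand index against the known groups.
5. **Infiltration** — single-sample GSEA: per sample, genes are ranked and
   each signature set scored by the integrated difference between the
   rank-weighted in-set running sum (weight = bottom-up rank^α, α = 0.25)
   and the uniform out-of-set running sum; group differences per cell type
   by Wilcoxon + BH.
6. **Enrichment** — hypergeometric upper-tail over-representation of module
   genes against user-supplied term → gene annotations and an explicit
   universe, BH-corrected within namespace.
7. **Relative quantification** — the 2^−ΔΔCt fold-change contract for
   qPCR-style validation data.

A synthetic-data generator plants every piece of ground truth (co-expressed
modules with closed-form within-module correlation β²/(β²+σ²), PPI edges
enriched within modules, category labels, infiltration shifts), so each
stage is tested against known answers with no downloads.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
cohorts (tables land under `results/`, bulky simulated data under
`scratch/`):

```
python analysis/01_simulate_cohorts.py
python analysis/02_build_common_network.py
python analysis/04_detect_modules.py
python analysis/05_classify_samples.py
python analysis/06_immune_infiltration.py
```

Printed output (seed 20240901):

```
co-expression pairs retained: 227
common network: 50 nodes, 175 edges
category counts: {'PD': 20, 'immune-PD': 15, 'immune': 10, 'other': 5}
...
MCL found 5 clusters (sizes [10, 10, 10, 10, 10])
5 modules pass the 6-core filter; selected top 5
  module 1: 10 genes, 7 cores, density 0.89, score 6.22
...
train cohort: ARI vs true groups = 1.000
test cohort: ARI vs true groups = 1.000
...
5 of 24 cell types differ at q<0.05: ['CELL_01', 'CELL_02', 'CELL_03', 'CELL_04', 'CELL_20']
planted shifted sets: ['CELL_01', 'CELL_02', 'CELL_03', 'CELL_04'] (all recovered)
```

The five planted co-expression modules come back as the five MCL clusters,
consensus clustering at K = 2 reproduces the control/disease split in both
cohorts (ARI 1.0 at this seed), and the four signature sets carrying a
planted 2σ disease shift are all flagged (with one stray flag — ssGSEA
scores are compositional in the ranks, see `docs/methods.md`).

The same stages are available as a CLI (`immunet simulate`,
`immunet build-network`, `immunet pdnc`, `immunet modules`,
`immunet consensus`, `immunet ssgsea`, `immunet enrich`, and
`immunet run --config run.yaml` for the full pipeline with a JSON
manifest).

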