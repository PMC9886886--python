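# Methods

This note documents the models, parameter choices and numerical decisions
behind the pipeline, and what the synthetic studies do and do not
demonstrate about real data.

## Synthetic cohorts

Expression of gene *g* (module *m*) in sample *j* follows a single-factor
module model:

    x_gj = μ_g + β·f_mj + δ·1[j ∈ disease, m shifted] + σ·ε_gj

with f_mj, ε_gj independent standard normal and μ_g a fixed gene baseline
(default N(7, 1)). Genes outside modules are baseline plus noise. Two
genes of the same module then have population correlation

    ρ = β² / (β² + σ²),

which the tests use in closed form (β=2, σ=1 → ρ=0.8 by default; β=3 →
ρ=0.9 for the network-recovery study). PPI edges are Bernoulli: 0.8
within modules, 0.02 between. Category labels (PD / immune-PD / immune /
other) are assigned per module as deterministic leading blocks of the
requested fractions, so ground truth is reproducible from the seed alone;
one RNG stream per dataset makes identical configs bit-identical.

The disease shift δ applies to a configurable subset of modules,
defaulting to the first ⌈n_modules/2⌉. A shift on *every* module gene
would be a per-sample constant, and Pearson-based sample distances are
invariant to adding a constant to one sample's profile — the default
keeps planted group structure visible to correlation-based clustering.

The signature-study generator drops the module factor entirely: genes are
independent, and the members of the first `n_shifted_sets` signature sets
gain δ in disease samples. Values are abstract continuous intensities on
a log-like scale; probe-level artifacts, batch effects, missingness and
count-distribution quirks of real platforms are deliberately not
emulated, so passing tests demonstrate correctness of the algorithms
under the stated model, not robustness to platform pathology.

## Statistical primitives

* **Pearson + p** — two-sided p from t = r√(n−2)/√(1−r²) on n−2 df.
  |r| within 10⁻¹² of 1 is snapped to ±1 with p = 0 (exact collinearity
  up to float noise). The t approximation (not permutation) keeps
  all-pairs construction tractable.
* **BH** — step-up q_(i) = min_{j≥i}(p_(j)·m/j), capped at 1. Note BH is
  *not* idempotent (e.g. [0.25, 1] → [0.5, 1] → [1, 1]); the tested
  invariants are q ≥ p and order preservation.
* **Wilcoxon rank-sum** — exact mode enumerates the tie-free null
  distribution of the rank sum by the classic counting recursion;
  two-sided p = min(1, 2·min(P≤, P≥)). The approximation uses the normal
  with mid-rank tie correction and a 0.5 continuity correction, matching
  scipy's asymptotic mode to machine precision. `auto` uses exact when
  both n ≤ 10 and there are no ties. At very unbalanced tiny splits
  (n1 = 1–2) the exact two-sided p moves in steps of ~1/6, so *no*
  continuous approximation tracks it closely; the measured worst-case
  |approx − exact| over all splits with n1+n2 ≤ 12 is ≈ 0.13. This is a
  property of the approximation itself, and is why `auto` defers to
  enumeration at small n.
* **Hypergeometric tail** — upper tail summed in log-space (gammaln +
  logsumexp); agrees with direct mass summation to < 10⁻¹³ over every
  configuration with N ≤ 30.
* **ΔΔCt** — ΔCt = Ct_target − Ct_reference, ΔΔCt subtracts the
  control-group mean ΔCt, fold = 2^−ΔΔCt; the control-group geometric
  mean fold is 1 by construction.

## Network construction

Correlation is computed over all gene pairs after dropping
constant-expression genes (their r is undefined); BH runs jointly over
all computed pairs, and retention requires |r| > 0.7 **and** q < 0.05,
both strict. The common network keeps only the endpoints of edges
surviving the PPI intersection — isolated nodes are not retained (the
motivating study reports more nodes than edges for its common network,
which implies a different isolated-node convention; no quantity here
depends on that choice). Filtering is threshold-monotone by construction.

One subtlety the tests acknowledge: sample correlation is scale-invariant,
so shrinking the noise σ does not drive *between*-module correlations to
zero — a rare chance correlation among background genes can pass the
filter even in the "noise-free" limit. Recovery claims are therefore
statistical (mean Jaccard over seeds), not set equalities.

## Neighbor dissection

Cores are the nodes whose category is in the requested set (default PD +
immune-PD); neighbors are non-core nodes adjacent to a core; the edge set
keeps every parent edge with a core endpoint. Each edge contributes its
(signed) r exactly once to the category of its non-core endpoint;
core–core edges go to the category of the second endpoint in canonical
order — a fixed tie-break so that group sizes always sum to the edge
count. Pairwise Wilcoxon tests across categories are BH-corrected as a
family; |r| comparison is available behind a flag.

## Module detection

MCL on the adjacency matrix with unit self-loops: column-normalise,
then alternate expansion (matrix square) and inflation (elementwise power
2.0, renormalise), pruning entries below 10⁻⁶ (always keeping each
column's maximum) until the matrix changes by < 10⁻⁸. Clusters are the
connected components of the limit's non-zero structure — a deterministic,
node-order-independent partition. The **functional score** ranking
modules is this package's own definition: core-gene count × edge density
(the term has no standard definition); it is monotone in core count at
fixed density, and ties break by size then lexicographic first member.
The core threshold (≥ 6) is exposed as `min_core`.

## Consensus classification

For each K, samples are subsampled at 80% for 1000 resamples (100 in the
desk-scale studies, per the acceptance protocol) and clustered by the
inner method; consensus(i,j) = co-cluster count / co-sample count; the
final per-K assignment hierarchically clusters 1 − consensus (average
linkage). The CDF area uses the Monti step sum
A = Σ(x_i − x_{i−1})·F(x_{i−1}) — the exact integral of the step CDF, so
a degenerate all-ones matrix has area 0 (a trapezoid rule would give 0.5
there). Delta-area is (A_K − A_{K−1})/A_{K−1} with A_min for the first K;
the reported `chosen_k` is the smallest K whose next delta falls below
0.1, and is reported rather than hard-coded because the delta-area
criterion is conservative on gradually separating data.

Two inner clusterers are provided. Hierarchical average linkage on
1 − Pearson (the referenced tool's convention) is the default, but it
partially cancels mean-shift group structure: the component of a shift
common to all genes is invisible to correlation distance, and per-sample
module factors add heavy-tailed noise to sample correlations. The
classification-power study therefore uses the Euclidean k-means inner
option, under conditions fixed ahead of the acceptance runs by a
separation analysis: 10 modules × 10 genes, β = 1 (within-module
r = 0.5), δ = 2 on half the modules, 15/15 samples per cohort. Under
these conditions the external-cohort ARI against the true groups averages
≈ 0.9 over 20 seed pairs, and ≈ 0 under the δ = 0 null (50 seeds).

## ssGSEA infiltration

Per sample, genes are walked in descending expression order (ties broken
by gene symbol); rank weights are bottom-up mid-ranks raised to α = 0.25
(the top gene weighs N^α), and

    ES = Σ_i ( P_in(i) − P_out(i) ),

with P_in the normalised cumulative weight of in-set genes and P_out the
uniform cumulative count of out-of-set genes. Scores depend on ranks
only — any strictly increasing transform of a sample's values leaves them
unchanged — and α = 0 reduces P_in to the unweighted in-set CDF.
Optional normalisation divides the whole matrix by its global range,
preserving all orderings. Differential infiltration is Wilcoxon per set
with BH across sets; gene/cell correlations are Pearson with significance
tiers at p < 0.05 and p < 0.01 (Spearman-vs-Pearson is not configurable;
rank-transform the input if Spearman is wanted).

ssGSEA is **compositional**: scores are functions of within-sample ranks,
so strongly shifting one block of genes displaces every other gene's rank
coherently across the shifted group. In the power study (24 disjoint
20-gene sets in a 2000-gene universe, 4 sets shifted by 2σ, 15/15
samples) all shifted sets are flagged at q < 0.05 in every seed, but
roughly half a stray null set per seed is flagged too — a real property
of the method, not a calibration error. Calibration proper is measured
under the no-shift null, where the raw p < 0.05 rate is ≈ 0.05.

## Over-representation

Hypergeometric upper tail per term against an explicit, user-supplied
universe (the background universe is required input — term counts from
the motivating study depend on database snapshots and are not
reproduced). BH runs within each namespace (BP/CC/MF/pathway) separately;
retention needs p < 0.05 strictly and overlap ≥ 2 (`min_overlap`,
interpreting a p-and-count filter). A query that covers most of the
universe cannot be enriched in anything (tail saturation) — the analysis
drivers therefore test modules individually.

## Problem sizes and determinism

The seeded studies use 20 seeds for network/module recovery and
classification power, 50 for the classification null and infiltration
power, and 25 for infiltration calibration; enumerations are exhaustive
(all rank splits with n1+n2 ≤ 12; all hypergeometric configurations with
N ≤ 30; all 720 permutations at N = 6). Every random draw descends from a
single SeedSequence, and the pipeline manifest records input hashes,
parameters and the seed so reruns are byte-identical.

## Known limitations

* The model plants coherent single-factor modules; overlapping modules,
  correlated factors and hub structure are not represented.
* Correlation-distance consensus clustering is unreliable for pure
  mean-shift class structure (see above); on real data, gene-wise
  standardisation or the k-means inner is advisable.
* The paper-scale counts of the motivating study (e.g. its common-network
  node/edge counts) depend on frozen external databases and a web
  clustering service with an unpublished algorithm and score; they are
  out of scope here, and the module ranking score is intentionally our
  own documented definition.
* ssGSEA's compositionality means "differential infiltration" of one cell
  type can induce apparent opposite shifts elsewhere; interpret stray
  flags accordingly.
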