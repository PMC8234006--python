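# Methods

This note documents the models, defaults and design decisions behind
`bfcorr`: what each stage assumes, what the synthetic-data generator does
and does not emulate, and the numerical choices a maintainer would want
spelled out.

## Preprocessing

Counts are normalized to transcripts per million: per sample,
`rate_g = count_g / (length_g/1000)` and `TPM_g = rate_g / Σ rate · 1e6`,
so every column with any signal sums to 1e6 exactly (all-zero columns are
left at zero rather than producing NaNs). Gene lengths come from the
annotation table; a missing length is an error naming the gene.

Multiple sources are merged on the intersection of their gene sets (gene
order follows the first matrix; sample-ID collisions are rejected). Genes
detected (value strictly greater than zero) in less than 25% of biofluid
samples are then excluded; the boundary is inclusive-keep, i.e. a gene
detected in exactly 25% of samples survives, because the exclusion rule
is strictly "less than". "Detected" means nonzero exactly — no
expression floor is applied.

Downstream statistics operate on log2(TPM+1). The pseudocount of 1 is the
field default and keeps zeros at zero; the log scale makes batch offsets
additive and stabilizes the mean–variance relation for the averaging
steps (Spearman statistics are per-vector rank-invariant, but means over
samples are not).

Batch correction fits, per gene, the least-squares linear model
`expression ~ fluid-type + batch`, with the batch factor coded with
sum-to-zero contrasts, and subtracts only the fitted batch component, so
fluid-type differences and residual structure are preserved. The
operation is a projection (applying it twice changes nothing beyond
1e-9). If the batch factor is confounded with the preserved factor (the
design matrix cannot separate them — e.g. every batch contains exactly
one fluid type), the batch term is dropped with a warning and the matrix
is returned unchanged; identifiability requires the fluid/batch
incidence graph to be connected, which real multi-source designs
typically satisfy because one repository contributes several fluids.

Biotype partition collapses annotation strings onto three classes:
`protein_coding → mRNA`; `lncRNA`, `lincRNA`, `antisense → lncRNA`;
everything else → `other` (excluded from both partitions).

## BTSI and the randomization label

The similarity index is the Spearman rank correlation, implemented as the
Pearson correlation of mid-ranks (average ranks for ties) with the
two-sided t approximation `t = ρ·√((n−2)/(1−ρ²))` on `n−2` df; a
degenerate `ρ = ±1` is reported with p = 0, and constant input vectors
are an error rather than a silent NaN. A vectorized variant ranks every
column of a matrix once and computes all correlations against a reference
vector in one pass; this is what makes the randomization procedures cheap.

The intended-correlation label asks whether a fluid's affinity for a
specific tissue exceeds its affinity for arbitrary tissue samples. The
comparison unit is the population of per-tissue-sample correlations
against the fluid type's mean vector; the null draws `n_random` samples
from the pooled panel (the target tissue's samples included) without
replacement within a repeat and independently across repeats. Welch's
unequal-variance t-test compares the two arms; the label requires the
pair-level Spearman p below alpha, a higher mean than the null in every
repeat, and a significant t-test in every repeat (defaults 1000 draws, 10
repeats, alpha 0.05). A tissue with fewer than two samples is
`not_evaluated`. Per-pair alpha is applied without multiple-testing
correction, mirroring the analysis design this implements;
Benjamini–Hochberg q-values are reported as an additional column. The
conjunction over repeats makes the empirical type-I rate far below alpha
(the acceptance suite measures ≤ 6% on 200 null pairs at alpha = 0.05,
and the observed rate is typically 1–3%).

## Stratified contrasts

The Welch t-test is implemented directly (Welch–Satterthwaite df); two
identical constant groups give t = 0, p = 1 by convention. The
mRNA/lncRNA contrast compares per-sample BTSI populations computed on the
two gene partitions. For the expression-matched variant, the k = 50
highest-expressed lncRNAs (mean expression > 0 over the fluid's samples)
are each greedily paired with the unused mRNA of closest mean expression,
ties broken by gene ID — deterministic given the matrix. An optional
minimum-mean-expression threshold is exposed (`min_mean`, default off)
for callers who want an explicit expression floor.

Sex stratification builds three per-sample BTSI populations per fluid —
F~F (female fluid samples vs the female-tissue mean vector), M~M, and
F~M (both cross pairings pooled) — and reports the three pairwise Welch
tests plus a pooled same-sex vs cross-sex test, which is the single
detection statistic used in the power analyses. A sex missing from either
compartment (fewer than two samples) renders the contrast not evaluated.

The depth regression is ordinary least squares of per-sample BTSI
(against the all-tissue mean vector, the same reference as the overall
index) on the per-sample non-zero gene count.

## Variability ranking and enrichment

Per-gene mean and variance are computed on log2(TPM+1). A LOESS fit —
tricube-weighted local polynomial regression, degree 2, span 0.3, sliding
window of the nearest `ceil(span·n)` points — of log10 variance on log10
mean over genes with positive mean and variance predicts each gene's
expected variance; the prediction is interpolated for genes off the
fitted support. Standardized variance is the variance of the per-sample
values centered by the gene mean and scaled by √expected-variance, with
standardized values clipped at ±√n_samples before the final variance (the
clip tames single-sample outliers). Constant genes score zero. The top-k
genes by standardized variance (descending, ties by gene ID) are HVGs and
the bottom-k LVGs; classes are disjoint and `2k ≤ n_genes` is enforced.
The LOESS is written in-package because no installed library provides a
degree-2 local polynomial smoother; span and degree are exposed.

Over-representation uses the exact hypergeometric upper tail
`P(X ≥ overlap)` with the analysis universe (the filtered merged gene
set, not the whole annotation) as background, and Benjamini–Hochberg
q-values across the collection. Gene sets are read from GMT text; sets
are restricted to the universe and empty sets dropped.

## Deconvolution

The reference panel reduces each tissue to marker genes: per tissue,
genes ranked by the specificity margin (mean log expression in the tissue
minus the maximum mean over all other tissues), keeping the top
`n_per_tissue = 100` (default) with strictly positive margin. A positive
margin is possible for at most one tissue per gene, so marker lists are
disjoint by construction; a tissue with no positive-margin gene (e.g. a
duplicated profile) is an error. Margins are computed on the log scale
(specificity), while the mixture model operates on the linear scale
(bulk mixing is additive in abundance): the estimator solves
`min‖y − Xp‖²` over the probability simplex, where X holds linear-scale
per-tissue means on the marker union and y the fluid's linear-scale mean
vector. The solver augments the system with a sum-to-one row weighted
1e4 relative to the unit-rescaled data, solves with Lawson–Hanson NNLS
(deterministic, active-set), and renormalizes, making the simplex
constraint exact to 1e-9 and noise-free mixtures exact to machine
precision.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, not any real
dataset's distributions.

*Tissue panel.* Each gene has a baseline log2 abundance ~ N(3, 1.5)
(lncRNAs shifted −1.5: lower expressed); a configurable fraction
(default 10%) are tissue-specific markers, elevated by 4 log2 units in
exactly one tissue. Samples are lognormal perturbations (within-tissue
log2 sd 0.25) of the tissue profile, converted to integer counts with a
length-proportional rate (lengths log-uniform on [500, 10000] nt), so TPM
normalization has real work to undo. Tissue donors carry a sex label.

*Biofluids.* Each fluid sample's latent expression is a convex
combination `Σ w_t · (mean tissue-t count profile)` on the linear scale
(deconvolution of bulk mixtures is linear in abundance), followed in
order by: multiplicative lognormal noise with the configured CV (default
0.3); dropout zeroing with baseline rate 0.3 jittered per sample by
±0.15 (sequencing depth varies across samples — this heterogeneity is
what gives the depth regression its signal), lncRNA detection scaled by a
penalty (default 0.7, i.e. lncRNAs are detected less often); the batch
offset applied multiplicatively (additive on the log scale) — dropout
precedes the offset so zeros stay zeros; and the sex shift for male
donors. Counts are rounded at the end.

*Sex effect.* Sex-dimorphic genes (a random subset excluding markers)
are parameterized with the female level as the latent base — the mixture
rows for these genes use female panel samples only — and male donors
apply the full shift (default 3 log2 units ≈ 8-fold, the near-binary
regime of X-inactivation- and Y-linked genes, which dominate real sex-
dimorphic expression). A pooled-sex base would place both sexes
equidistant from their same-sex references and erase the very signal the
sex contrast measures.

*Planted HVGs.* After sample generation, each planted gene's realized
log2-scale deviations (nonzero entries; zeros stay zeros) are amplified
so its variance is multiplied by `hvg_variance_multiplier` (default 8).
The per-sample swing is bounded at min(2.5 sd, 4 log2 units): compositional
data cannot absorb unbounded tails — a single gene taking over a sample's
library would shift every other gene's TPM in that sample and leak the
plant into all genes' variances. Plants are drawn from genes above the
40th percentile of baseline expression, since an undetectable gene
cannot carry a variability signal.

*Study-scale configuration.* `study_config()` mirrors the emulated study
design: 53 tissues, five fluids totalling 444 samples (blood 150, urine
70 with 36F/34M, saliva 70, bile 43, stool 111 with 45F/66M), multiple
batched sources with log2 offsets in [−0.3, 0.4], and one source spanning
several fluids so the fluid/batch graph is connected and the batch term
estimable. Each fluid mixes one dominant tissue (weight 0.6) with a
secondary tissue (0.2) and a uniform remainder.

*What the generator does not emulate* — real GTEx expression
distributions, GC and positional bias, isoform structure, correlated
gene modules, or library-preparation chemistry differences between RNA
fractions. Passing tests therefore demonstrate that the statistics
recover planted structure under the stated generative assumptions, not
that those assumptions hold for any particular real dataset.

## Problem sizes and numerical choices

The test suite and the acceptance script use deliberately desk-sized
problems chosen once as part of the experimental design: calibration of
the intended label on 200 null pairs (2000 genes, 200 random draws, 10
repeats); origin recovery and labeling over 100 replicates (1000 genes,
6 tissues, dominant weight 0.7, CV 0.2); biotype and depth mechanisms
over 50 replicates; sex power and null over 100 replicates each (70
fluid samples, the study's urine scale); HVG recovery at 2000 genes / 40
samples; deconvolution recovery over 100 replicates at CV 0.1. The
acceptance script runs the full pipeline at 4000 genes × 53 tissues ×
444 fluid samples with 200 random draws per labeling repeat.

Determinism: every stochastic component takes an explicit seed;
independent streams are derived via seed sequences, so panel and fluid
draws, per-pair randomization streams and replicate fixtures are all
reproducible bit-for-bit. Tie-breaks (HVG ranking, marker ranking,
expression matching) are lexicographic on gene ID. Degenerate inputs
(constant vectors, all-zero columns, single batches, missing sexes,
tissues with one sample) are either defined conventions or named errors,
as listed per function.

## Known limitations

- The intended-correlation label is conservative by construction (a
  conjunction over repeats); its effective type-I rate is well below the
  nominal alpha, so absence of the label is weak evidence of absence.
- The expression-matched subset uses greedy nearest-neighbor rank
  matching; it minimizes the pairwise gap locally, not any global
  distribution distance.
- Marker-based deconvolution assumes the reference tissues span the
  mixture; RNA from cell types absent from the panel is absorbed into
  the closest profiles.
- The LOESS smoother refits at every point (O(n·span·n)); it is sized for
  tens of thousands of genes, not millions of features.
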