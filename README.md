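# bfcorr — biofluid–tissue transcriptome correlation analysis

Biofluids (blood plasma and serum, urine, saliva, bile, stool-derived
fractions) are attractive sources of non-invasive RNA biomarkers, but a
biomarker read from a fluid is only as good as the fluid's agreement with
the tissue it is supposed to report on. `bfcorr` implements a complete,
tested pipeline for quantifying that agreement: from raw count matrices
through normalization and batch correction to similarity statistics,
significance labeling, stratified contrasts, variability ranking and
tissue-of-origin deconvolution. A first-class synthetic-data generator
emulates the assumed structure of biofluid transcriptomes (tissue
mixtures, noise, dropout, batches, donor sex), so every stage of the
analysis is verifiable against planted ground truth without any external
downloads.

## The statistics at the core

**BTSI (biofluid–tissue similarity index).** For a biofluid expression
vector *x* and a tissue expression vector *y* (each usually a mean over
samples, on the log2(TPM+1) scale),

    BTSI(x, y) = ρ_S(x, y)

the Spearman rank correlation (Pearson correlation of mid-ranks; p-value
from the t approximation *t = ρ·√((n−2)/(1−ρ²))* on *n−2* df). BTSI is
computed at three granularities: fluid type vs the pooled tissue panel,
fluid type vs each tissue type, and per fluid sample.

**Intended-correlation labeling.** A fluid–tissue pair is an *intended
correlation* when the association survives a randomization test: with
*B* = {BTSI(fluid mean, tissue sample *s*)} over the target tissue's
samples, and *N_r* the same statistic over *A* tissue-panel samples drawn
at random (without replacement, independently for each of *R* repeats),
the pair is labeled intended iff the pair-level Spearman *p* < α,
mean(*B*) > mean(*N_r*) in every repeat, and Welch's t-test of *B* vs
*N_r* gives *p* < α in every repeat (defaults A = 1000, R = 10, α = 0.05).

**Stratified contrasts.** Welch t-tests compare per-sample BTSI
populations between mRNA and lncRNA gene sets (optionally on
expression-matched 50+50 gene subsets), and between same-sex and
cross-sex fluid–tissue pairings; ordinary least squares regresses
per-sample BTSI on the non-zero gene count (a sequencing-depth proxy).

**Variability and enrichment.** Genes are ranked by variance standardized
against a LOESS (tricube-weighted local polynomial) trend of log10
variance on log10 mean, with standardized values clipped at √n; the top
500 by standardized variance are highly variable genes (HVGs), the bottom
500 lowly variable (LVGs). Gene sets (GMT format) are tested for
over-representation with the exact hypergeometric upper tail and
Benjamini–Hochberg correction.

**Deconvolution.** Each fluid's linear-scale mean expression vector *y*
is decomposed against per-tissue reference profiles *X* restricted to
tissue-specific marker genes (largest log-scale specificity margin) by
simplex-constrained least squares

    min_p ‖y − X·p‖²  s.t.  p ≥ 0, Σp = 1

solved with deterministic active-set NNLS on a sum-penalized system.

## Worked example

```python
import bfcorr as b

cfg = b.study_config(n_genes=2000, n_tissues=10, samples_per_tissue=6, seed=0)
bundle = b.simulate_bundle(cfg)   # 10-tissue panel + 444 biofluid samples

tpm_fluid = b.tpm_normalize(bundle.biofluid_matrix, bundle.annotation)
filtered  = b.filter_low_prevalence(tpm_fluid, 0.25)
fluids    = b.remove_batch_effect(b.log_transform(filtered), bundle.metadata)
tissue_tpm = b.tpm_normalize(bundle.tissue_matrix, bundle.annotation)
tissues = b.log_transform(
    b.ExpressionMatrix(tissue_tpm.values.loc[fluids.gene_ids], "tpm"))

print(f"{fluids.shape[0]} genes survive the 25% prevalence filter")
for rec in b.btsi_overall(fluids, tissues, bundle.metadata):
    print(f"BTSI {rec.biofluid:<7s} vs all tissues: "
          f"rho = {rec.rho:.2f} (p = {rec.p_value:.2e})")

est = [e for e in b.deconvolve_all(fluids, tissues, bundle.metadata,
                                   n_per_tissue=30)
       if e.biofluid == "urine"][0]
top = est.proportions.sort_values(ascending=False)
print(f"urine deconvolution: {top.index[0]} {top.iloc[0]:.2f}, "
      f"{top.index[1]} {top.iloc[1]:.2f}")
```

prints

```
1985 genes survive the 25% prevalence filter
BTSI bile    vs all tissues: rho = 0.81 (p = 0.00e+00)
BTSI blood   vs all tissues: rho = 0.85 (p = 0.00e+00)
BTSI saliva  vs all tissues: rho = 0.84 (p = 0.00e+00)
BTSI stool   vs all tissues: rho = 0.85 (p = 0.00e+00)
BTSI urine   vs all tissues: rho = 0.84 (p = 0.00e+00)
urine deconvolution: tissue02 0.41, tissue03 0.21
```

Every fluid correlates strongly and positively with the pooled tissue
panel, and urine's estimated composition is led by its true dominant
mixture tissue (tissue02, planted weight 0.6) followed by its true
secondary tissue — the qualitative behavior the pipeline is built to
measure. The same stages are available from the shell via the `bfcorr`
CLI (`simulate`, `preprocess`, `btsi`, `compare`, `variability`,
`enrich`, `deconvolve`); see `bfcorr --help`.

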