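"""Synthetic tissue panels and biofluid samples for pipeline testing.

The generator produces count matrices with the statistical structure the
downstream analysis assumes: a tissue reference panel with tissue-specific
marker genes, and biofluid samples built as convex mixtures of tissue
profiles subject to multiplicative lognormal noise, dropout (with a reduced
detection rate for lncRNAs), batch-specific offsets on the log scale, and a
sex-dimorphic expression shift.  Ground truth (mixing weights, planted
highly-variable genes, sex-dimorphic genes, tissue markers) is recorded so
recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import (
    COUNTS,
    ExpressionMatrix,
    InputError,
    write_annotation,
    write_matrix,
    write_metadata,
)


class ConfigurationError(ValueError):
    """An invalid simulation configuration, naming the offending field."""


@dataclass
class BiofluidSpec:
    """One biofluid type: sample count, tissue mixing weights, batch, sex mix."""

    name: str
    n_samples: int
    tissue_weights: np.ndarray
    batch: str = "batch0"
    sex_ratio: float = 0.5  # fraction of male donors

    def __post_init__(self) -> None:
        self.tissue_weights = np.asarray(self.tissue_weights, dtype=float)
        if self.n_samples <= 0:
            raise ConfigurationError(f"biofluid {self.name!r}: n_samples must be > 0")
        if (self.tissue_weights < 0).any():
            raise ConfigurationError(f"biofluid {self.name!r}: negative tissue weight")
        if abs(self.tissue_weights.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"biofluid {self.name!r}: tissue_weights must sum to 1 "
                f"(got {self.tissue_weights.sum():.12g})"
            )
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError(f"biofluid {self.name!r}: sex_ratio outside [0,1]")


@dataclass
class SexEffect:
    """Sex-dimorphic expression: n genes shifted by log2_shift in male donors."""

    n_sex_genes: int = 0
    log2_shift: float = 0.0


@dataclass
class SimulationConfig:
    """Knobs of the generative model; identical config + seed gives identical output."""

    n_genes: int = 5000
    n_tissues: int = 53
    samples_per_tissue: int = 8
    biofluid_specs: list[BiofluidSpec] = field(default_factory=list)
    frac_lncRNA: float = 0.22
    lncRNA_detection_penalty: float = 0.7
    noise_cv: float = 0.3
    dropout_rate: float = 0.3
    dropout_heterogeneity: float = 0.15  # half-width of per-sample dropout jitter
    batch_offsets: dict[str, float] = field(default_factory=dict)
    sex_effect: SexEffect = field(default_factory=SexEffect)
    marker_fraction: float = 0.1
    marker_log2_boost: float = 4.0
    tissue_sample_sd: float = 0.25  # within-tissue log2 spread
    n_planted_hvg: int = 0
    hvg_variance_multiplier: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tissues", "samples_per_tissue"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0.0 <= self.frac_lncRNA <= 1.0:
            raise ConfigurationError("frac_lncRNA outside [0,1]")
        if not 0.0 < self.lncRNA_detection_penalty <= 1.0:
            raise ConfigurationError("lncRNA_detection_penalty outside (0,1]")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate outside [0,1)")
        if self.dropout_heterogeneity < 0:
            raise ConfigurationError("dropout_heterogeneity must be >= 0")
        if not 0.0 <= self.marker_fraction <= 1.0:
            raise ConfigurationError("marker_fraction outside [0,1]")
        if self.n_planted_hvg < 0:
            raise ConfigurationError("n_planted_hvg must be >= 0")
        if self.n_planted_hvg > 0 and self.hvg_variance_multiplier <= 1.0:
            raise ConfigurationError("hvg_variance_multiplier must be > 1")
        for spec in self.biofluid_specs:
            if len(spec.tissue_weights) != self.n_tissues:
                raise ConfigurationError(
                    f"biofluid {spec.name!r}: tissue_weights length "
                    f"{len(spec.tissue_weights)} != n_tissues {self.n_tissues}"
                )


@dataclass
class TissuePanel:
    """A simulated reference panel with its annotation, metadata and truth."""

    matrix: ExpressionMatrix  # counts, genes x samples
    annotation: pd.DataFrame
    metadata: pd.DataFrame
    markers: dict[str, list[str]]  # tissue -> marker gene IDs
    sex_genes: list[str]
    hvg_genes: list[str]


@dataclass
class FixtureBundle:
    """Everything one simulation run produced, plus its ground truth."""

    tissue_matrix: ExpressionMatrix
    biofluid_matrix: ExpressionMatrix
    annotation: pd.DataFrame
    metadata: pd.DataFrame  # tissue + biofluid samples combined
    truth: dict


def tissue_name(t: int) -> str:
    return f"tissue{t:02d}"


def _rng_for(config: SimulationConfig, stream: int) -> np.random.Generator:
    # separate deterministic streams so panel and fluids can be drawn
    # independently from the same config seed
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def simulate_tissue_panel(config: SimulationConfig) -> TissuePanel:
    """Draw a tissue reference panel of counts.

    Each tissue gets a latent log2 profile (shared baseline plus a
    marker-gene boost confined to that tissue); samples are lognormal
    perturbations of the latent profile converted to integer counts via a
    length-dependent rate, so TPM normalization has real work to undo.
    Tissue donors carry a sex label and male donors receive the configured
    shift on the sex-dimorphic genes.
    """
    rng = _rng_for(config, 0)
    G, T, S = config.n_genes, config.n_tissues, config.samples_per_tissue
    gene_ids = [f"G{i:05d}" for i in range(G)]
    lengths = np.round(np.exp(rng.uniform(np.log(500), np.log(10000), G))).astype(int)

    n_lnc = int(round(config.frac_lncRNA * G))
    lnc_idx = rng.choice(G, size=n_lnc, replace=False)
    biotype = np.array(["mRNA"] * G, dtype=object)
    biotype[lnc_idx] = "lncRNA"

    baseline = rng.normal(3.0, 1.5, G)
    baseline[lnc_idx] -= 1.5  # lncRNAs sit lower on the expression scale

    n_markers = int(round(config.marker_fraction * G))
    marker_idx = rng.choice(G, size=n_markers, replace=False)
    marker_tissue = rng.integers(0, T, size=n_markers)
    markers: dict[str, list[str]] = {tissue_name(t): [] for t in range(T)}
    mu = np.tile(baseline, (T, 1))  # tissues x genes, latent log2 profiles
    for g, t in zip(marker_idx, marker_tissue):
        mu[t, g] += config.marker_log2_boost
        markers[tissue_name(t)].append(gene_ids[g])

    non_marker = np.setdiff1d(np.arange(G), marker_idx)
    n_sex = min(config.sex_effect.n_sex_genes, len(non_marker))
    sex_idx = rng.choice(non_marker, size=n_sex, replace=False) if n_sex else np.array([], int)
    free = np.setdiff1d(non_marker, sex_idx)
    # a variability plant needs detectable expression to carry it, so avoid
    # the weakly-expressed tail when drawing planted HVGs
    detectable = free[baseline[free] >= np.quantile(baseline, 0.4)]
    pool = detectable if len(detectable) else free
    n_hvg = min(config.n_planted_hvg, len(pool))
    hvg_idx = rng.choice(pool, size=n_hvg, replace=False) if n_hvg else np.array([], int)

    cols, sample_ids, groups, sexes = [], [], [], []
    for t in range(T):
        for s in range(S):
            sex = "male" if rng.random() < 0.5 else "female"
            z = mu[t] + rng.normal(0.0, config.tissue_sample_sd, G)
            if sex == "male" and len(sex_idx):
                z[sex_idx] += config.sex_effect.log2_shift
            abundance = np.exp2(z)
            cols.append(np.rint(abundance * lengths / 1000.0))
            sample_ids.append(f"{tissue_name(t)}_s{s:02d}")
            groups.append(tissue_name(t))
            sexes.append(sex)

    values = pd.DataFrame(np.column_stack(cols), index=gene_ids, columns=sample_ids)
    annotation = pd.DataFrame(
        {"biotype": biotype, "length_nt": lengths}, index=pd.Index(gene_ids, name="gene_id")
    )
    metadata = pd.DataFrame(
        {
            "compartment": "tissue",
            "group": groups,
            "batch": "panel",
            "sex": sexes,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return TissuePanel(
        matrix=ExpressionMatrix(values, COUNTS),
        annotation=annotation,
        metadata=metadata,
        markers=markers,
        sex_genes=[gene_ids[g] for g in sex_idx],
        hvg_genes=[gene_ids[g] for g in hvg_idx],
    )


def simulate_biofluids(
    config: SimulationConfig, panel: TissuePanel
) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Draw biofluid samples as noisy mixtures of the panel's tissue profiles.

    Per sample: latent expression = sum_t w_t * (mean tissue-t count profile,
    linear scale), then multiplicative lognormal noise with the configured
    CV (planted HVGs get a variance-inflated CV), then dropout zeroing
    (lncRNA detection scaled by the penalty), then the batch offset on the
    log scale, then the sex shift for male donors, then rounding to counts.
    Dropout precedes the batch offset so zeros stay zeros.
    """
    if not config.biofluid_specs:
        raise ConfigurationError("biofluid_specs is empty")
    if not panel.matrix.gene_ids.equals(panel.annotation.index):
        raise InputError("panel matrix and annotation gene universes differ")
    rng = _rng_for(config, 1)
    G = config.n_genes
    gene_ids = panel.matrix.gene_ids
    if len(gene_ids) != G:
        raise InputError("panel gene universe does not match the configuration")

    tissue_means = panel.matrix.values.T.groupby(panel.metadata["group"]).mean().T
    tissue_order = [tissue_name(t) for t in range(config.n_tissues)]
    profiles = tissue_means[tissue_order].to_numpy()  # genes x tissues

    # The latent level of sex-dimorphic genes is the female level; male
    # donors apply the full shift.  Pooled-sex tissue means would park these
    # genes halfway between the sexes, so recompute their rows from female
    # panel samples only (falling back to the pooled mean if a tissue has
    # no female samples).
    if panel.sex_genes:
        female_cols = panel.metadata.index[panel.metadata["sex"] == "female"]
        fvals = panel.matrix.values[list(female_cols)]
        fmeta = panel.metadata.loc[female_cols, "group"]
        fmeans = fvals.T.groupby(fmeta).mean().T
        sex_rows = panel.matrix.gene_ids.get_indexer(panel.sex_genes)
        for j, t in enumerate(tissue_order):
            if t in fmeans.columns:
                profiles[sex_rows, j] = fmeans[t].to_numpy()[sex_rows]

    is_lnc = (panel.annotation["biotype"] == "lncRNA").to_numpy()
    sex_pos = gene_ids.get_indexer(panel.sex_genes)
    hvg_pos = gene_ids.get_indexer(panel.hvg_genes)

    sigma = np.sqrt(np.log1p(config.noise_cv**2))

    cols, sample_ids, groups, batches, sexes = [], [], [], [], []
    truth_fluids = {}
    for spec in config.biofluid_specs:
        base = profiles @ spec.tissue_weights
        if spec.name in truth_fluids:  # one fluid type drawn from several sources
            truth_fluids[spec.name]["batches"].append(spec.batch)
        else:
            truth_fluids[spec.name] = {
                "tissue_weights": dict(zip(tissue_order, spec.tissue_weights.tolist())),
                "batches": [spec.batch],
            }
        for j in range(spec.n_samples):
            sex = "male" if rng.random() < spec.sex_ratio else "female"
            x = base * np.exp(rng.normal(-0.5 * sigma**2, sigma, G))

            d = config.dropout_rate
            if config.dropout_heterogeneity > 0:
                d = float(np.clip(
                    d + rng.uniform(-config.dropout_heterogeneity, config.dropout_heterogeneity),
                    0.0, 0.95,
                ))
            p_zero = np.where(is_lnc, 1.0 - (1.0 - d) * config.lncRNA_detection_penalty, d)
            x = np.where(rng.random(G) < p_zero, 0.0, x)

            offset = config.batch_offsets.get(spec.batch, 0.0)
            if offset:
                x = x * 2.0**offset
            if sex == "male" and len(sex_pos):
                x[sex_pos] = x[sex_pos] * 2.0**config.sex_effect.log2_shift

            cols.append(np.rint(x))
            sample_ids.append(f"{spec.name}_{spec.batch}_s{j:03d}")
            groups.append(spec.name)
            batches.append(spec.batch)
            sexes.append(sex)

    values = pd.DataFrame(np.column_stack(cols), index=gene_ids, columns=sample_ids)

    # Plant highly variable genes: amplify each planted gene's realized
    # sample-to-sample variability on the log2 scale until its variance is
    # multiplied by hvg_variance_multiplier.  The extra spread goes into the
    # detected (nonzero) entries -- zeros stay zeros -- emulating genes whose
    # expression genuinely differs across biofluid samples.
    if len(hvg_pos) and config.hvg_variance_multiplier > 1.0:
        M = config.hvg_variance_multiplier
        for g in hvg_pos:
            row = values.iloc[g].to_numpy()
            nz = row > 0
            if nz.sum() < 2:
                continue
            y = np.log2(row + 1.0)
            v = y.var(ddof=1)
            if v <= 0:
                continue
            extra_sd = np.sqrt((M - 1.0) * v / (nz.sum() / len(row)))
            noise = rng.normal(0.0, extra_sd, nz.sum())
            # bound the per-sample swing so no single gene can dominate a
            # library (unbounded lognormal tails would distort every other
            # gene's TPM in that sample)
            bound = min(2.5 * extra_sd, 4.0)
            y[nz] = y[nz] + np.clip(noise, -bound, bound)
            values.iloc[g] = np.rint(np.maximum(np.exp2(y) - 1.0, 0.0))

    metadata = pd.DataFrame(
        {
            "compartment": "biofluid",
            "group": groups,
            "batch": batches,
            "sex": sexes,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = {
        "biofluids": truth_fluids,
        "planted_hvg": panel.hvg_genes,
        "planted_lvg": [],
        "sex_genes": panel.sex_genes,
        "markers": panel.markers,
    }
    return ExpressionMatrix(values, COUNTS), metadata, truth


def simulate_bundle(config: SimulationConfig) -> FixtureBundle:
    """Run the full generator: tissue panel, biofluids, combined metadata."""
    panel = simulate_tissue_panel(config)
    fluid_matrix, fluid_meta, truth = simulate_biofluids(config, panel)
    metadata = pd.concat([panel.metadata, fluid_meta])
    return FixtureBundle(
        tissue_matrix=panel.matrix,
        biofluid_matrix=fluid_matrix,
        annotation=panel.annotation,
        metadata=metadata,
        truth=truth,
    )


def write_fixtures(bundle: FixtureBundle, out_dir) -> dict[str, Path]:
    """Write the bundle as TSVs plus a truth JSON; round-trips bit-exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tissue_counts": out / "tissue_counts.tsv",
        "biofluid_counts": out / "biofluid_counts.tsv",
        "annotation": out / "annotation.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.json",
    }
    write_matrix(bundle.tissue_matrix, paths["tissue_counts"])
    write_matrix(bundle.biofluid_matrix, paths["biofluid_counts"])
    write_annotation(bundle.annotation, paths["annotation"])
    write_metadata(bundle.metadata, paths["metadata"])
    paths["truth"].write_text(json.dumps(bundle.truth, indent=1))
    return paths


def study_biofluid_specs(n_tissues: int) -> list[BiofluidSpec]:
    """Five biofluid types at the study's scale (444 samples total).

    Each fluid is dominated by one tissue (weight 0.6) with a secondary
    tissue (0.2) and the remainder spread uniformly; urine and stool carry
    the study's sex composition (36F/34M and 45F/66M).  Several fluids are
    split across two sources and one source spans several fluids, so the
    fluid-batch incidence graph is connected and the batch term of the
    correction model is estimable alongside the fluid-type factor.
    """

    def weights(dominant: int, secondary: int) -> np.ndarray:
        w = np.full(n_tissues, 0.2 / max(n_tissues - 2, 1))
        w[dominant] = 0.6
        w[secondary] = 0.2
        return w / w.sum()

    specs = [
        ("blood", 75, 0, 1, "geo_blood", 0.5),
        ("blood", 75, 0, 1, "exrna_atlas", 0.5),
        ("urine", 70, 2 % n_tissues, 3 % n_tissues, "exrna_atlas", 34 / 70),
        ("saliva", 35, 4 % n_tissues, 0, "geo_saliva", 0.5),
        ("saliva", 35, 4 % n_tissues, 0, "exrna_atlas", 0.5),
        ("bile", 43, 1 % n_tissues, 2 % n_tissues, "exrna_atlas", 0.5),
        ("stool", 66, 3 % n_tissues, 4 % n_tissues, "geo_stool", 66 / 111),
        ("stool", 45, 3 % n_tissues, 4 % n_tissues, "exrna_atlas", 66 / 111),
    ]
    return [
        BiofluidSpec(name, n, weights(d, s), batch, ratio)
        for name, n, d, s, batch, ratio in specs
    ]


def study_config(
    n_genes: int = 5000,
    n_tissues: int = 53,
    samples_per_tissue: int = 8,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """A configuration emulating the study's design: 5 biofluid types,
    444 biofluid samples, distinct batches per source, sex-dimorphic genes."""
    defaults = dict(
        n_genes=n_genes,
        n_tissues=n_tissues,
        samples_per_tissue=samples_per_tissue,
        biofluid_specs=study_biofluid_specs(n_tissues),
        batch_offsets={
            "geo_blood": 0.4,
            "exrna_atlas": -0.3,
            "geo_saliva": 0.2,
            "geo_stool": 0.3,
        },
        sex_effect=SexEffect(n_sex_genes=max(1, n_genes // 10), log2_shift=3.0),
        n_planted_hvg=max(1, n_genes // 20),
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
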