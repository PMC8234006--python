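"""The biofluid-tissue similarity index (BTSI) and intended-correlation labeling.

BTSI is the Spearman rank correlation between a biofluid expression vector
and a tissue expression vector (each usually a mean over samples).  A
biofluid-tissue pair is labeled an *intended correlation* when its BTSI is
significant and the per-tissue-sample BTSIs beat those of randomized draws
from the whole tissue panel in every one of a series of repeated t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_preprocess import ExpressionMatrix, InputError


class CorrelationError(ValueError):
    """Spearman correlation is undefined (constant input)."""


@dataclass
class BtsiRecord:
    biofluid: str
    tissue: str  # "ALL" for the pooled tissue panel
    rho: float
    p_value: float
    n_genes: int
    label: str = "not_evaluated"  # intended | not_intended | not_evaluated


@dataclass
class RandomizationConfig:
    """Randomized-panel null: A draws per repeat, repeated n_repeats times."""

    n_random: int = 1000
    n_repeats: int = 10
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random < 2:
            raise InputError("n_random must be >= 2")
        if self.n_repeats < 1:
            raise InputError("n_repeats must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise InputError("alpha must be in (0,1)")


def _check_vector(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise InputError(f"{name} must be one-dimensional")
    if np.ptp(v) == 0:
        raise CorrelationError(f"{name} is constant; Spearman correlation undefined")
    return v


def _p_from_rho(rho: float, n: int) -> float:
    # two-sided p from the t approximation on n-2 df; |rho|=1 reported as 0
    if 1.0 - rho * rho <= 0.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    Returns ``(rho, p)`` where rho is the Pearson correlation of the
    mid-rank vectors and p comes from the two-sided t approximation
    ``t = rho * sqrt((n-2)/(1-rho^2))`` on ``n-2`` degrees of freedom.
    """
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    if len(x) != len(y):
        raise InputError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 3:
        raise InputError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.clip(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)), -1.0, 1.0))
    return rho, _p_from_rho(rho, n)


def spearman_vs_columns(x, M: np.ndarray) -> np.ndarray:
    """Spearman rho of a vector against every column of a matrix (vectorized).

    Columns are ranked independently; constant columns yield NaN.
    """
    x = _check_vector(x, "x")
    rx = stats.rankdata(x)
    rx = rx - rx.mean()
    R = stats.rankdata(M, axis=0)
    R = R - R.mean(axis=0, keepdims=True)
    denom = np.sqrt((rx @ rx) * np.einsum("ij,ij->j", R, R))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ R) / denom
    return np.clip(rho, -1.0, 1.0)


def nonzero_gene_count(matrix: ExpressionMatrix) -> pd.Series:
    """Per-sample number of genes with expression strictly greater than zero."""
    return (matrix.values > 0).sum(axis=0)


# ---------------------------------------------------------------------------
# grouped BTSI
# ---------------------------------------------------------------------------

def _group_columns(matrix: ExpressionMatrix, metadata: pd.DataFrame,
                   compartment: str) -> dict[str, list[str]]:
    missing = matrix.sample_ids.difference(metadata.index)
    if len(missing):
        raise InputError(f"samples missing from metadata: {list(missing[:5])}")
    meta = metadata.loc[matrix.sample_ids]
    meta = meta[meta["compartment"] == compartment]
    return {g: list(sub.index) for g, sub in meta.groupby("group", sort=True)}


def _check_universe(biofluid: ExpressionMatrix, tissue: ExpressionMatrix) -> None:
    if not biofluid.gene_ids.equals(tissue.gene_ids):
        raise InputError("biofluid and tissue matrices must share the gene universe")


def btsi_overall(
    biofluid: ExpressionMatrix, tissue: ExpressionMatrix, metadata: pd.DataFrame
) -> list[BtsiRecord]:
    """BTSI of each biofluid type against the pooled tissue panel.

    The biofluid vector is the mean over that type's samples; the tissue
    vector is the mean over *all* tissue samples (tissue="ALL").
    """
    _check_universe(biofluid, tissue)
    tissue_mean = tissue.values.mean(axis=1).to_numpy()
    records = []
    for fluid, cols in _group_columns(biofluid, metadata, "biofluid").items():
        fluid_mean = biofluid.values[cols].mean(axis=1).to_numpy()
        rho, p = spearman(fluid_mean, tissue_mean)
        records.append(BtsiRecord(fluid, "ALL", rho, p, len(fluid_mean)))
    return records


def btsi_per_tissue(
    biofluid: ExpressionMatrix, tissue: ExpressionMatrix, metadata: pd.DataFrame
) -> list[BtsiRecord]:
    """BTSI for every (biofluid type, tissue type) pair, rankable per fluid."""
    _check_universe(biofluid, tissue)
    tissue_groups = _group_columns(tissue, metadata, "tissue")
    records = []
    for fluid, fcols in _group_columns(biofluid, metadata, "biofluid").items():
        fluid_mean = biofluid.values[fcols].mean(axis=1).to_numpy()
        for tis, tcols in tissue_groups.items():
            tis_mean = tissue.values[tcols].mean(axis=1).to_numpy()
            rho, p = spearman(fluid_mean, tis_mean)
            records.append(BtsiRecord(fluid, tis, rho, p, len(fluid_mean)))
    return records


def label_intended(
    pair: tuple[str, str],
    biofluid: ExpressionMatrix,
    tissue: ExpressionMatrix,
    metadata: pd.DataFrame,
    rc: RandomizationConfig,
) -> BtsiRecord:
    """Label one biofluid-tissue pair by the randomized-panel procedure.

    Let B be the per-sample BTSIs between the biofluid type's mean vector
    and each sample of the target tissue.  For each of ``n_repeats``
    repeats, ``n_random`` tissue-panel samples are drawn without
    replacement (across all tissues, independently across repeats) and the
    null BTSIs N_r are computed the same way; B and N_r are compared with
    Welch's t-test.  The pair is *intended* iff the pair-level Spearman p
    is below alpha, mean(B) > mean(N_r) in every repeat, and every t-test
    p is below alpha.  A target tissue with fewer than 2 samples is
    not_evaluated.
    """
    _check_universe(biofluid, tissue)
    fluid_name, tissue_name = pair
    fluid_groups = _group_columns(biofluid, metadata, "biofluid")
    tissue_groups = _group_columns(tissue, metadata, "tissue")
    if fluid_name not in fluid_groups:
        raise InputError(f"unknown biofluid type {fluid_name!r}")
    if tissue_name not in tissue_groups:
        raise InputError(f"unknown tissue type {tissue_name!r}")
    n_panel = tissue.shape[1]
    if rc.n_random > n_panel:
        raise InputError(
            f"n_random={rc.n_random} exceeds the tissue panel size {n_panel}"
        )

    fluid_mean = biofluid.values[fluid_groups[fluid_name]].mean(axis=1).to_numpy()
    tcols = tissue_groups[tissue_name]
    tis_mean = tissue.values[tcols].mean(axis=1).to_numpy()
    rho, p = spearman(fluid_mean, tis_mean)
    record = BtsiRecord(fluid_name, tissue_name, rho, p, len(fluid_mean))

    if len(tcols) < 2:
        return record

    panel_rho = spearman_vs_columns(fluid_mean, tissue.values.to_numpy())
    col_pos = tissue.sample_ids.get_indexer(tcols)
    B = panel_rho[col_pos]

    rng = np.random.default_rng(rc.seed)
    intended = p < rc.alpha
    for _ in range(rc.n_repeats):
        draw = rng.choice(n_panel, size=rc.n_random, replace=False)
        N_r = panel_rho[draw]
        if not intended:
            continue  # keep consuming the stream for reproducibility
        t_res = stats.ttest_ind(B, N_r, equal_var=False)
        if not (B.mean() > N_r.mean() and t_res.pvalue < rc.alpha):
            intended = False
    record.label = "intended" if intended else "not_intended"
    return record


def label_all_intended(
    biofluid: ExpressionMatrix,
    tissue: ExpressionMatrix,
    metadata: pd.DataFrame,
    rc: RandomizationConfig,
) -> list[BtsiRecord]:
    """Run :func:`label_intended` on the full biofluid x tissue grid.

    Each pair gets an independent, deterministic randomization stream
    derived from ``rc.seed``.
    """
    fluid_groups = _group_columns(biofluid, metadata, "biofluid")
    tissue_groups = _group_columns(tissue, metadata, "tissue")
    records = []
    for i, fluid in enumerate(fluid_groups):
        for j, tis in enumerate(tissue_groups):
            sub = RandomizationConfig(
                n_random=rc.n_random,
                n_repeats=rc.n_repeats,
                alpha=rc.alpha,
                seed=int(np.random.SeedSequence([rc.seed, i, j]).generate_state(1)[0] % (2**31)),
            )
            records.append(label_intended((fluid, tis), biofluid, tissue, metadata, sub))
    return records


def records_to_frame(records: list[BtsiRecord], with_q: bool = True) -> pd.DataFrame:
    """Tabulate BTSI records; optionally append Benjamini-Hochberg q-values."""
    df = pd.DataFrame(
        {
            "biofluid": [r.biofluid for r in records],
            "tissue": [r.tissue for r in records],
            "rho": [r.rho for r in records],
            "p_value": [r.p_value for r in records],
            "n_genes": [r.n_genes for r in records],
            "label": [r.label for r in records],
        }
    )
    if with_q and len(df):
        from statsmodels.stats.multitest import multipletests

        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
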