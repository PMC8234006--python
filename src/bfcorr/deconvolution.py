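"""Marker-based tissue deconvolution of bulk biofluid profiles.

A reference panel of per-tissue mean profiles is reduced to tissue-specific
marker genes (largest log-scale margin over every other tissue), and each
biofluid's linear-scale mean expression vector is decomposed as a convex
combination of the tissue profiles by simplex-constrained least squares:

    min_p || y - X p ||^2   s.t.  p >= 0,  sum(p) = 1

solved with the Lawson-Hanson active-set NNLS on a sum-penalized system,
which is deterministic and exact for noise-free mixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io_preprocess import LOG_TPM, ExpressionMatrix, InputError

logger = logging.getLogger(__name__)


class PanelError(ValueError):
    """No usable markers can be found for a tissue."""


class UndefinedCompositionError(ValueError):
    """The biofluid vector carries no signal on the marker genes."""


@dataclass
class ReferencePanel:
    """Per-tissue mean expression profiles plus their marker genes.

    ``tissue_profiles`` holds log-scale means (used for marker margins);
    ``linear_profiles`` holds linear-scale means (used for the mixture
    model, which is additive in abundance).
    """

    tissue_profiles: pd.DataFrame  # genes x tissues, log scale
    linear_profiles: pd.DataFrame  # genes x tissues, linear scale
    markers: dict[str, list[str]]  # tissue -> ordered marker gene IDs

    @property
    def marker_union(self) -> list[str]:
        out: list[str] = []
        for tissue in self.tissue_profiles.columns:
            out.extend(self.markers.get(tissue, []))
        return out


@dataclass
class ProportionEstimate:
    biofluid: str
    proportions: pd.Series  # indexed by tissue, on the simplex
    n_markers_used: int


def select_markers(
    tissue_matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    n_per_tissue: int = 100,
) -> ReferencePanel:
    """Build a reference panel with per-tissue marker genes.

    For each tissue, genes are ranked by the specificity margin
    (mean log expression in the tissue) minus (max mean log expression over
    all other tissues); the top ``n_per_tissue`` genes with a strictly
    positive margin become that tissue's markers.  A positive margin is
    attainable for at most one tissue per gene, so marker lists are
    disjoint by construction.  A tissue with no positive-margin gene
    raises :class:`PanelError`.
    """
    if tissue_matrix.state != LOG_TPM:
        raise InputError(f"select_markers expects log_tpm, got {tissue_matrix.state}")
    if n_per_tissue < 1:
        raise InputError("n_per_tissue must be >= 1")
    meta = metadata.loc[tissue_matrix.sample_ids]
    groups = meta["group"]
    if groups.nunique() < 2:
        raise InputError("need at least 2 tissues to select markers")

    log_means = tissue_matrix.values.T.groupby(groups).mean().T  # genes x tissues
    linear_means = (
        (np.exp2(tissue_matrix.values) - 1.0).T.groupby(groups).mean().T
    )
    tissues = list(log_means.columns)
    M = log_means.to_numpy()
    markers: dict[str, list[str]] = {}
    for j, tissue in enumerate(tissues):
        others = np.delete(M, j, axis=1).max(axis=1)
        margin = pd.Series(M[:, j] - others, index=log_means.index)
        positive = margin[margin > 0]
        if positive.empty:
            raise PanelError(f"tissue {tissue!r} has no positive-margin marker gene")
        ranked = positive.reset_index()
        ranked.columns = ["gene_id", "margin"]
        ranked = ranked.sort_values(
            ["margin", "gene_id"], ascending=[False, True], kind="mergesort"
        )
        chosen = ranked["gene_id"].iloc[:n_per_tissue].tolist()
        if len(chosen) < n_per_tissue:
            logger.warning(
                "tissue %r has only %d usable markers (requested %d)",
                tissue, len(chosen), n_per_tissue,
            )
        markers[tissue] = chosen
    return ReferencePanel(log_means, linear_means, markers)


def estimate_proportions(
    biofluid_vector: pd.Series, panel: ReferencePanel, name: str = "biofluid"
) -> ProportionEstimate:
    """Estimate tissue proportions for one biofluid mean-expression vector.

    ``biofluid_vector`` must be on the linear scale and cover the panel's
    marker genes.  The simplex constraint is enforced by augmenting the
    least-squares system with a heavily weighted sum-to-one row and
    renormalizing the NNLS solution.
    """
    genes = panel.marker_union
    missing = [g for g in genes if g not in biofluid_vector.index]
    if missing:
        raise InputError(f"biofluid vector missing marker genes: {missing[:5]}")
    y = biofluid_vector.loc[genes].to_numpy(dtype=float)
    X = panel.linear_profiles.loc[genes].to_numpy(dtype=float)
    if not np.any(y > 0):
        raise UndefinedCompositionError(
            f"{name}: biofluid vector is zero on all marker genes"
        )
    scale = np.abs(X).max()
    if scale == 0:
        raise PanelError("reference profiles are identically zero on markers")
    Xs, ys = X / scale, y / scale
    mu = 1e4  # weight of the sum-to-one constraint relative to unit-scaled data
    A = np.vstack([Xs, mu * np.ones((1, X.shape[1]))])
    b = np.concatenate([ys, [mu]])
    p, _ = nnls(A, b)
    total = p.sum()
    if total <= 0:
        raise UndefinedCompositionError(f"{name}: degenerate all-zero solution")
    p = p / total
    return ProportionEstimate(
        biofluid=name,
        proportions=pd.Series(p, index=panel.tissue_profiles.columns),
        n_markers_used=len(genes),
    )


def deconvolve_all(
    biofluid_matrix: ExpressionMatrix,
    tissue_matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    n_per_tissue: int = 100,
) -> list[ProportionEstimate]:
    """Marker selection plus per-biofluid-type proportion estimation.

    Both matrices must be log2(TPM+1); the biofluid mean vector is formed
    on the linear scale (mean of 2^x - 1 over the fluid's samples).
    """
    from .btsi_core import _group_columns

    if not biofluid_matrix.gene_ids.equals(tissue_matrix.gene_ids):
        raise InputError("biofluid and tissue matrices must share the gene universe")
    panel = select_markers(tissue_matrix, metadata, n_per_tissue)
    estimates = []
    for fluid, cols in _group_columns(biofluid_matrix, metadata, "biofluid").items():
        linear = np.exp2(biofluid_matrix.values[cols]) - 1.0
        estimates.append(estimate_proportions(linear.mean(axis=1), panel, name=fluid))
    return estimates


def proportions_to_frame(estimates: list[ProportionEstimate]) -> pd.DataFrame:
    """Long-format table: biofluid, tissue, proportion."""
    rows = []
    for est in estimates:
        for tissue, prop in est.proportions.items():
            rows.append((est.biofluid, tissue, prop))
    return pd.DataFrame(rows, columns=["biofluid", "tissue", "proportion"])
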