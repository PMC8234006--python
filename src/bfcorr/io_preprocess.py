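"""Expression-matrix containers, TSV readers/writers and preprocessing.

The preprocessing pipeline mirrors standard bulk RNA-seq practice for
cross-study integration: TPM normalization, merging on the shared gene
universe, a prevalence filter on detection frequency, linear-model batch
correction on the log scale, and partition of the gene universe by biotype
(mRNA vs lncRNA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNTS = "counts"
TPM = "tpm"
LOG_TPM = "log_tpm"
_STATES = (COUNTS, TPM, LOG_TPM)

#: Annotation biotype strings collapsed onto the three-way analysis classes.
BIOTYPE_MAP = {
    "protein_coding": "mRNA",
    "mRNA": "mRNA",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
}


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class ParseError(InputError):
    """A table cell could not be parsed."""


class AnnotationError(InputError):
    """A gene is missing from, or inconsistent with, the annotation."""


def canonical_biotype(biotype: str) -> str:
    """Map an annotation biotype string to ``mRNA``, ``lncRNA`` or ``other``."""
    return BIOTYPE_MAP.get(biotype, "other")


@dataclass
class ExpressionMatrix:
    """A gene-by-sample expression matrix with an explicit normalization state.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns.
    state
        One of ``counts``, ``tpm`` or ``log_tpm`` (log2(TPM+1)).  Negative
        entries are only legal in ``log_tpm`` state (they can arise from
        batch correction).
    """

    values: pd.DataFrame
    state: str

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise InputError(f"unknown state {self.state!r}; expected one of {_STATES}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene IDs: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample IDs: {dups[:5]}")
        if self.state in (COUNTS, TPM) and (self.values.to_numpy() < 0).any():
            raise InputError(f"negative values are not allowed in {self.state} state")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.state)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path, state: str) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene ID, header of sample IDs)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    converted = {}
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.argmax()]
            raise ParseError(
                f"{path}: non-numeric value {raw[col][bad].iloc[0]!r} "
                f"at gene {gene!r}, sample {col!r}"
            )
        converted[col] = numeric.astype(float)
    values = pd.DataFrame(converted, index=raw.index.astype(str))
    values.index.name = None
    values.columns.name = None
    return ExpressionMatrix(values, state)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV; round-trips losslessly through :func:`read_matrix`."""
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")  # default float repr is shortest-round-trip


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation TSV with columns gene_id, biotype, length_nt."""
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "biotype": str})
    for col in ("gene_id", "biotype", "length_nt"):
        if col not in ann.columns:
            raise AnnotationError(f"{path}: missing column {col!r}")
    ann = ann.set_index("gene_id")
    if ann.index.has_duplicates:
        raise AnnotationError(f"{path}: duplicate gene IDs in annotation")
    if (ann["length_nt"] <= 0).any():
        bad = ann.index[ann["length_nt"] <= 0][0]
        raise AnnotationError(f"{path}: non-positive length for gene {bad!r}")
    return ann


def write_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV: sample_id, compartment, group, batch, sex."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "compartment", "group", "batch", "sex"):
        if col not in meta.columns:
            raise InputError(f"{path}: missing column {col!r}")
    meta = meta.set_index("sample_id")
    if meta.index.has_duplicates:
        raise InputError(f"{path}: duplicate sample IDs in metadata")
    if (meta["group"].fillna("") == "").any():
        raise InputError(f"{path}: empty group label in metadata")
    return meta


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def tpm_normalize(counts: ExpressionMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Transcripts-per-million normalization.

    Per sample: ``rate_g = count_g / (length_g / 1000)`` (reads per kilobase),
    then ``TPM_g = rate_g / sum(rates) * 1e6``.  Columns with no nonzero
    entry are left all-zero.
    """
    if counts.state != COUNTS:
        raise InputError(f"tpm_normalize expects counts, got {counts.state}")
    missing = counts.gene_ids.difference(annotation.index)
    if len(missing):
        raise AnnotationError(f"genes missing length annotation: {list(missing[:5])}")
    lengths_kb = annotation.loc[counts.gene_ids, "length_nt"].to_numpy(dtype=float) / 1000.0
    rates = counts.values.to_numpy(dtype=float) / lengths_kb[:, None]
    colsum = rates.sum(axis=0)
    scale = np.divide(1e6, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    tpm = rates * scale[None, :]
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.gene_ids, columns=counts.sample_ids), TPM
    )


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1); zeros stay at zero."""
    if matrix.state != TPM:
        raise InputError(f"log_transform expects tpm, got {matrix.state}")
    return ExpressionMatrix(np.log2(matrix.values + 1.0), LOG_TPM)


def merge_on_intersection(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge matrices on their shared gene set; columns are concatenated.

    Gene order follows the first matrix; sample ID collisions across
    sources are rejected.
    """
    if len(matrices) < 2:
        raise InputError("merge_on_intersection needs at least two matrices")
    states = {m.state for m in matrices}
    if len(states) > 1:
        raise InputError(f"matrices are in mixed states: {sorted(states)}")
    common = matrices[0].gene_ids
    for m in matrices[1:]:
        common = common[common.isin(m.gene_ids)]
    if len(common) == 0:
        raise InputError("empty gene intersection across matrices")
    pieces = [m.values.loc[common] for m in matrices]
    merged = pd.concat(pieces, axis=1)
    if merged.columns.has_duplicates:
        dups = merged.columns[merged.columns.duplicated()].unique().tolist()
        raise InputError(f"duplicate sample IDs across sources: {dups[:5]}")
    return ExpressionMatrix(merged, matrices[0].state)


def filter_low_prevalence(matrix: ExpressionMatrix, min_frac: float = 0.25) -> ExpressionMatrix:
    """Drop genes detected (value > 0) in less than ``min_frac`` of samples.

    The boundary is kept: a gene detected in exactly ``min_frac`` of samples
    survives (the exclusion rule is strictly "less than").
    """
    frac = (matrix.values.to_numpy() > 0).mean(axis=1)
    keep = frac >= min_frac
    return ExpressionMatrix(matrix.values.loc[keep], matrix.state)


def _sum_coded_batches(batches: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero contrast columns for a batch factor (k-1 columns)."""
    levels = sorted(batches.unique())
    cols = np.zeros((len(batches), len(levels) - 1))
    arr = batches.to_numpy()
    for j, lev in enumerate(levels[:-1]):
        cols[arr == lev, j] = 1.0
        cols[arr == levels[-1], j] = -1.0
    return cols, levels


def remove_batch_effect(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    preserve: str = "group",
) -> ExpressionMatrix:
    """Remove additive batch offsets from a log-scale matrix.

    Per gene, fits the least-squares linear model
    ``expression ~ preserve-factor + batch`` (batch coded with sum-to-zero
    contrasts) and subtracts only the fitted batch component, so differences
    between the preserved factor's levels and the residual structure are
    retained.  With a single batch, or a batch factor confounded with the
    preserved factor, the matrix is returned unchanged with a warning.

    The operation is a projection: applying it twice equals applying it once.
    """
    if matrix.state != LOG_TPM:
        raise InputError(f"remove_batch_effect expects log_tpm, got {matrix.state}")
    missing = matrix.sample_ids.difference(metadata.index)
    if len(missing):
        raise InputError(f"samples missing from metadata: {list(missing[:5])}")
    meta = metadata.loc[matrix.sample_ids]
    batches = meta["batch"].astype(str)
    if batches.nunique() < 2:
        return matrix.copy()

    groups = meta[preserve].astype(str)
    group_levels = sorted(groups.unique())
    n = len(meta)
    design_cols = [np.ones(n)]
    for lev in group_levels[1:]:
        design_cols.append((groups == lev).to_numpy(dtype=float))
    base = np.column_stack(design_cols)
    batch_cols, _ = _sum_coded_batches(batches)
    X = np.column_stack([base, batch_cols])

    rank_base = np.linalg.matrix_rank(base)
    rank_full = np.linalg.matrix_rank(X)
    if rank_full < rank_base + batch_cols.shape[1]:
        logger.warning(
            "batch factor is confounded with %r; batch term dropped, matrix unchanged",
            preserve,
        )
        return matrix.copy()

    Y = matrix.values.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    n_base = base.shape[1]
    batch_component = batch_cols @ beta[n_base:, :]
    corrected = (Y - batch_component).T
    return ExpressionMatrix(
        pd.DataFrame(corrected, index=matrix.gene_ids, columns=matrix.sample_ids),
        LOG_TPM,
    )


def partition_by_biotype(
    matrix: ExpressionMatrix, annotation: pd.DataFrame
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split a matrix into mRNA and lncRNA sub-matrices.

    Genes with canonical biotype ``other`` are excluded from both.  Every
    gene in the matrix must be annotated.
    """
    missing = matrix.gene_ids.difference(annotation.index)
    if len(missing):
        raise AnnotationError(f"unannotated genes: {list(missing[:5])}")
    biotype = annotation.loc[matrix.gene_ids, "biotype"].map(canonical_biotype)
    mrna = ExpressionMatrix(matrix.values.loc[(biotype == "mRNA").to_numpy()], matrix.state)
    lnc = ExpressionMatrix(matrix.values.loc[(biotype == "lncRNA").to_numpy()], matrix.state)
    logger.info(
        "biotype partition: %d mRNA, %d lncRNA, %d other (excluded)",
        mrna.shape[0], lnc.shape[0], matrix.shape[0] - mrna.shape[0] - lnc.shape[0],
    )
    return mrna, lnc
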