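"""Stratified BTSI comparisons: biotype contrast, sex stratification, and
the regression of BTSI on per-sample detection depth.

The contrasts are plain Welch t-tests between populations of per-sample
rank correlations, and an ordinary least-squares regression of BTSI on the
non-zero gene count (a proxy for sequencing depth), matching the study
design they implement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .btsi_core import spearman_vs_columns
from .io_preprocess import ExpressionMatrix, InputError


class DegenerateFitError(ValueError):
    """A regression or test cannot be computed (zero variance input)."""


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    t_stat: float
    p_value: float
    n_a: int
    n_b: int


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def welch_t_test(a, b, name_a: str = "a", name_b: str = "b") -> GroupComparison:
    """Two-sided Welch (unequal-variance) t-test.

    Degenerate case: both groups constant and equal gives t=0, p=1 by
    convention; constant but different groups give p=0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise InputError("each group needs at least 2 observations")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        t = 0.0 if ma == mb else np.inf * np.sign(ma - mb)
        p = 1.0 if ma == mb else 0.0
    else:
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return GroupComparison(name_a, name_b, float(ma), float(mb), float(t), p, na, nb)


def per_sample_btsi(
    biofluid: ExpressionMatrix, tissue: ExpressionMatrix,
    gene_subset: list[str] | None = None,
) -> pd.Series:
    """Per-biofluid-sample Spearman correlation against the all-tissue mean.

    This is the per-sample unit underlying the depth regression and the
    biotype contrast; restricting to ``gene_subset`` gives the biotype- or
    matched-set-specific BTSI.
    """
    if not biofluid.gene_ids.equals(tissue.gene_ids):
        raise InputError("biofluid and tissue matrices must share the gene universe")
    fluid_vals = biofluid.values
    tissue_vals = tissue.values
    if gene_subset is not None:
        fluid_vals = fluid_vals.loc[gene_subset]
        tissue_vals = tissue_vals.loc[gene_subset]
    ref = tissue_vals.mean(axis=1).to_numpy()
    rho = spearman_vs_columns(ref, fluid_vals.to_numpy())
    return pd.Series(rho, index=biofluid.sample_ids, name="btsi")


def compare_biotype_btsi(mrna_btsi, lncrna_btsi) -> GroupComparison:
    """Welch t-test of mRNA-based vs lncRNA-based BTSI populations."""
    if len(mrna_btsi) < 2 or len(lncrna_btsi) < 2:
        raise InputError("need at least 2 BTSI values per biotype arm")
    return welch_t_test(mrna_btsi, lncrna_btsi, "mRNA", "lncRNA")


def expression_matched_subset(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    metadata: pd.DataFrame,
    k: int = 50,
    min_mean: float | None = None,
) -> dict[str, tuple[list[str], list[str]]]:
    """Per biofluid type, pick k mRNAs and k lncRNAs matched on mean expression.

    Eligible genes have mean expression > 0 (and > ``min_mean`` if given)
    over that fluid's samples.  The k highest-expressed lncRNAs are chosen,
    and each is greedily paired with the unused eligible mRNA whose mean
    expression is closest (ties broken by gene ID), so the two sets'
    expression distributions match as closely as the data allow.  The
    procedure is deterministic given the matrix.
    """
    from .btsi_core import _group_columns
    from .io_preprocess import canonical_biotype

    missing = matrix.gene_ids.difference(annotation.index)
    if len(missing):
        raise InputError(f"unannotated genes: {list(missing[:5])}")
    biotype = annotation.loc[matrix.gene_ids, "biotype"].map(canonical_biotype)
    threshold = 0.0 if min_mean is None else float(min_mean)

    result = {}
    for fluid, cols in _group_columns(matrix, metadata, "biofluid").items():
        means = matrix.values[cols].mean(axis=1)
        eligible = means > threshold
        pools = {}
        for bt in ("mRNA", "lncRNA"):
            pool = means[eligible & (biotype == bt).to_numpy()]
            if len(pool) < k:
                raise InputError(
                    f"biofluid {fluid!r}: only {len(pool)} eligible {bt} genes, need {k}"
                )
            pools[bt] = pool.sort_values(ascending=False, kind="mergesort")
        # take the k highest-expressed lncRNAs, ties broken by gene ID
        lnc_pool = pools["lncRNA"].reset_index()
        lnc_pool.columns = ["gene_id", "mean"]
        lnc_pool = lnc_pool.sort_values(
            ["mean", "gene_id"], ascending=[False, True], kind="mergesort"
        )
        chosen_lnc = lnc_pool.iloc[:k].set_index("gene_id")["mean"]
        # deterministic tie-break: sort candidate mRNAs by (mean, gene_id)
        mrna_pool = pools["mRNA"].reset_index()
        mrna_pool.columns = ["gene_id", "mean"]
        mrna_pool = mrna_pool.sort_values(["mean", "gene_id"], kind="mergesort")
        m_means = mrna_pool["mean"].to_numpy()
        m_ids = mrna_pool["gene_id"].to_numpy()
        used = np.zeros(len(m_ids), dtype=bool)
        mrna_sel = []
        for target in chosen_lnc.to_numpy():
            dist = np.abs(m_means - target)
            dist[used] = np.inf
            best = int(np.argmin(dist))  # argmin takes the first (lowest id) on ties
            used[best] = True
            mrna_sel.append(m_ids[best])
        result[fluid] = (mrna_sel, chosen_lnc.index.tolist())
    return result


def sex_stratified_btsi(
    biofluid: ExpressionMatrix,
    tissue: ExpressionMatrix,
    metadata: pd.DataFrame,
) -> dict[str, dict[str, GroupComparison | None]]:
    """Sex-stratified BTSI contrasts per biofluid type.

    Three per-sample BTSI populations are built for each fluid: F~F
    (female fluid samples vs the female-tissue mean vector), M~M, and the
    F~M cross pairings (female fluid vs male-tissue mean pooled with male
    fluid vs female-tissue mean).  Pairwise Welch tests among the three,
    plus a pooled same-sex vs cross-sex test, are returned.  A sex with
    fewer than 2 samples in either compartment yields ``None`` contrasts
    (not evaluated).
    """
    from .btsi_core import _group_columns

    if not biofluid.gene_ids.equals(tissue.gene_ids):
        raise InputError("biofluid and tissue matrices must share the gene universe")
    meta_t = metadata.loc[tissue.sample_ids]
    t_by_sex = {
        sex: list(meta_t.index[meta_t["sex"] == sex]) for sex in ("female", "male")
    }
    results: dict[str, dict[str, GroupComparison | None]] = {}
    for fluid, cols in _group_columns(biofluid, metadata, "biofluid").items():
        meta_f = metadata.loc[cols]
        f_by_sex = {
            sex: list(meta_f.index[meta_f["sex"] == sex]) for sex in ("female", "male")
        }
        if any(len(t_by_sex[s]) < 2 or len(f_by_sex[s]) < 2 for s in ("female", "male")):
            results[fluid] = {
                "FF_vs_MM": None, "FF_vs_FM": None,
                "MM_vs_FM": None, "same_vs_cross": None,
            }
            continue
        ref = {
            sex: tissue.values[t_by_sex[sex]].mean(axis=1).to_numpy()
            for sex in ("female", "male")
        }
        fvals = {
            sex: biofluid.values[f_by_sex[sex]].to_numpy()
            for sex in ("female", "male")
        }
        ff = spearman_vs_columns(ref["female"], fvals["female"])
        mm = spearman_vs_columns(ref["male"], fvals["male"])
        fm = np.concatenate([
            spearman_vs_columns(ref["male"], fvals["female"]),
            spearman_vs_columns(ref["female"], fvals["male"]),
        ])
        same = np.concatenate([ff, mm])
        results[fluid] = {
            "FF_vs_MM": welch_t_test(ff, mm, "F~F", "M~M"),
            "FF_vs_FM": welch_t_test(ff, fm, "F~F", "F~M"),
            "MM_vs_FM": welch_t_test(mm, fm, "M~M", "F~M"),
            "same_vs_cross": welch_t_test(same, fm, "same-sex", "cross-sex"),
        }
    return results


def btsi_depth_regression(per_sample_btsi, nonzero_counts) -> RegressionFit:
    """OLS of per-sample BTSI on the per-sample non-zero gene count."""
    y = np.asarray(per_sample_btsi, dtype=float)
    x = np.asarray(nonzero_counts, dtype=float)
    if len(x) != len(y):
        raise InputError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise InputError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise DegenerateFitError("non-zero gene count has zero variance")
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
    )
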