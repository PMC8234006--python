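"""Variance-based gene ranking against a LOESS mean-variance trend, and a
hypergeometric over-representation test for user-supplied gene sets.

The ranking follows the variance-stabilizing scheme popularized by
single-cell feature selection: a local polynomial (LOESS) regression of
log10 variance on log10 mean predicts each gene's expected variance, the
per-sample values are standardized by that expectation (clipped at
sqrt(n_samples)), and the variance of the standardized values ranks genes.
The top-k by standardized variance are highly variable genes (HVGs), the
bottom-k lowly variable genes (LVGs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_preprocess import ExpressionMatrix, InputError


def loess_fit(x, y, span: float = 0.3, degree: int = 2) -> np.ndarray:
    """Local polynomial regression with tricube weights, evaluated at x.

    For each point the nearest ``ceil(span * n)`` neighbours (in x) form
    the local window; a weighted degree-``degree`` polynomial is fit and
    evaluated at the point.  Degenerate windows (all x equal) fall back to
    the weighted mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise InputError("x and y must have equal length")
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    fitted_sorted = np.empty(n)
    lo = 0
    for i in range(n):
        # slide the window of k nearest neighbours along the sorted axis
        while lo + k < n and xs[lo + k] - xs[i] < xs[i] - xs[lo]:
            lo += 1
        window = slice(lo, lo + k)
        xw, yw = xs[window], ys[window]
        d = np.abs(xw - xs[i])
        dmax = d.max()
        if dmax == 0:
            fitted_sorted[i] = yw.mean()
            continue
        w = (1.0 - (d / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-12)
        try:
            coeffs = np.polyfit(xw - xs[i], yw, deg=degree, w=np.sqrt(w))
            fitted_sorted[i] = coeffs[-1]  # polynomial evaluated at the centre
        except np.linalg.LinAlgError:
            fitted_sorted[i] = np.average(yw, weights=w)
    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    return fitted


def fit_variance_trend(
    matrix: ExpressionMatrix, span: float = 0.3, degree: int = 2
) -> pd.DataFrame:
    """Per-gene mean, variance, LOESS-expected variance and standardized variance.

    The LOESS trend is fit on log10(variance) vs log10(mean) over genes with
    positive mean and variance; other genes get standardized variance 0.
    Standardized variance is the mean of squared standardized residuals
    ``(x - mean) / sqrt(expected_variance)`` after clipping at
    ``sqrt(n_samples)``, divided by n_samples - 1.
    """
    X = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise InputError("need at least 2 samples to estimate variances")
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)

    fit_mask = (mean > 0) & (var > 0)
    expected = np.zeros(n_genes)
    if fit_mask.sum() >= 3:
        lx = np.log10(mean[fit_mask])
        ly = np.log10(var[fit_mask])
        trend = loess_fit(lx, ly, span=span, degree=degree)
        # interpolate the fitted curve for genes with mean>0 but zero variance
        order = np.argsort(lx, kind="mergesort")
        pred_mask = (mean > 0) & ~fit_mask
        expected[fit_mask] = 10.0 ** trend
        if pred_mask.any():
            expected[pred_mask] = 10.0 ** np.interp(
                np.log10(mean[pred_mask]), lx[order], trend[order]
            )
    std_var = np.zeros(n_genes)
    pos = expected > 0
    if pos.any():
        z = (X[pos] - mean[pos, None]) / np.sqrt(expected[pos, None])
        clip = np.sqrt(n_samples)
        z = np.clip(z, -clip, clip)
        std_var[pos] = (z**2).sum(axis=1) / (n_samples - 1)
    return pd.DataFrame(
        {
            "mean_expr": mean,
            "variance": var,
            "expected_variance": expected,
            "standardized_variance": std_var,
        },
        index=matrix.gene_ids,
    )


def select_top_variable(table: pd.DataFrame, top_k: int = 500) -> pd.DataFrame:
    """Classify the top_k genes by standardized variance as HVG and the
    bottom top_k as LVG; ties broken by gene ID.  Classes are disjoint."""
    n = len(table)
    if 2 * top_k > n:
        raise InputError(f"2*top_k = {2 * top_k} exceeds the {n} available genes")
    out = table.copy()
    ranked = out.reset_index(names="gene_id").sort_values(
        ["standardized_variance", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    out["hvg_rank"] = pd.Series(
        np.arange(1, n + 1), index=ranked["gene_id"].to_numpy()
    )
    out["class"] = "neither"
    out.loc[out["hvg_rank"] <= top_k, "class"] = "HVG"
    out.loc[out["hvg_rank"] > n - top_k, "class"] = "LVG"
    return out


# ---------------------------------------------------------------------------
# gene-set over-representation
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets restricted to an analysis universe."""

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        restricted = {}
        for name, genes in self.sets.items():
            kept = sorted(set(genes) & uni)
            if kept:
                restricted[name] = kept
        self.sets = restricted


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, tab-separated name, description, genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def overrepresentation_test(
    selected: list[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation of ``selected`` in each set.

    p = P(X >= overlap) with universe size N, set size K and draw size n;
    q-values are Benjamini-Hochberg across the collection's sets.
    """
    uni = set(collection.universe)
    offenders = sorted(set(selected) - uni)
    if offenders:
        raise InputError(f"selected genes outside the universe: {offenders[:5]}")
    sel = set(selected)
    N, n = len(uni), len(sel)
    rows = []
    for name, genes in sorted(collection.sets.items()):
        K = len(genes)
        overlap = len(sel & set(genes))
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
        rows.append((name, overlap, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(
        rows,
        columns=["set_name", "overlap", "set_size", "selected_size",
                 "universe_size", "p_value"],
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df
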