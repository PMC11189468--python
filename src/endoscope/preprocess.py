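"""Count preprocessing: gene filtering, normalization, variance stabilization.

The pipeline starts from a raw gene x patient count matrix and produces a
variance-stabilized expression matrix in three steps:

1. remove low-expression genes (mean CPM below a threshold), sex-linked
   genes (chromosomes X and Y, to avoid sex bias in feature selection) and
   features not mapped to a known gene;
2. estimate per-patient size factors by the median-of-ratios method;
3. fit a dispersion--mean trend ``alpha(mu) = a0 + a1/mu`` to per-gene
   method-of-moments dispersions and apply the closed-form
   negative-binomial variance-stabilizing transformation (VST).

The VST used here is, for a normalized count x,

    u(x) = log2( (1 + a1 + 2*a0*x + 2*sqrt(a0*x*(1 + a1 + a0*x))) / (4*a0) )

which is strictly increasing in x and asymptotically log2(x) + const for
large x, so downstream mean differences read as log2 fold changes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CountMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


def compute_cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million on the raw (pre-filter) library totals."""
    totals = counts.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero library total for patient(s): {list(zero.index)}")
    return counts.values / totals * 1e6


@dataclass
class FilterLog:
    n_low_expression: int
    n_sex_linked: int
    n_unannotated: int
    n_retained: int


def filter_genes(
    counts: CountMatrix,
    cpm_threshold: float = 10.0,
    drop_sex_linked: bool = True,
    drop_unannotated: bool = True,
    return_log: bool = False,
):
    """Retain genes with mean CPM >= threshold (inclusive), autosomal
    location (when ``drop_sex_linked``), and known annotation (when
    ``drop_unannotated``).  CPM is computed on pre-filter totals; gene order
    is preserved; the operation is idempotent.
    """
    mean_cpm = compute_cpm(counts).mean(axis=1)
    keep = mean_cpm >= cpm_threshold
    n_low = int((~keep).sum())
    n_sex = 0
    n_unann = 0
    if drop_sex_linked:
        sexed = counts.chromosome.isin(["X", "Y"])
        n_sex = int((keep & sexed).sum())
        keep &= ~sexed
    if drop_unannotated:
        unann = counts.chromosome == "unknown"
        n_unann = int((keep & unann).sum())
        keep &= ~unann
    kept_ids = counts.gene_ids[keep.to_numpy()]
    if len(kept_ids) == 0:
        raise ValueError("no genes retained after filtering")
    logger.info(
        "filter_genes: %d low-expression, %d sex-linked, %d unannotated removed; %d retained",
        n_low, n_sex, n_unann, len(kept_ids),
    )
    result = counts.subset_genes(kept_ids)
    if return_log:
        return result, FilterLog(n_low, n_sex, n_unann, len(kept_ids))
    return result


def median_of_ratios(counts: CountMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference profile is the per-gene geometric mean over patients,
    computed on genes with strictly positive counts everywhere.  With
    ``pseudo_reference=True`` the geometric mean is taken over positive
    counts only (for sparse data with no all-positive gene).
    """
    x = counts.values.to_numpy(dtype=float)
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logx = np.where(x > 0, np.log(x), np.nan)
        n_pos = (~np.isnan(logx)).sum(axis=1)
        ref_rows = n_pos > 0
        geomean = np.exp(np.nanmean(logx[ref_rows], axis=1))
        ratios = x[ref_rows] / geomean[:, None]
        ratios = np.where(x[ref_rows] > 0, ratios, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            s = np.nanmedian(ratios, axis=0)
        if np.isnan(s).any() or (s <= 0).any():
            raise ValueError("size factors undefined for some patients (all-zero columns?)")
    else:
        all_pos = (x > 0).all(axis=1)
        if not all_pos.any():
            raise ValueError(
                "no gene has positive counts in every patient; "
                "retry with pseudo_reference=True"
            )
        ref = x[all_pos]
        geomean = np.exp(np.log(ref).mean(axis=1))
        s = np.median(ref / geomean[:, None], axis=0)
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.patient_ids, name="size_factor")


def _mom_dispersions(normalized: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = normalized.mean(axis=1)
    var = normalized.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mu) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return mu, np.maximum(alpha, DISPERSION_FLOOR)


def fit_dispersion_trend(counts: CountMatrix, size_factors: pd.Series) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu to per-gene method-of-moments dispersions.

    Robust iterative fit: ordinary least squares on the design [1, 1/mu],
    refit after excluding genes whose residual exceeds 2 median absolute
    deviations, repeated to convergence; coefficients clamped >= 0.
    Degenerate input (all dispersions at the floor) falls back to
    (0.01, 1.0) with a warning.
    """
    normalized = counts.values.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    mu, alpha = _mom_dispersions(normalized)
    ok = mu > 0
    if ok.sum() < 50:
        raise ValueError("need at least 50 genes with positive mean to fit the trend")
    mu, alpha = mu[ok], alpha[ok]

    if (alpha <= DISPERSION_FLOOR * 1.001).all():
        warnings.warn("all dispersion estimates at floor; using fallback trend (0.01, 1.0)")
        return 0.01, 1.0

    from scipy.optimize import nnls

    keep = np.ones(alpha.size, dtype=bool)
    coef = np.array([0.0, 0.0])
    for _ in range(10):
        design = np.column_stack([np.ones(keep.sum()), 1.0 / mu[keep]])
        coef, _ = nnls(design, alpha[keep])
        resid = alpha - (coef[0] + coef[1] / mu)
        mad = np.median(np.abs(resid - np.median(resid)))
        if mad <= 0:
            break
        new_keep = np.abs(resid - np.median(resid)) <= 2.0 * mad
        if new_keep.sum() < 50 or (new_keep == keep).all():
            break
        keep = new_keep
    return float(coef[0]), float(coef[1])


def vst_transform_values(x: np.ndarray, a0: float, a1: float) -> np.ndarray:
    """Closed-form NB variance-stabilizing transform, elementwise."""
    if (np.asarray(x) < 0).any():
        raise ValueError("VST input must be non-negative")
    return np.log2(
        (1.0 + a1 + 2.0 * a0 * x + 2.0 * np.sqrt(a0 * x * (1.0 + a1 + a0 * x))) / (4.0 * a0)
    )


def vst(
    counts: CountMatrix, size_factors: pd.Series, trend: tuple[float, float]
) -> ExpressionMatrix:
    """Apply the variance-stabilizing transformation to normalized counts.

    Falls back to log2(x + 1) when the fitted a0 is not positive (pure
    Poisson-like data has no quadratic variance component).
    """
    a0, a1 = trend
    x = counts.values.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    if a0 <= 0:
        warnings.warn("non-positive a0; falling back to log2(normalized + 1)")
        values = np.log2(x + 1.0)
    else:
        values = vst_transform_values(x, a0, a1)
    return ExpressionMatrix(
        pd.DataFrame(values, index=counts.gene_ids, columns=counts.patient_ids),
        vst_params=(float(a0), float(a1)),
    )


def preprocess_counts(
    counts: CountMatrix,
    cpm_threshold: float = 10.0,
    drop_sex_linked: bool = True,
    drop_unannotated: bool = True,
    pseudo_reference: bool = False,
):
    """filter -> median-of-ratios -> dispersion trend -> VST.

    Returns (ExpressionMatrix, size_factors, filtered CountMatrix).
    """
    filtered = filter_genes(counts, cpm_threshold, drop_sex_linked, drop_unannotated)
    s = median_of_ratios(filtered, pseudo_reference=pseudo_reference)
    trend = fit_dispersion_trend(filtered, s)
    expr = vst(filtered, s, trend)
    return expr, s, filtered
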