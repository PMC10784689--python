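"""OLS residualization of battery performance on covariate-task scores.

Tests whether the reliable individual differences a battery captures
survive after removing variance explained by covariate tasks (e.g.
mental rotation, working memory): per iteration, trials are split in
half, the combined battery score of each half is regressed on the
covariates, and the residuals of the two regressions are correlated
across subjects.  A reliably positive residual correlation means the
battery measures something the covariates do not.

The same machinery in cross-measure mode partials the covariates out of
two different score vectors (e.g. a short-form battery and a novel
transfer task) and correlates the residuals across measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from physbattery.data import (
    CorrelationStat,
    DegenerateDataError,
    ResponseMatrix,
    correlation_stats,
)
from physbattery.reliability import (
    SplitHalfResult,
    _bootstrap_z,
    _half_accuracy,
    _pair_z,
    _precompute,
    _rng,
    _split_columns,
    _summarize,
)

__all__ = [
    "ResidualizationResult",
    "ols_residuals",
    "residual_correlation",
    "residual_split_half",
]


@dataclass
class ResidualizationResult:
    """Residual split-half analysis summary."""

    r_squared_per_half: tuple[float, float]  # mean covariate R^2, each half
    residual_split_half: SplitHalfResult
    coefficients: pd.DataFrame  # covariate (+ intercept) weights, per half
    raw_split_half: SplitHalfResult  # non-residualized combined measure

    def to_dict(self) -> dict:
        return {
            "r_squared_per_half": list(self.r_squared_per_half),
            "residual_split_half": self.residual_split_half.to_dict(),
            "raw_split_half": self.raw_split_half.to_dict(),
            "coefficients": self.coefficients.to_dict(),
        }


def ols_residuals(y, X) -> tuple[np.ndarray, float, np.ndarray]:
    """Ordinary least squares of ``y`` on ``X`` with an intercept.

    Returns ``(residuals, R², coefficients)`` where coefficients are
    ``[intercept, b_1, ..., b_k]``.  Requires ``n >= k + 2`` rows and a
    full-column-rank design.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if n < k + 2:
        raise DegenerateDataError(f"need >= {k + 2} rows for {k} covariates, got {n}")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        pairs = []
        if k > 1:
            for i in range(k):
                for j in range(i + 1, k):
                    if abs(corr[i, j]) > 1 - 1e-10:
                        pairs.append((i, j))
        raise DegenerateDataError(f"rank-deficient design; collinear column pairs: {pairs}")
    fit = sm.OLS(y, design).fit()
    return np.asarray(fit.resid), float(fit.rsquared), np.asarray(fit.params)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise DegenerateDataError("zero-variance covariate column")
    return (X - mu) / sd


def residual_split_half(
    rm: ResponseMatrix,
    covariates: pd.DataFrame,
    n_iter: int = 1000,
    n_perm: int = 200,
    seed: int = 0,
) -> ResidualizationResult:
    """Split-half reliability of battery performance after regressing out
    covariate-task scores.

    Per iteration: split trials, form the combined (mean across tasks)
    accuracy per half, regress each half on the standardized covariates
    (intercept included), and correlate the two residual vectors
    (Fisher z).  The permutation p is an exact conditional test on one
    dedicated inference split, shuffling the subject alignment of its
    half-B residuals.  Covariates must be defined for all retained
    subjects.
    """
    cov = covariates.reindex(rm.subjects)
    if cov.isna().any().any():
        missing = list(cov.index[cov.isna().any(axis=1)])[:5]
        raise DegenerateDataError(f"covariates undefined for subjects: {missing}...")
    X = _standardize(cov.to_numpy(dtype=float))
    hits, observed, _ = _precompute(rm)
    tasks = rm.tasks
    n = rm.n_subjects
    zs = np.full(n_iter, np.nan)
    raw_zs = np.full(n_iter, np.nan)
    r2a = np.full(n_iter, np.nan)
    r2b = np.full(n_iter, np.nan)
    coef_a = np.zeros((n_iter, X.shape[1] + 1))
    coef_b = np.zeros_like(coef_a)
    ra_all = np.full((n_iter, n), np.nan)
    rb_all = np.full((n_iter, n), np.nan)
    for it in range(n_iter):
        cols = _split_columns(rm, _rng(seed, 1, it))
        ya, yb = _combined_halves(hits, observed, cols, tasks)
        ok = ~(np.isnan(ya) | np.isnan(yb))
        if ok.sum() < X.shape[1] + 3:
            continue
        ra, r2_a, ca = ols_residuals(ya[ok], X[ok])
        rb, r2_b, cb = ols_residuals(yb[ok], X[ok])
        ra_all[it, ok], rb_all[it, ok] = ra, rb
        zs[it] = _pair_z(ra, rb)
        raw_zs[it] = _pair_z(ya, yb)
        r2a[it], r2b[it] = r2_a, r2_b
        coef_a[it], coef_b[it] = ca, cb

    # exact conditional permutation test on one dedicated inference split:
    # shuffle the subject alignment of the half-B residuals
    obs0 = np.nan
    null = np.full(n_perm, np.nan)
    for attempt in range(50):
        cols = _split_columns(rm, _rng(seed, 3, attempt))
        ya, yb = _combined_halves(hits, observed, cols, tasks)
        ok0 = ~(np.isnan(ya) | np.isnan(yb))
        if ok0.sum() < X.shape[1] + 3:
            continue
        ra0, _, _ = ols_residuals(ya[ok0], X[ok0])
        rb0, _, _ = ols_residuals(yb[ok0], X[ok0])
        obs0 = _pair_z(ra0, rb0)
        if not np.isnan(obs0):
            break
    for j in range(n_perm):
        perm = _rng(seed, 2, j).permutation(rb0.size)
        null[j] = _pair_z(ra0, rb0[perm])

    res = _summarize(zs, null[~np.isnan(null)], n_iter, n_perm, seed, observed_for_p=obs0)
    raw = _summarize(raw_zs, None, n_iter, 0, seed)
    names = ["intercept"] + list(cov.columns)
    coefficients = pd.DataFrame(
        {
            "half_a": np.nanmean(coef_a, axis=0),
            "half_b": np.nanmean(coef_b, axis=0),
        },
        index=names,
    )
    return ResidualizationResult(
        r_squared_per_half=(float(np.nanmean(r2a)), float(np.nanmean(r2b))),
        residual_split_half=res,
        coefficients=coefficients,
        raw_split_half=raw,
    )


def _combined_halves(hits, observed, split_cols, tasks):
    n = hits.shape[0]
    acc_a = np.empty((n, len(tasks)))
    acc_b = np.empty_like(acc_a)
    for k, task in enumerate(tasks):
        a, b = split_cols[task]
        acc_a[:, k] = _half_accuracy(hits, observed, a)
        acc_b[:, k] = _half_accuracy(hits, observed, b)
    with np.errstate(invalid="ignore"):
        return np.nanmean(acc_a, axis=1), np.nanmean(acc_b, axis=1)


def residual_correlation(
    y1,
    y2,
    covariates: pd.DataFrame | np.ndarray,
    n_boot: int = 10000,
    seed: int = 0,
) -> CorrelationStat:
    """Correlate two measures after partialing the covariates out of each
    (cross-measure residualization, e.g. a battery score against a novel
    transfer task).

    Both measures are regressed on the standardized covariates
    (intercept included); the residuals are correlated, with a 95%
    bootstrap CI over subject resamples.
    """
    X = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    ok = ~(np.isnan(y1) | np.isnan(y2) | np.isnan(X).any(axis=1))
    Xs = _standardize(X[ok])
    r1, _, _ = ols_residuals(y1[ok], Xs)
    r2, _, _ = ols_residuals(y2[ok], Xs)
    stat = correlation_stats(r1, r2)
    bz = _bootstrap_z(r1, r2, n_boot, _rng(seed, 6))
    bz = bz[~np.isnan(bz)]
    lo, hi = np.percentile(bz, [2.5, 97.5])
    stat.ci_low, stat.ci_high = float(lo), float(hi)
    return stat
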