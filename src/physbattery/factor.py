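"""Single-factor extraction and split-half cross-validated factor
variance.

A one-factor model is fitted to the task-accuracy correlation matrix by
iterated principal-axis factoring (initial communalities from squared
multiple correlations, leading eigenpair of the reduced matrix, iterate
to convergence).  Subject factor scores come from the regression
(Thurstone) method.  With only a handful of tasks and modest samples,
principal-axis is the robust default; maximum-likelihood extraction is
available via ``method="ml"``.

The cross-validated analysis asks how much of each task's *reliable*
variance a single common factor explains: per iteration, trials are
split in half, the factor is fitted on half-A accuracies, its subject
scores are correlated with each task's half-B accuracy, and the
resulting R² is compared with the task's own split-half R² on the same
splits.  A ratio near 1 means the factor captures essentially all the
explainable (reliable) variance in that task; a low ratio flags a task
whose reliable variance is mostly task-specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from physbattery.data import AccuracyTable, DegenerateDataError, ResponseMatrix
from physbattery.reliability import (
    _pair_z,
    _paired_column_z,
    _precompute,
    _rng,
    _split_columns,
    permutation_pvalue,
)

__all__ = [
    "FactorSolution",
    "FactorValidationResult",
    "crossvalidated_factor_variance",
    "extract_single_factor",
]

MAX_COMMUNALITY = 0.9999  # Heywood clamp


@dataclass
class FactorSolution:
    """One-factor loadings, uniquenesses and subject factor scores."""

    loadings: pd.Series  # per task, in [-1, 1]
    uniquenesses: pd.Series  # 1 - loading^2 at convergence
    scores: pd.Series  # standardized subject scores
    converged: bool
    n_iterations: int
    heywood: bool = False


@dataclass
class FactorValidationResult:
    """Per-task cross-validated factor-variance summary."""

    mean_z: pd.Series  # factor scores vs left-out half accuracy
    sd_z: pd.Series
    r_squared: pd.Series  # tanh(mean_z)^2
    p: pd.Series  # permutation p per task
    ratio_to_reliability: pd.Series  # R^2(factor) / R^2(split-half)
    split_half_mean_z: pd.Series
    n_iter: int
    n_perm: int
    n_degenerate: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "mean_z": self.mean_z.to_dict(),
            "sd_z": self.sd_z.to_dict(),
            "r_squared": self.r_squared.to_dict(),
            "p": self.p.to_dict(),
            "ratio_to_reliability": self.ratio_to_reliability.to_dict(),
            "split_half_mean_z": self.split_half_mean_z.to_dict(),
            "n_iter": self.n_iter,
            "n_perm": self.n_perm,
            "n_degenerate": self.n_degenerate,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# extraction


def _pairwise_corr(acc: pd.DataFrame) -> np.ndarray:
    R = acc.corr(method="pearson").to_numpy()  # pairwise-complete
    if np.isnan(R).any():
        raise DegenerateDataError("correlation matrix has undefined entries")
    return R


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations as starting communalities, with a
    fallback for near-singular R."""
    try:
        Rinv = np.linalg.inv(R)
        smc = 1.0 - 1.0 / np.diag(Rinv)
    except np.linalg.LinAlgError:
        smc = np.full(R.shape[0], np.nan)
    bad = ~np.isfinite(smc) | (smc < 0) | (smc > 1)
    if bad.any():
        off = np.abs(R - np.eye(len(R)))
        smc = np.where(bad, off.max(axis=1), smc)
    return np.clip(smc, 0.0, MAX_COMMUNALITY)


def _paf_loadings(R: np.ndarray, tol: float = 1e-6, max_iter: int = 1000):
    h = _smc(R)
    heywood = False
    converged = False
    it = 0
    loading = np.zeros(len(R))
    for it in range(1, max_iter + 1):
        Rh = R.copy()
        np.fill_diagonal(Rh, h)
        w, v = np.linalg.eigh(Rh)
        lead = max(w[-1], 0.0)
        loading = v[:, -1] * np.sqrt(lead)
        h_new = loading**2
        if (h_new >= 1.0).any():
            heywood = True
        h_new = np.clip(h_new, 0.0, MAX_COMMUNALITY)
        if np.max(np.abs(h_new - h)) < tol:
            h = h_new
            converged = True
            break
        h = h_new
    loading = np.sign(loading) * np.sqrt(np.clip(loading**2, 0, MAX_COMMUNALITY))
    return loading, converged, it, heywood


def _ml_loadings(R: np.ndarray, tol: float = 1e-8):
    """One-factor ML: minimize the Wishart discrepancy over uniquenesses."""
    p = len(R)

    def neg_ll(log_psi):
        psi = np.exp(log_psi)
        # conditional maximization over the loading given psi
        d = 1.0 / np.sqrt(psi)
        Rs = R * np.outer(d, d)
        w, v = np.linalg.eigh(Rs)
        lam2 = max(w[-1] - 1.0, 0.0)
        lam = v[:, -1] * np.sqrt(lam2) * np.sqrt(psi)
        sigma = np.outer(lam, lam) + np.diag(psi)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return np.inf
        return logdet + np.trace(np.linalg.solve(sigma, R))

    start = np.log(np.clip(1.0 - _smc(R), 1e-4, 1.0))
    res = minimize(neg_ll, start, method="L-BFGS-B", tol=tol)
    psi = np.exp(res.x)
    d = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(d, d)
    w, v = np.linalg.eigh(Rs)
    lam2 = max(w[-1] - 1.0, 0.0)
    loading = v[:, -1] * np.sqrt(lam2) * np.sqrt(psi)
    heywood = bool((loading**2 >= 1.0).any())
    loading = np.sign(loading) * np.sqrt(np.clip(loading**2, 0, MAX_COMMUNALITY))
    return loading, bool(res.success), int(res.nit), heywood


def extract_single_factor(
    acc: AccuracyTable | pd.DataFrame, method: str = "paf"
) -> FactorSolution:
    """Fit a one-factor model to subject x task accuracies.

    Loadings are sign-oriented so their sum is nonnegative; communalities
    above 1 (Heywood cases) are clamped and flagged.  Scores use the
    regression method ``f = Z R^{-1} λ`` on column-standardized
    accuracies (missing cells mean-imputed for scoring only) and are
    standardized.
    """
    table = acc.accuracy if isinstance(acc, AccuracyTable) else acc
    tasks = list(table.columns)
    if len(tasks) < 3:
        raise DegenerateDataError("need at least 3 tasks")
    if len(table) < len(tasks) + 2:
        raise DegenerateDataError("need at least n_tasks + 2 subjects")
    sds = table.std(ddof=0)
    zero = [t for t in tasks if sds[t] == 0 or np.isnan(sds[t])]
    if zero:
        raise DegenerateDataError(f"zero-variance task(s): {zero}")

    R = _pairwise_corr(table)
    if method == "paf":
        loading, converged, n_it, heywood = _paf_loadings(R)
    elif method == "ml":
        loading, converged, n_it, heywood = _ml_loadings(R)
    else:
        raise ValueError(f"unknown extraction method {method!r}")
    if loading.sum() < 0:
        loading = -loading
    if not converged:
        warnings.warn("factor extraction did not converge", stacklevel=2)

    Z = (table - table.mean()) / table.std(ddof=0)
    Z = Z.fillna(0.0).to_numpy()  # mean-impute undefined cells for scoring
    weights = np.linalg.solve(R, loading)
    raw = Z @ weights
    sd = raw.std(ddof=0)
    scores = (raw - raw.mean()) / (sd if sd > 0 else 1.0)

    return FactorSolution(
        loadings=pd.Series(loading, index=tasks, name="loading"),
        uniquenesses=pd.Series(1.0 - loading**2, index=tasks, name="uniqueness"),
        scores=pd.Series(scores, index=table.index, name="factor_score"),
        converged=converged,
        n_iterations=n_it,
        heywood=heywood,
    )


# ---------------------------------------------------------------------------
# cross-validated factor variance


def _half_task_accuracy(hits, observed, split_cols, tasks):
    n = hits.shape[0]
    acc_a = np.empty((n, len(tasks)))
    acc_b = np.empty_like(acc_a)
    for k, task in enumerate(tasks):
        a, b = split_cols[task]
        na = observed[:, a].sum(axis=1)
        nb = observed[:, b].sum(axis=1)
        with np.errstate(invalid="ignore"):
            acc_a[:, k] = np.where(na > 0, hits[:, a].sum(axis=1) / np.maximum(na, 1), np.nan)
            acc_b[:, k] = np.where(nb > 0, hits[:, b].sum(axis=1) / np.maximum(nb, 1), np.nan)
    return acc_a, acc_b


def _factor_scores_of_half(acc_half: np.ndarray, tasks, index, method="paf"):
    df = pd.DataFrame(acc_half, columns=tasks, index=index)
    sol = extract_single_factor(df, method=method)
    return sol.scores.to_numpy()


def crossvalidated_factor_variance(
    rm: ResponseMatrix,
    n_iter: int = 1000,
    n_perm: int = 200,
    seed: int = 0,
    method: str = "paf",
) -> FactorValidationResult:
    """Split-half cross-validation of the single-factor solution.

    Per iteration: split every task's trials (the same split stream as
    :func:`physbattery.reliability.split_half_reliability`, so a shared
    seed yields identical halves), fit the factor on half-A accuracies,
    and correlate its subject scores with each task's half-B accuracy
    (Fisher z).  ``ratio_to_reliability`` divides the resulting mean-z
    R² by the split-half R² computed on the identical splits, removing
    split noise from the comparison.  The permutation p is an exact
    conditional test on one dedicated inference split: the factor is fit
    on its half A and the subject alignment of half B is shuffled.
    """
    if len(rm.tasks) < 3:
        raise DegenerateDataError("need at least 3 tasks")
    if rm.n_subjects < 10:
        raise DegenerateDataError("need at least 10 subjects")
    hits, observed, _ = _precompute(rm)
    tasks = rm.tasks
    n = rm.n_subjects
    T = len(tasks)
    fz = np.full((n_iter, T), np.nan)  # factor vs half-B
    sz = np.full((n_iter, T), np.nan)  # half-A vs half-B (reliability)
    n_deg = 0
    for it in range(n_iter):
        cols = _split_columns(rm, _rng(seed, 1, it))
        acc_a, acc_b = _half_task_accuracy(hits, observed, cols, tasks)
        try:
            scores = _factor_scores_of_half(acc_a, tasks, rm.subjects, method)
        except DegenerateDataError:
            n_deg += 1
            continue
        for k in range(T):
            fz[it, k] = _pair_z(scores, acc_b[:, k])
            sz[it, k] = _pair_z(acc_a[:, k], acc_b[:, k])
    if n_deg > 0.5 * n_iter:
        raise DegenerateDataError(f"{n_deg}/{n_iter} iterations degenerate")

    # exact conditional permutation test on one dedicated inference split:
    # fit the factor on its half A, then shuffle the subject alignment of
    # half B; conditional on the half scores this is exactly exchangeable
    # under the no-individual-differences null
    obs0 = np.full(T, np.nan)
    null = np.full((n_perm, T), np.nan)
    for attempt in range(50):
        cols = _split_columns(rm, _rng(seed, 3, attempt))
        acc_a0, acc_b0 = _half_task_accuracy(hits, observed, cols, tasks)
        try:
            scores0 = _factor_scores_of_half(acc_a0, tasks, rm.subjects, method)
        except DegenerateDataError:
            continue
        obs0 = _paired_column_z(np.tile(scores0[:, None], (1, T)), acc_b0)
        if not np.isnan(obs0).any():
            break
    for j in range(n_perm):
        perm = _rng(seed, 2, j).permutation(n)
        null[j] = _paired_column_z(np.tile(scores0[:, None], (1, T)), acc_b0[perm])

    mean_fz = np.nanmean(fz, axis=0)
    mean_sz = np.nanmean(sz, axis=0)
    sd_fz = np.nanstd(fz, axis=0, ddof=1)
    r2_f = np.tanh(mean_fz) ** 2
    r2_s = np.tanh(mean_sz) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(r2_s > 0, r2_f / r2_s, np.nan)
    pvals = []
    for k in range(len(tasks)):
        nk = null[:, k]
        nk = nk[~np.isnan(nk)]
        ok = nk.size and not np.isnan(obs0[k])
        pvals.append(permutation_pvalue(float(obs0[k]), nk) if ok else np.nan)

    idx = pd.Index(tasks, name="task_id")
    return FactorValidationResult(
        mean_z=pd.Series(mean_fz, index=idx),
        sd_z=pd.Series(sd_fz, index=idx),
        r_squared=pd.Series(r2_f, index=idx),
        p=pd.Series(pvals, index=idx),
        ratio_to_reliability=pd.Series(ratio, index=idx),
        split_half_mean_z=pd.Series(mean_sz, index=idx),
        n_iter=n_iter,
        n_perm=n_perm,
        n_degenerate=n_deg,
        seed=seed,
    )
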