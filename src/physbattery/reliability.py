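"""Iterated split-half reliability with permutation nulls, between-task
correlations with bootstrap CIs, and difference-of-correlation tests.

The reliability of a task is estimated by repeatedly splitting its
trials at random into two balanced halves, scoring every subject on each
half, and correlating the half scores across subjects (Fisher z).  The
mean z over iterations summarises reliability; the 2.5th/97.5th
percentiles of the iterated z distribution give a 95% interval.  A
permutation null is built by repeating the procedure while shuffling the
subject correspondence between halves, and the observed mean z is
compared against that null (one-sided: positive association is the
hypothesis).  A combined battery measure averages per-task half scores
within each half before correlating.

Note the uncorrected split-half correlation is a conservative
reliability estimate (each half has only half the trials of the full
score); no Spearman-Brown correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from physbattery.data import (
    AccuracyTable,
    CorrelationStat,
    DegenerateDataError,
    ResponseMatrix,
    fisher_z,
)

__all__ = [
    "SplitHalfResult",
    "TrialSplit",
    "between_task_correlations",
    "correlation_difference_test",
    "permutation_pvalue",
    "split_half_reliability",
    "split_trials",
]

COMBINED = "combined"


@dataclass
class TrialSplit:
    """A balanced random partition of each task's trials into two halves."""

    halves: dict[str, tuple[list[str], list[str]]]

    def validate(self, rm: ResponseMatrix) -> None:
        for task, (a, b) in self.halves.items():
            sa, sb = set(a), set(b)
            assert not sa & sb, f"halves overlap in task {task!r}"
            assert sa | sb == set(rm.trials_by_task[task]), f"non-exhaustive split in {task!r}"
            assert abs(len(a) - len(b)) <= 1, f"unbalanced split in {task!r}"


@dataclass
class SplitHalfResult:
    """Distributional summary of an iterated split-half statistic."""

    mean_z: float
    sd_z: float
    ci_low: float
    ci_high: float
    p: float | None
    n_iter: int
    n_perm: int
    n_degenerate: int
    seed: int

    @property
    def mean_r(self) -> float:
        return float(np.tanh(self.mean_z))

    @property
    def r_squared(self) -> float:
        return float(np.tanh(self.mean_z) ** 2)

    def to_dict(self) -> dict:
        return {
            "mean_z": self.mean_z,
            "sd_z": self.sd_z,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "r_squared": self.r_squared,
            "n_iter": self.n_iter,
            "n_perm": self.n_perm,
            "n_degenerate": self.n_degenerate,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# splitting


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _split_columns(
    rm: ResponseMatrix, rng: np.random.Generator
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Column-index form of a balanced random split, one per task."""
    out = {}
    for task in rm.tasks:
        cols = rm.task_columns(task)
        m = len(cols)
        if m < 2:
            raise ValueError(f"task {task!r} has fewer than 2 trials")
        perm = rng.permutation(m)
        half = (m + 1) // 2
        a, b = cols[perm[:half]], cols[perm[half:]]
        assert len(a) + len(b) == m and abs(len(a) - len(b)) <= 1
        out[task] = (a, b)
    return out


def split_trials(rm: ResponseMatrix, seed: int) -> TrialSplit:
    """Draw one balanced random split of every task's trials.

    The same split applies to all subjects; reproducible from ``seed``.
    """
    cols = _split_columns(rm, _rng(seed, 1, 0))
    start = 0
    trial_at = {}
    for task in rm.tasks:
        for j, trial in enumerate(rm.trials_by_task[task]):
            trial_at[start + j] = trial
        start += len(rm.trials_by_task[task])
    halves = {
        task: ([trial_at[c] for c in a], [trial_at[c] for c in b])
        for task, (a, b) in cols.items()
    }
    split = TrialSplit(halves=halves)
    split.validate(rm)
    return split


# ---------------------------------------------------------------------------
# fast inner loops


def _precompute(rm: ResponseMatrix):
    observed = (~rm.missing).astype(np.int32)
    hits = rm.correct.astype(np.int32) * observed
    task_cols = {t: rm.task_columns(t) for t in rm.tasks}
    return hits, observed, task_cols


def _half_accuracy(hits, observed, idx) -> np.ndarray:
    n = observed[:, idx].sum(axis=1)
    h = hits[:, idx].sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, h / np.maximum(n, 1), np.nan)


def _pair_z(x: np.ndarray, y: np.ndarray) -> float:
    """Fisher z of the pairwise-complete correlation; NaN if degenerate."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return np.nan
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = float(((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy))
    return fisher_z(r)[0]


_VAR_FLOOR = 1e-12  # below this a half is treated as zero-variance


def _paired_column_z(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Fisher z of the pairwise-complete Pearson correlation between each
    matched column pair of ``A`` and ``B`` (subjects x columns).

    Columns with fewer than 3 complete pairs or a zero-variance member
    come back NaN.  Vectorized: this is the inner loop of every
    permutation engine in the package.
    """
    mask = ~(np.isnan(A) | np.isnan(B))
    Aw = np.where(mask, A, 0.0)
    Bw = np.where(mask, B, 0.0)
    n = mask.sum(axis=0)
    nn = np.maximum(n, 1)
    sa = Aw.sum(axis=0)
    sb = Bw.sum(axis=0)
    saa = np.einsum("ij,ij->j", Aw, Aw)
    sbb = np.einsum("ij,ij->j", Bw, Bw)
    sab = np.einsum("ij,ij->j", Aw, Bw)
    cov = sab - sa * sb / nn
    va = saa - sa * sa / nn
    vb = sbb - sb * sb / nn
    bad = (n < 3) | (va <= _VAR_FLOOR) | (vb <= _VAR_FLOOR)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(np.maximum(va, _VAR_FLOOR) * np.maximum(vb, _VAR_FLOOR))
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(r)
    z[bad] = np.nan
    return z


def _half_accuracy_block(hits, observed, rm, seed, iterations, stream: int = 1):
    """Half-score arrays for a block of split iterations.

    Returns ``(acc_a, acc_b)`` of shape (n_iterations, n_subjects,
    n_tasks + 1); the last column is the combined (mean across tasks)
    measure of each half.
    """
    tasks = rm.tasks
    m = len(iterations)
    n = hits.shape[0]
    acc_a = np.empty((m, n, len(tasks) + 1))
    acc_b = np.empty_like(acc_a)
    for row, it in enumerate(iterations):
        cols = _split_columns(rm, _rng(seed, stream, it))
        for k, task in enumerate(tasks):
            a, b = cols[task]
            acc_a[row, :, k] = _half_accuracy(hits, observed, a)
            acc_b[row, :, k] = _half_accuracy(hits, observed, b)
        with np.errstate(invalid="ignore"):
            acc_a[row, :, -1] = np.nanmean(acc_a[row, :, :-1], axis=1)
            acc_b[row, :, -1] = np.nanmean(acc_b[row, :, :-1], axis=1)
    return acc_a, acc_b


def _summarize(
    zs: np.ndarray,
    null: np.ndarray | None,
    n_iter,
    n_perm,
    seed,
    observed_for_p: float | None = None,
) -> SplitHalfResult:
    valid = zs[~np.isnan(zs)]
    n_deg = int(np.isnan(zs).sum())
    if n_deg > 0.5 * len(zs):
        raise DegenerateDataError(
            f"{n_deg}/{len(zs)} split iterations degenerate (zero-variance half)"
        )
    mean_z = float(valid.mean())
    lo, hi = np.percentile(valid, [2.5, 97.5])
    p = None
    if null is not None:
        obs = mean_z if observed_for_p is None else observed_for_p
        null_valid = null[~np.isnan(null)]
        if null_valid.size and not np.isnan(obs):
            p = permutation_pvalue(obs, null_valid)
    return SplitHalfResult(
        mean_z=mean_z,
        sd_z=float(valid.std(ddof=1)) if valid.size > 1 else 0.0,
        ci_low=float(lo),
        ci_high=float(hi),
        p=p,
        n_iter=n_iter,
        n_perm=n_perm,
        n_degenerate=n_deg,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# public engines


def split_half_reliability(
    rm: ResponseMatrix,
    n_iter: int = 10000,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, SplitHalfResult]:
    """Iterated split-half reliability per task plus the combined battery.

    Each iteration draws one joint split (the same split seed stream the
    factor-validation engine uses, so the two analyses see identical
    halves for a given seed), scores both halves, and records the
    across-subject Fisher z per task and for the combined (mean across
    tasks) measure.  Iterations with a zero-variance half are flagged
    and excluded from the mean; more than 50% degenerate is an error.
    Permutation p: an exact conditional test on one dedicated inference
    split — conditional on that split's half scores, each null draw
    shuffles the subject correspondence between halves, and the observed
    z is ranked among the draws (add-one counting rule).  This is
    exactly calibrated under the no-individual-differences null; the
    iterated mean z and its percentile CI remain the reliability
    estimate.  Returns ``{task_id: SplitHalfResult, ..., "combined":
    SplitHalfResult}``.
    """
    if rm.n_subjects < 3:
        raise DegenerateDataError("need at least 3 subjects")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    hits, observed, _ = _precompute(rm)
    keys = list(rm.tasks) + [COMBINED]
    K = len(keys)
    n = rm.n_subjects
    zs = np.empty((n_iter, K))
    chunk = max(1, min(n_iter, 4_000_000 // max(n * K, 1)))
    for lo in range(0, n_iter, chunk):
        its = range(lo, min(lo + chunk, n_iter))
        acc_a, acc_b = _half_accuracy_block(hits, observed, rm, seed, its)
        m = len(its)
        A = acc_a.transpose(1, 0, 2).reshape(n, m * K)
        B = acc_b.transpose(1, 0, 2).reshape(n, m * K)
        zs[lo : lo + m] = _paired_column_z(A, B).reshape(m, K)

    obs0, null = _exact_permutation_null(hits, observed, rm, seed, n_perm)
    return {
        k: _summarize(
            zs[:, i],
            null[:, i] if n_perm else None,
            n_iter,
            n_perm,
            seed,
            observed_for_p=obs0[i],
        )
        for i, k in enumerate(keys)
    }


def _exact_permutation_null(hits, observed, rm, seed, n_perm, max_tries: int = 50):
    """Observed z and alignment-shuffle null draws for the inference split.

    One dedicated split (its own seed stream) supplies the half scores;
    conditional on them, shuffling the subject correspondence between
    halves is exactly exchangeable under the no-individual-differences
    null, so the counting-rule p is exactly calibrated.  A degenerate
    inference split (zero-variance half) is redrawn, up to ``max_tries``.
    """
    n = hits.shape[0]
    K = len(rm.tasks) + 1
    for attempt in range(max_tries):
        acc_a, acc_b = _half_accuracy_block(
            hits, observed, rm, seed, [attempt], stream=3
        )
        A0, B0 = acc_a[0], acc_b[0]  # (n, K)
        obs = _paired_column_z(A0, B0)
        if not np.isnan(obs).any():
            break
    null = np.full((n_perm, K), np.nan)
    for j in range(n_perm):
        perm = _rng(seed, 2, j).permutation(n)
        null[j] = _paired_column_z(A0, B0[perm])
    return obs, null


def permutation_pvalue(observed: float, null_draws) -> float:
    """One-sided permutation p-value with the add-one correction:
    ``p = (1 + #{null >= observed}) / (1 + n)``."""
    null_draws = np.asarray(null_draws, dtype=float)
    if null_draws.size == 0:
        raise ValueError("null_draws must be nonempty")
    return float((1 + (null_draws >= observed).sum()) / (1 + null_draws.size))


def _bootstrap_z(
    x: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator, chunk: int = 2000
) -> np.ndarray:
    """Fisher z of subject-resampled correlations (vectorized, chunked).
    Degenerate replicates come back NaN."""
    n = x.size
    out = np.empty(n_boot)
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(m, n))
        xs, ys = x[idx], y[idx]
        xs = xs - xs.mean(axis=1, keepdims=True)
        ys = ys - ys.mean(axis=1, keepdims=True)
        sx = np.sqrt((xs * xs).sum(axis=1))
        sy = np.sqrt((ys * ys).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xs * ys).sum(axis=1) / (sx * sy)
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
        r[(sx == 0) | (sy == 0)] = np.nan
        out[done : done + m] = np.arctanh(r)
        done += m
    return out


def between_task_correlations(
    acc: AccuracyTable, n_boot: int = 10000, seed: int = 0
) -> dict[tuple[str, str], CorrelationStat]:
    """Pairwise between-task correlations with 95% bootstrap CIs.

    Subjects with an undefined accuracy in either task of a pair are
    dropped pairwise.  CIs are 2.5th/97.5th percentiles of the Fisher-z
    distribution over ``n_boot`` subject resamples.  The diagonal
    (within-task reliability) belongs to the split-half engine and is
    not computed here.
    """
    tasks = acc.tasks
    out: dict[tuple[str, str], CorrelationStat] = {}
    data = acc.accuracy.to_numpy()
    for i, t1 in enumerate(tasks):
        for j in range(i + 1, len(tasks)):
            t2 = tasks[j]
            x, y = data[:, i], data[:, j]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3:
                raise DegenerateDataError(f"fewer than 3 complete subjects for ({t1}, {t2})")
            xs, ys = x[ok], y[ok]
            if xs.std() == 0:
                raise DegenerateDataError(f"zero variance in task {t1!r}")
            if ys.std() == 0:
                raise DegenerateDataError(f"zero variance in task {t2!r}")
            r = float(np.corrcoef(xs, ys)[0, 1])
            z, clamped = fisher_z(r)
            rng = _rng(seed, 4, i, j)
            bz = _bootstrap_z(xs, ys, n_boot, rng)
            bz = bz[~np.isnan(bz)]
            lo, hi = np.percentile(bz, [2.5, 97.5])
            stat = CorrelationStat(
                r=r,
                z=z,
                r_squared=r * r,
                ci_low=float(lo),
                ci_high=float(hi),
                n=int(ok.sum()),
                clamped=clamped,
            )
            out[(t1, t2)] = stat
            out[(t2, t1)] = stat
    return out


def correlation_difference_test(
    x1,
    y1,
    x2,
    y2,
    n_boot: int = 10000,
    seed: int = 0,
    max_redraw_fraction: float = 0.10,
) -> tuple[float, float]:
    """Two-tailed bootstrap test for the difference between two
    correlations measured on the same subjects.

    Subjects are resampled jointly; each replicate yields
    Δz = z(x1,y1) − z(x2,y2).  Degenerate replicates (zero variance) are
    redrawn, with an error if redraws exceed ``max_redraw_fraction``.
    Returns ``(Δz_observed, p)`` with
    ``p = 2·min(P(Δz ≤ 0), P(Δz ≥ 0))`` (add-one corrected, capped at 1).
    """
    arrs = [np.asarray(v, dtype=float) for v in (x1, y1, x2, y2)]
    n = arrs[0].size
    if any(a.size != n for a in arrs) or n < 4:
        raise ValueError("all four vectors must share a common subject set of >= 4")
    ok = ~np.any([np.isnan(a) for a in arrs], axis=0)
    x1v, y1v, x2v, y2v = (a[ok] for a in arrs)
    z1 = fisher_z(float(np.corrcoef(x1v, y1v)[0, 1]))[0]
    z2 = fisher_z(float(np.corrcoef(x2v, y2v)[0, 1]))[0]
    dz_obs = z1 - z2

    rng = _rng(seed, 5)
    m = x1v.size
    dz = np.empty(n_boot)
    redraws = 0
    filled = 0
    while filled < n_boot:
        idx = rng.integers(0, m, size=m)
        sub = [v[idx] for v in (x1v, y1v, x2v, y2v)]
        if any(s.std() == 0 for s in sub):
            redraws += 1
            if redraws > max_redraw_fraction * n_boot:
                raise DegenerateDataError("more than 10% of bootstrap replicates degenerate")
            continue
        b1 = fisher_z(float(np.corrcoef(sub[0], sub[1])[0, 1]))[0]
        b2 = fisher_z(float(np.corrcoef(sub[2], sub[3])[0, 1]))[0]
        dz[filled] = b1 - b2
        filled += 1
    p_low = (1 + (dz <= 0).sum()) / (1 + n_boot)
    p_high = (1 + (dz >= 0).sum()) / (1 + n_boot)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return float(dz_obs), float(p)
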