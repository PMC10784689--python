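"""Short-form battery construction by cross-validated trial subsampling.

To compress a battery, k trials are drawn at random from each task and a
subject's mean performance on the drawn trials is correlated (across
subjects) with their mean performance on the full battery; the draw with
the highest correlation over many iterations is retained.  Because the
selected trials are contained in the full battery, this part-whole
correlation is optimistically biased; an exclude-selected comparison
mode is available for an unbiased diagnostic, and subjects can be split
once into selection and validation sets so the winner is re-scored on
subjects that played no role in selecting it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from physbattery.data import CorrelationStat, ResponseMatrix, correlation_stats
from physbattery.reliability import _precompute, _rng

__all__ = ["BatterySubset", "compress_battery", "evaluate_subset"]


@dataclass
class BatterySubset:
    """A selected trial subset and its correlations with the full battery."""

    selected: dict[str, list[str]]  # task -> trial ids, k each
    k_per_task: int
    train_correlation: CorrelationStat
    validation_correlation: CorrelationStat | None
    n_candidates_evaluated: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "k_per_task": self.k_per_task,
            "train_correlation": self.train_correlation.to_dict(),
            "validation_correlation": (
                None
                if self.validation_correlation is None
                else self.validation_correlation.to_dict()
            ),
            "n_candidates_evaluated": self.n_candidates_evaluated,
            "seed": self.seed,
        }


def _subset_columns(rm: ResponseMatrix, subset: dict[str, list[str]]) -> dict[str, np.ndarray]:
    cols = {}
    for task, trials in subset.items():
        all_trials = rm.trials_by_task[task]
        pos = {t: i for i, t in enumerate(all_trials)}
        unknown = [t for t in trials if t not in pos]
        if unknown:
            raise ValueError(f"unknown trials for task {task!r}: {unknown}")
        if len(set(trials)) != len(trials):
            raise ValueError(f"duplicate trials selected in task {task!r}")
        base = rm.task_columns(task)
        cols[task] = base[[pos[t] for t in trials]]
    return cols


def _mean_scores(hits, observed, col_sets, grand_mean: bool) -> np.ndarray:
    """Mean-of-task-means (default) or grand-mean accuracy over the given
    per-task column sets."""
    if grand_mean:
        cols = np.concatenate(list(col_sets.values()))
        n = observed[:, cols].sum(axis=1)
        h = hits[:, cols].sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, h / np.maximum(n, 1), np.nan)
    per_task = np.empty((hits.shape[0], len(col_sets)))
    for k, cols in enumerate(col_sets.values()):
        n = observed[:, cols].sum(axis=1)
        h = hits[:, cols].sum(axis=1)
        with np.errstate(invalid="ignore"):
            per_task[:, k] = np.where(n > 0, h / np.maximum(n, 1), np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(per_task, axis=1)


def evaluate_subset(
    rm: ResponseMatrix,
    subset: dict[str, list[str]],
    subjects: list[str] | None = None,
    comparison: str = "include",
    grand_mean: bool = False,
) -> CorrelationStat:
    """Correlate subset mean performance with full-battery performance.

    ``comparison="include"`` (the part-whole form) compares against the
    mean over *all* trials; ``"exclude"`` drops the selected trials from
    the comparison score to remove the overlap bias.  Scores default to
    mean-of-task-means (``grand_mean=True`` pools all trials instead).
    """
    hits, observed, task_cols = _precompute(rm)
    if subjects is not None:
        idx = [rm.subject_index()[s] for s in subjects]
        hits, observed = hits[idx], observed[idx]
    sub_cols = _subset_columns(rm, subset)
    if comparison == "include":
        full_cols = task_cols
    elif comparison == "exclude":
        full_cols = {
            t: np.setdiff1d(task_cols[t], sub_cols.get(t, np.array([], dtype=int)))
            for t in rm.tasks
        }
    else:
        raise ValueError(f"unknown comparison mode {comparison!r}")
    short = _mean_scores(hits, observed, sub_cols, grand_mean)
    full = _mean_scores(hits, observed, full_cols, grand_mean)
    return correlation_stats(short, full)


def compress_battery(
    rm: ResponseMatrix,
    k_per_task: int = 10,
    n_iter: int = 10000,
    holdout_fraction: float = 0.5,
    seed: int = 0,
    exhaustive: bool = False,
    comparison: str = "include",
    grand_mean: bool = False,
) -> BatterySubset:
    """Random-search battery compression with held-out-subject validation.

    Subjects are split once into selection (train) and validation sets
    by ``holdout_fraction``; ``n_iter`` random k-per-task draws are
    scored on the train subjects by :func:`evaluate_subset` and the
    argmax is retained (ties broken by first-seen draw), then re-scored
    on the validation subjects.  ``holdout_fraction=0`` reproduces the
    selection-only procedure with no validation.  With
    ``exhaustive=True`` every possible k-per-task combination is scored
    instead of random draws.
    """
    for task in rm.tasks:
        if k_per_task > len(rm.trials_by_task[task]):
            raise ValueError(
                f"k_per_task={k_per_task} exceeds task {task!r} "
                f"size {len(rm.trials_by_task[task])}"
            )
    if not 0 <= holdout_fraction <= 0.9:
        raise ValueError("holdout_fraction must be in [0, 0.9]")

    rng = _rng(seed, 7)
    n = rm.n_subjects
    n_val = int(round(holdout_fraction * n))
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    train_subjects = [rm.subjects[i] for i in sorted(train_idx)]
    val_subjects = [rm.subjects[i] for i in sorted(val_idx)]

    hits, observed, task_cols = _precompute(rm)
    tr = sorted(train_idx)
    hits_tr, obs_tr = hits[tr], observed[tr]

    def score(sub_cols: dict[str, np.ndarray]) -> float:
        if comparison == "include":
            full_cols = task_cols
        else:
            full_cols = {t: np.setdiff1d(task_cols[t], sub_cols[t]) for t in rm.tasks}
        short = _mean_scores(hits_tr, obs_tr, sub_cols, grand_mean)
        full = _mean_scores(hits_tr, obs_tr, full_cols, grand_mean)
        ok = ~(np.isnan(short) | np.isnan(full))
        s, f = short[ok], full[ok]
        if s.size < 3 or s.std() == 0 or f.std() == 0:
            return -np.inf
        return float(np.corrcoef(s, f)[0, 1])

    best_cols: dict[str, np.ndarray] | None = None
    best_r = -np.inf
    n_eval = 0
    if exhaustive:
        combos_per_task = [
            list(itertools.combinations(range(len(rm.trials_by_task[t])), k_per_task))
            for t in rm.tasks
        ]
        for combo in itertools.product(*combos_per_task):
            sub_cols = {
                t: task_cols[t][list(c)] for t, c in zip(rm.tasks, combo)
            }
            r = score(sub_cols)
            n_eval += 1
            if r > best_r:
                best_r, best_cols = r, sub_cols
    else:
        draw_rng = _rng(seed, 8)
        for _ in range(n_iter):
            sub_cols = {
                t: np.sort(
                    task_cols[t][
                        draw_rng.choice(len(rm.trials_by_task[t]), k_per_task, replace=False)
                    ]
                )
                for t in rm.tasks
            }
            r = score(sub_cols)
            n_eval += 1
            if r > best_r:
                best_r, best_cols = r, sub_cols
    if best_cols is None:
        raise RuntimeError("no valid candidate subset found")

    # column indices back to trial ids
    start = 0
    trial_at = {}
    for task in rm.tasks:
        for j, trial in enumerate(rm.trials_by_task[task]):
            trial_at[start + j] = trial
        start += len(rm.trials_by_task[task])
    selected = {t: [trial_at[c] for c in cols] for t, cols in best_cols.items()}
    for t, trials in selected.items():
        assert len(trials) == k_per_task and len(set(trials)) == k_per_task

    train_corr = evaluate_subset(
        rm, selected, train_subjects, comparison=comparison, grand_mean=grand_mean
    )
    val_corr = None
    if n_val >= 3:
        val_corr = evaluate_subset(
            rm, selected, val_subjects, comparison=comparison, grand_mean=grand_mean
        )
    elif n_val > 0:
        warnings.warn("fewer than 3 validation subjects; validation skipped", stacklevel=2)
    return BatterySubset(
        selected=selected,
        k_per_task=k_per_task,
        train_correlation=train_corr,
        validation_correlation=val_corr,
        n_candidates_evaluated=n_eval,
        seed=seed,
    )
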