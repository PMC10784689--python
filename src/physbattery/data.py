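"""Core data types: response matrices, accuracy scoring, correlation
arithmetic, and participant/task exclusion rules.

The unit of observation is a single trial of a binary-choice task:
``(subject, task, trial) -> correct in {0, 1}``, with an explicit
missingness flag (missing trials are ignored by all scoring, never
coded as incorrect).  Batteries are held in a :class:`ResponseMatrix`
— subjects x trials with a per-task column partition — from which
per-task proportion-correct scores are derived.

Correlations between subject-level scores are summarised as
:class:`CorrelationStat`, carrying the Pearson r, its Fisher z
(variance-stabilised ``atanh(r)``) and r².  Perfect correlations are
clamped to ``±(1 - 1e-12)`` before the transform so that deterministic
fixtures do not silently produce infinities; the clamp is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "AccuracyTable",
    "CorrelationStat",
    "DegenerateDataError",
    "ExclusionRuleSet",
    "IntegrityError",
    "ResponseMatrix",
    "TrialResponse",
    "apply_exclusions",
    "correlation_stats",
    "fisher_z",
    "load_covariates",
    "load_responses",
    "score_accuracy",
]

RESPONSE_COLUMNS = ["subject_id", "task_id", "trial_id", "correct", "missing"]

#: r is clamped to +/-(1 - CLAMP_EPS) before atanh.
CLAMP_EPS = 1e-12


class IntegrityError(ValueError):
    """Raised when input data violate a structural invariant."""


class DegenerateDataError(ValueError):
    """Raised when a statistic is requested on degenerate input
    (zero variance, too few observations)."""


@dataclass(frozen=True)
class TrialResponse:
    """A single trial observation.

    ``missing=True`` means the trial was never observed (e.g. a stimulus
    failed to load); its ``correct`` value is ignored by all scoring.
    """

    subject_id: str
    task_id: str
    trial_id: str
    correct: int
    missing: bool = False


@dataclass
class ResponseMatrix:
    """Subjects x trials binary correctness, partitioned into tasks.

    Parameters
    ----------
    subjects
        Ordered subject identifiers (rows).
    tasks
        Ordered task identifiers.
    trials_by_task
        Ordered trial identifiers per task.  Columns of ``correct`` /
        ``missing`` are the concatenation of these lists in task order.
    correct
        ``(n_subjects, n_trials)`` array in {0, 1}.
    missing
        Boolean mask of the same shape; masked cells are ignored.
    chance_by_task
        Chance-level success probability per task (0.5 for
        two-alternative tasks).
    responses
        Optional raw response codes (same shape), used only by the
        uniform-response exclusion rule.
    """

    subjects: list[str]
    tasks: list[str]
    trials_by_task: dict[str, list[str]]
    correct: np.ndarray
    missing: np.ndarray
    chance_by_task: dict[str, float]
    responses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.subjects = list(self.subjects)
        self.tasks = list(self.tasks)
        self.correct = np.asarray(self.correct, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        n_trials = sum(len(v) for v in self.trials_by_task.values())
        if self.correct.shape != (len(self.subjects), n_trials):
            raise IntegrityError(
                f"correct has shape {self.correct.shape}, expected "
                f"({len(self.subjects)}, {n_trials})"
            )
        if self.missing.shape != self.correct.shape:
            raise IntegrityError("missing mask shape mismatch")
        if set(self.tasks) != set(self.trials_by_task):
            raise IntegrityError("tasks and trials_by_task disagree")
        seen: set[str] = set()
        for task, trials in self.trials_by_task.items():
            if len(set(trials)) != len(trials):
                raise IntegrityError(f"duplicate trial ids within task {task!r}")
            seen |= set(trials)
        for task, c in self.chance_by_task.items():
            if not 0.0 < c < 1.0:
                raise IntegrityError(f"chance for task {task!r} not in (0,1): {c}")
        observed = self.correct[~self.missing]
        if observed.size and not np.isin(observed, [0, 1]).all():
            raise IntegrityError("non-missing correctness values must be 0 or 1")

    # -- column bookkeeping ------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_trials(self) -> int:
        return self.correct.shape[1]

    def task_columns(self, task_id: str) -> np.ndarray:
        """Column indices of a task's trials."""
        start = 0
        for task in self.tasks:
            width = len(self.trials_by_task[task])
            if task == task_id:
                return np.arange(start, start + width)
            start += width
        raise KeyError(task_id)

    def subject_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.subjects)}

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format view (one row per subject x trial)."""
        rows = []
        start = 0
        for task in self.tasks:
            trials = self.trials_by_task[task]
            for j, trial in enumerate(trials):
                col = start + j
                for i, subject in enumerate(self.subjects):
                    rows.append(
                        (
                            subject,
                            task,
                            trial,
                            int(self.correct[i, col]),
                            bool(self.missing[i, col]),
                        )
                    )
            start += len(trials)
        return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def select_subjects(self, keep: list[str]) -> "ResponseMatrix":
        idx = [self.subject_index()[s] for s in keep]
        return replace(
            self,
            subjects=list(keep),
            correct=self.correct[idx],
            missing=self.missing[idx],
            responses=None if self.responses is None else self.responses[idx],
        )

    def canonicalize(self) -> "ResponseMatrix":
        """Copy with subjects, tasks and trials in sorted order (the
        ordering :func:`load_responses` produces), for order-independent
        comparison."""
        subjects = sorted(self.subjects)
        tasks = sorted(self.tasks)
        trials_by_task = {t: sorted(self.trials_by_task[t]) for t in tasks}
        row = [self.subject_index()[s] for s in subjects]
        old_cols: dict[tuple[str, str], int] = {}
        start = 0
        for task in self.tasks:
            for j, trial in enumerate(self.trials_by_task[task]):
                old_cols[(task, trial)] = start + j
            start += len(self.trials_by_task[task])
        col = [old_cols[(t, tr)] for t in tasks for tr in trials_by_task[t]]
        return ResponseMatrix(
            subjects=subjects,
            tasks=tasks,
            trials_by_task=trials_by_task,
            correct=self.correct[np.ix_(row, col)],
            missing=self.missing[np.ix_(row, col)],
            chance_by_task={t: self.chance_by_task[t] for t in tasks},
            responses=None if self.responses is None else self.responses[np.ix_(row, col)],
        )

    def equals(self, other: "ResponseMatrix") -> bool:
        return (
            self.subjects == other.subjects
            and self.tasks == other.tasks
            and self.trials_by_task == other.trials_by_task
            and np.array_equal(self.correct, other.correct)
            and np.array_equal(self.missing, other.missing)
            and self.chance_by_task == other.chance_by_task
        )


@dataclass
class AccuracyTable:
    """Per subject x task proportion correct over non-missing trials.

    Cells with zero observed trials are NaN (flagged, never silently 0);
    downstream correlations use pairwise deletion.
    """

    accuracy: pd.DataFrame
    n_observed: pd.DataFrame

    @property
    def subjects(self) -> list[str]:
        return list(self.accuracy.index)

    @property
    def tasks(self) -> list[str]:
        return list(self.accuracy.columns)


@dataclass
class CorrelationStat:
    """A Pearson correlation with its Fisher z and r²."""

    r: float
    z: float
    r_squared: float
    ci_low: float | None = None
    ci_high: float | None = None
    p: float | None = None
    n: int | None = None
    clamped: bool = False

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "z": self.z,
            "r_squared": self.r_squared,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n": self.n,
            "clamped": self.clamped,
        }


def fisher_z(r: float) -> tuple[float, bool]:
    """Fisher z-transform ``atanh(r)`` with clamping at |r| = 1.

    Returns ``(z, clamped)``.  Split halves of deterministic fixtures
    legitimately reach r = 1; clamping to ``±(1 - 1e-12)`` keeps the
    transform finite while flagging the event.
    """
    clamped = False
    if abs(r) >= 1.0 - CLAMP_EPS:
        r = math.copysign(1.0 - CLAMP_EPS, r)
        clamped = True
    return math.atanh(r), clamped


def correlation_stats(x, y) -> CorrelationStat:
    """Pearson correlation of two subject-level score vectors.

    NaN entries are removed pairwise.  Requires >= 3 complete pairs and
    nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DegenerateDataError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero variance in x")
    if np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in y")
    r = float(np.corrcoef(x, y)[0, 1])
    z, clamped = fisher_z(r)
    return CorrelationStat(r=r, z=z, r_squared=r * r, n=int(x.size), clamped=clamped)


# ---------------------------------------------------------------------------
# ingestion


def load_responses(path, chance_map: dict[str, float]) -> ResponseMatrix:
    """Load a long-format responses CSV into a :class:`ResponseMatrix`.

    The file must have columns ``subject_id,task_id,trial_id,correct,missing``
    (an optional ``response`` column carries raw response codes for the
    uniform-response exclusion rule).  Row order never affects the result:
    subjects, tasks and trials are ordered by first appearance, and the
    same set of rows in any order yields an identical matrix.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "task_id": str, "trial_id": str})
    missing_cols = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise IntegrityError(f"responses CSV missing columns: {missing_cols}")
    return _frame_to_matrix(df, chance_map)


def _frame_to_matrix(df: pd.DataFrame, chance_map: dict[str, float]) -> ResponseMatrix:
    bad = df.loc[~df["correct"].isin([0, 1])]
    if len(bad):
        line = int(bad.index[0]) + 2  # header + 1-based
        raise IntegrityError(
            f"correct not in {{0,1}} at line {line}: {bad.iloc[0]['correct']!r}"
        )
    dup = df.duplicated(subset=["subject_id", "task_id", "trial_id"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise IntegrityError(
            "duplicate (subject, task, trial) key: "
            f"({row['subject_id']}, {row['task_id']}, {row['trial_id']})"
        )
    # deterministic canonical ordering, independent of row order
    subjects = sorted(df["subject_id"].unique())
    tasks = sorted(df["task_id"].unique())
    trials_by_task = {
        t: sorted(df.loc[df["task_id"] == t, "trial_id"].unique()) for t in tasks
    }
    unknown = [t for t in tasks if t not in chance_map]
    if unknown:
        raise IntegrityError(f"no chance level given for tasks: {unknown}")
    n_trials = sum(len(v) for v in trials_by_task.values())
    correct = np.zeros((len(subjects), n_trials), dtype=np.int8)
    missing = np.ones((len(subjects), n_trials), dtype=bool)  # absent rows = missing
    has_resp = "response" in df.columns
    responses = np.full((len(subjects), n_trials), np.nan) if has_resp else None

    col_of: dict[tuple[str, str], int] = {}
    start = 0
    for task in tasks:
        for j, trial in enumerate(trials_by_task[task]):
            col_of[(task, trial)] = start + j
        start += len(trials_by_task[task])
    row_of = {s: i for i, s in enumerate(subjects)}

    ii = df["subject_id"].map(row_of).to_numpy()
    jj = np.array([col_of[(t, tr)] for t, tr in zip(df["task_id"], df["trial_id"])])
    correct[ii, jj] = df["correct"].to_numpy(dtype=np.int8)
    missing[ii, jj] = df["missing"].astype(bool).to_numpy()
    if has_resp:
        responses[ii, jj] = pd.to_numeric(df["response"], errors="coerce").to_numpy()

    return ResponseMatrix(
        subjects=subjects,
        tasks=tasks,
        trials_by_task=trials_by_task,
        correct=correct,
        missing=missing,
        chance_by_task={t: float(chance_map[t]) for t in tasks},
        responses=responses,
    )


def load_covariates(path) -> pd.DataFrame:
    """Load a long covariates CSV (``subject_id,covariate_id,score``) into a
    wide subjects x covariates DataFrame."""
    df = pd.read_csv(path, dtype={"subject_id": str, "covariate_id": str})
    need = {"subject_id", "covariate_id", "score"}
    if not need.issubset(df.columns):
        raise IntegrityError(f"covariates CSV missing columns: {sorted(need - set(df.columns))}")
    wide = df.pivot(index="subject_id", columns="covariate_id", values="score")
    wide.index.name = "subject_id"
    return wide.sort_index()


# ---------------------------------------------------------------------------
# scoring


def score_accuracy(rm: ResponseMatrix) -> AccuracyTable:
    """Proportion correct per subject x task over non-missing trials.

    A cell with zero observed trials is NaN, with ``n_observed`` = 0.
    """
    observed = ~rm.missing
    acc = np.full((rm.n_subjects, len(rm.tasks)), np.nan)
    n_obs = np.zeros((rm.n_subjects, len(rm.tasks)), dtype=int)
    for k, task in enumerate(rm.tasks):
        cols = rm.task_columns(task)
        obs = observed[:, cols]
        n = obs.sum(axis=1)
        hits = (rm.correct[:, cols] * obs).sum(axis=1)
        with np.errstate(invalid="ignore"):
            a = np.where(n > 0, hits / np.maximum(n, 1), np.nan)
        acc[:, k] = a
        n_obs[:, k] = n
    index = pd.Index(rm.subjects, name="subject_id")
    return AccuracyTable(
        accuracy=pd.DataFrame(acc, index=index, columns=rm.tasks),
        n_observed=pd.DataFrame(n_obs, index=index, columns=rm.tasks),
    )


# ---------------------------------------------------------------------------
# exclusions


@dataclass
class ExclusionRuleSet:
    """Participant/task exclusion rules for online battery data.

    Whole-subject rules: below chance on ``below_chance_task_limit`` or
    more tasks; working-memory symmetry accuracy under
    ``wm_symmetry_min``; zero working-memory span score; the same raw
    response on every trial (bot filter).  The missingness rule is
    per-task: a subject missing more than ``max_missing_fraction`` of a
    task's trials is dropped from that task only.
    """

    below_chance_task_limit: int = 2
    chance_margin: float = 0.50
    max_missing_fraction: float = 0.25
    wm_symmetry_min: float = 0.85
    wm_zero_span_excludes: bool = True
    uniform_response_excludes: bool = True
    strict_below_chance: bool = True
    wm_symmetry_covariate: str = "wm_symmetry"
    wm_span_covariate: str = "wm_span"

    def __post_init__(self) -> None:
        for name in ("chance_margin", "max_missing_fraction", "wm_symmetry_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.below_chance_task_limit < 1:
            raise ValueError("below_chance_task_limit must be >= 1")


def apply_exclusions(
    rm: ResponseMatrix,
    covariates: pd.DataFrame | None = None,
    rules: ExclusionRuleSet | None = None,
    constant_response_accuracy: dict[str, float] | None = None,
) -> tuple[ResponseMatrix, list[dict]]:
    """Apply participant exclusion rules; return the filtered matrix and a
    per-subject report of every triggered rule.

    Whole-subject rules remove the subject everywhere; the per-task
    missingness rule only marks that subject's trials in the offending
    task as missing (so the cell drops out of that task's analyses by
    pairwise deletion while the subject is retained elsewhere).
    Idempotent: applying the rules to their own output changes nothing.
    """
    rules = rules or ExclusionRuleSet()
    acc = score_accuracy(rm)
    report: list[dict] = []
    drop: set[str] = set()

    chance = np.array(
        [rm.chance_by_task.get(t, rules.chance_margin) for t in rm.tasks]
    )
    a = acc.accuracy.to_numpy()
    with np.errstate(invalid="ignore"):
        below = (a < chance) if rules.strict_below_chance else (a <= chance)
    below &= ~np.isnan(a)
    n_below = below.sum(axis=1)
    for i, subject in enumerate(rm.subjects):
        if n_below[i] >= rules.below_chance_task_limit:
            drop.add(subject)
            tasks = [t for t, b in zip(rm.tasks, below[i]) if b]
            report.append(
                {
                    "subject_id": subject,
                    "rule": "below_chance_tasks",
                    "detail": f"below chance on {int(n_below[i])} tasks: {tasks}",
                }
            )

    if covariates is not None:
        cov = covariates.reindex(rm.subjects)
        if rules.wm_symmetry_covariate in cov.columns:
            sym = cov[rules.wm_symmetry_covariate]
            for subject, v in sym.items():
                if pd.notna(v) and v < rules.wm_symmetry_min and subject not in drop:
                    drop.add(subject)
                    report.append(
                        {
                            "subject_id": subject,
                            "rule": "wm_symmetry",
                            "detail": f"symmetry accuracy {v:.3f} < {rules.wm_symmetry_min}",
                        }
                    )
        if rules.wm_zero_span_excludes and rules.wm_span_covariate in cov.columns:
            span = cov[rules.wm_span_covariate]
            for subject, v in span.items():
                if pd.notna(v) and v == 0 and subject not in drop:
                    drop.add(subject)
                    report.append(
                        {
                            "subject_id": subject,
                            "rule": "wm_zero_span",
                            "detail": "working-memory span score of 0",
                        }
                    )

    if rules.uniform_response_excludes:
        for i, subject in enumerate(rm.subjects):
            if subject in drop:
                continue
            if _uniform_responder(rm, i, acc, constant_response_accuracy):
                drop.add(subject)
                report.append(
                    {
                        "subject_id": subject,
                        "rule": "uniform_response",
                        "detail": "same response on all trials",
                    }
                )

    keep = [s for s in rm.subjects if s not in drop]
    out = rm.select_subjects(keep)

    # per-task missingness rule on the retained subjects
    missing = out.missing.copy()
    for k, task in enumerate(out.tasks):
        cols = out.task_columns(task)
        frac = out.missing[:, cols].mean(axis=1)
        for i, subject in enumerate(out.subjects):
            over = frac[i] > rules.max_missing_fraction
            if over and not out.missing[i, cols].all():
                report.append(
                    {
                        "subject_id": subject,
                        "rule": "task_missingness",
                        "detail": f"{frac[i]:.0%} of trials missing in task {task!r}",
                    }
                )
            if over:
                missing[i, cols] = True
    out = replace(out, missing=missing)
    return out, report


def _uniform_responder(
    rm: ResponseMatrix,
    i: int,
    acc: AccuracyTable,
    constant_response_accuracy: dict[str, float] | None,
) -> bool:
    """Bot heuristic: one raw response throughout when a response stream
    is available, else accuracy exactly at the constant-response level
    (default: chance) in every observed task."""
    observed = ~rm.missing[i]
    if not observed.any():
        return False
    if rm.responses is not None:
        vals = rm.responses[i][observed]
        vals = vals[~np.isnan(vals)]
        return vals.size > 0 and np.unique(vals).size == 1
    const = constant_response_accuracy or rm.chance_by_task
    hit = False
    for k, task in enumerate(rm.tasks):
        a = acc.accuracy.iloc[i, k]
        if np.isnan(a):
            continue
        hit = True
        if not math.isclose(a, const.get(task, rm.chance_by_task[task]), abs_tol=1e-12):
            return False
    return hit
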