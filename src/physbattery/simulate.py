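"""Synthetic trial-level battery generator with retained ground truth.

The generator emulates a battery of two-alternative physical-inference
tasks administered online: each subject carries a general latent ability
θ (standard normal) plus independent task-specific abilities s_t, and
each trial j of task t is passed with probability

    P(correct) = c_t + (1 - c_t) * logistic(a_t * (λ_t·θ + sqrt(1-λ_t²)·s_t - b_j))

— a guessing-floor latent-trait (3PL-style) response model with chance
floor c_t, discrimination a_t, shared-factor loading λ_t and item
difficulties b_j ~ N(0, σ_b²).  Covariate tasks (mental rotation,
working memory, face memory) are linear in θ and a second "spatial"
latent correlated ρ with θ, plus noise.  Missing trials are MCAR.

The default roster mirrors a five-task physical-reasoning battery:
tower stability (48 trials), occluded-disc tracking (64), mass
inference from collisions (240), lifted-weight discrimination (40) and
ramp knock-off prediction (58), all at chance 0.5.

All randomness flows from one master seed through a counter-based
:class:`numpy.random.SeedSequence` spawn-key scheme, so adding a task or
covariate never perturbs draws for earlier ones.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from physbattery.data import ResponseMatrix

__all__ = [
    "CovariateConfig",
    "SyntheticConfig",
    "SyntheticTruth",
    "TaskConfig",
    "balanced_outcome_design",
    "collision_design",
    "default_config",
    "factorial_design",
    "generate_battery",
    "generate_covariates",
    "stay_or_go_design",
    "success_probability",
]


class ConfigError(ValueError):
    """Invalid generative configuration."""


@dataclass
class TaskConfig:
    task_id: str
    n_trials: int
    chance: float = 0.5
    loading: float = 0.6
    discrimination: float = 1.5
    difficulty_sd: float = 1.0

    def validate(self) -> None:
        if not 0 < self.chance < 1:
            raise ConfigError(f"{self.task_id}: chance must be in (0,1)")
        if not 0 <= self.loading <= 1:
            raise ConfigError(f"{self.task_id}: loading must be in [0,1]")
        if self.discrimination < 0:
            raise ConfigError(f"{self.task_id}: discrimination must be >= 0")
        if self.difficulty_sd < 0:
            raise ConfigError(f"{self.task_id}: difficulty_sd must be >= 0")
        if self.n_trials < 1:
            raise ConfigError(f"{self.task_id}: n_trials must be >= 1")


@dataclass
class CovariateConfig:
    covariate_id: str
    loading_on_general: float = 0.0
    loading_on_spatial: float = 0.0
    noise_sd: float = 1.0

    def validate(self) -> None:
        for name in ("loading_on_general", "loading_on_spatial"):
            if not -1 <= getattr(self, name) <= 1:
                raise ConfigError(f"{self.covariate_id}: {name} must be in [-1,1]")
        if self.noise_sd < 0:
            raise ConfigError(f"{self.covariate_id}: noise_sd must be >= 0")
        if (
            self.loading_on_general == 0
            and self.loading_on_spatial == 0
            and self.noise_sd == 0
        ):
            raise ConfigError(f"{self.covariate_id}: zero-variance covariate")


@dataclass
class SyntheticConfig:
    n_subjects: int = 300
    tasks: list[TaskConfig] = field(default_factory=lambda: _default_tasks())
    covariates: list[CovariateConfig] = field(
        default_factory=lambda: _default_covariates()
    )
    spatial_physics_correlation: float = 0.3
    missing_rate: float = 0.02
    #: scales theta and every s_t; 0 gives a null battery with no
    #: subject-level ability variance (all subjects exchangeable).
    ability_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.ability_sd < 0:
            raise ConfigError("ability_sd must be >= 0")
        if not -1 <= self.spatial_physics_correlation <= 1:
            raise ConfigError("spatial_physics_correlation must be in [-1,1]")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0,1)")
        ids = [t.task_id for t in self.tasks]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate task ids")
        for t in self.tasks:
            t.validate()
        for c in self.covariates:
            c.validate()

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "tasks" in d:  # absent -> default roster
            d["tasks"] = [TaskConfig(**t) for t in d["tasks"]]
        if "covariates" in d:
            d["covariates"] = [CovariateConfig(**c) for c in d["covariates"]]
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        text = open(path).read()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            if str(path).endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _default_tasks() -> list[TaskConfig]:
    # trial counts of the five-task battery; chance 0.5 throughout.
    # Mass inference gets a deliberately low common loading: its reliable
    # variance is dominated by a task-specific perceptual bias.
    return [
        TaskConfig("towers", 48, loading=0.60),
        TaskConfig("discs", 64, loading=0.65),
        TaskConfig("collisions", 240, loading=0.30),
        TaskConfig("weightlifting", 40, loading=0.70),
        TaskConfig("ramp", 58, loading=0.60),
    ]


def _default_covariates() -> list[CovariateConfig]:
    return [
        CovariateConfig("mental_rotation", 0.20, 0.60, 0.70),
        CovariateConfig("working_memory", 0.25, 0.40, 0.80),
        CovariateConfig("face_memory", 0.10, 0.00, 0.95),
    ]


def default_config(**overrides) -> SyntheticConfig:
    """The default five-task study configuration, with keyword overrides."""
    cfg = SyntheticConfig(**overrides)
    cfg.validate()
    return cfg


@dataclass
class SyntheticTruth:
    """Latents drawn by :func:`generate_battery`, for parameter recovery."""

    theta: np.ndarray  # (n_subjects,) general ability
    s: pd.DataFrame  # subjects x tasks task-specific abilities
    spatial: np.ndarray  # (n_subjects,) spatial nuisance latent
    difficulties: dict[str, np.ndarray]  # task -> (n_trials,) b_j
    covariate_latents: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "theta": self.theta.tolist(),
            "spatial": self.spatial.tolist(),
            "s": {t: self.s[t].tolist() for t in self.s.columns},
            "difficulties": {t: b.tolist() for t, b in self.difficulties.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def success_probability(
    theta: np.ndarray, s_t: np.ndarray, b: np.ndarray, task: TaskConfig
) -> np.ndarray:
    """Closed-form per-trial success probability, (n_subjects, n_trials)."""
    lam = task.loading
    ability = lam * theta + np.sqrt(1.0 - lam * lam) * s_t
    eta = task.discrimination * (ability[:, None] - b[None, :])
    return task.chance + (1.0 - task.chance) * expit(eta)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def generate_battery(cfg: SyntheticConfig) -> tuple[ResponseMatrix, SyntheticTruth]:
    """Draw a trial-level battery and its generating latents.

    Reproducible from ``cfg.seed``; per-task draws sit on independent
    seed streams keyed by task position, so the roster can grow without
    perturbing existing tasks.
    """
    cfg.validate()
    n = cfg.n_subjects
    rng_lat = _stream(cfg.seed, 0)
    u1 = rng_lat.standard_normal(n)
    u2 = rng_lat.standard_normal(n)
    rho = cfg.spatial_physics_correlation
    theta = u1 * cfg.ability_sd
    spatial = rho * u1 + np.sqrt(1.0 - rho * rho) * u2

    subjects = [f"s{i:04d}" for i in range(n)]
    tasks = [t.task_id for t in cfg.tasks]
    trials_by_task: dict[str, list[str]] = {}
    blocks_correct, blocks_missing = [], []
    s_cols, b_by_task = {}, {}
    for i, task in enumerate(cfg.tasks):
        rng = _stream(cfg.seed, 1, i)
        s_t = rng.standard_normal(n) * cfg.ability_sd
        b = rng.standard_normal(task.n_trials) * task.difficulty_sd
        p = success_probability(theta, s_t, b, task)
        correct = (rng.random((n, task.n_trials)) < p).astype(np.int8)
        miss = rng.random((n, task.n_trials)) < cfg.missing_rate
        trials_by_task[task.task_id] = [
            f"{task.task_id}_t{j:03d}" for j in range(task.n_trials)
        ]
        blocks_correct.append(correct)
        blocks_missing.append(miss)
        s_cols[task.task_id] = s_t
        b_by_task[task.task_id] = b

    rm = ResponseMatrix(
        subjects=subjects,
        tasks=tasks,
        trials_by_task=trials_by_task,
        correct=np.concatenate(blocks_correct, axis=1),
        missing=np.concatenate(blocks_missing, axis=1),
        chance_by_task={t.task_id: t.chance for t in cfg.tasks},
    )
    truth = SyntheticTruth(
        theta=theta,
        s=pd.DataFrame(s_cols, index=subjects),
        spatial=spatial,
        difficulties=b_by_task,
    )
    return rm, truth


def generate_covariates(truth: SyntheticTruth, cfg: SyntheticConfig) -> pd.DataFrame:
    """Covariate-task scores linear in the general and spatial latents.

    score = loading_on_general·θ + loading_on_spatial·spatial + noise,
    standardized across subjects.  Returns a wide subjects x covariates
    DataFrame aligned with the battery's subject order.
    """
    cfg.validate()
    n = len(truth.theta)
    cols = {}
    for j, cov in enumerate(cfg.covariates):
        rng = _stream(cfg.seed, 2, j)
        raw = (
            cov.loading_on_general * truth.theta
            + cov.loading_on_spatial * truth.spatial
            + rng.standard_normal(n) * cov.noise_sd
        )
        sd = raw.std(ddof=0)
        if sd == 0:
            raise ConfigError(f"{cov.covariate_id}: zero-variance covariate scores")
        cols[cov.covariate_id] = (raw - raw.mean()) / sd
    out = pd.DataFrame(cols, index=pd.Index(truth.s.index, name="subject_id"))
    truth.covariate_latents = out
    return out


def write_covariates(cov: pd.DataFrame, path) -> None:
    """Write a wide covariate table to the long CSV interchange format."""
    long = cov.reset_index().melt(
        id_vars="subject_id", var_name="covariate_id", value_name="score"
    )
    long.sort_values(["subject_id", "covariate_id"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stimulus-design enumeration helpers


def factorial_design(**levels) -> pd.DataFrame:
    """Full factorial crossing of named factors (one row per cell)."""
    names = list(levels)
    rows = list(itertools.product(*(levels[n] for n in names)))
    return pd.DataFrame(rows, columns=names)


def stay_or_go_design(
    objects: int | list = 14,
    ramp_angles: tuple = (12.02, 14.94, 17.85, 20.77),
    materials: tuple = ("metal", "glass", "rubber", "wood"),
) -> pd.DataFrame:
    """Full crossing of object x ramp angle x surface material for a
    ramp stay-or-go judgment task (14 x 4 x 4 = 224 stimuli by default)."""
    objs = list(range(objects)) if isinstance(objects, int) else list(objects)
    return factorial_design(object=objs, angle=list(ramp_angles), material=list(materials))


def collision_design(
    weights: tuple = (6, 8, 10, 12, 14, 16),
    filmings_per_pair: int = 2,
    presentations_per_stimulus: int = 4,
) -> pd.DataFrame:
    """Trial enumeration for a two-ball mass-inference task.

    All ordered pairs of distinct weights (incoming vs stationary ball:
    30 for six weights), each filmed ``filmings_per_pair`` times (60
    stimuli) and each stimulus presented ``presentations_per_stimulus``
    times (240 trials by default).
    """
    pairs = [(a, b) for a in weights for b in weights if a != b]
    rows = [
        (inc, sta, f, p)
        for inc, sta in pairs
        for f in range(filmings_per_pair)
        for p in range(presentations_per_stimulus)
    ]
    return pd.DataFrame(rows, columns=["incoming", "stationary", "filming", "presentation"])


def balanced_outcome_design(n_trials: int, seed: int = 0) -> np.ndarray:
    """Binary ground-truth outcomes balanced 50/50 (ramp knock-off style:
    the object is knocked off on half the trials), in random order."""
    half = n_trials // 2
    out = np.array([1] * half + [0] * (n_trials - half), dtype=np.int8)
    _stream(seed, 3).shuffle(out)
    return out
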