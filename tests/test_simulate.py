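"""Synthetic battery generator: response model, determinism, seed
streams, and stimulus-design enumeration."""

import numpy as np
import pytest

from physbattery.data import score_accuracy
from physbattery.reliability import split_half_reliability
from physbattery.simulate import (
    ConfigError,
    CovariateConfig,
    SyntheticConfig,
    TaskConfig,
    balanced_outcome_design,
    collision_design,
    default_config,
    generate_battery,
    generate_covariates,
    stay_or_go_design,
    success_probability,
)


def _cfg(**kw):
    base = dict(n_subjects=200, missing_rate=0.0, seed=0)
    base.update(kw)
    return SyntheticConfig(**base)


def test_default_roster_mirrors_battery():
    cfg = default_config()
    assert [t.n_trials for t in cfg.tasks] == [48, 64, 240, 40, 58]
    assert all(t.chance == 0.5 for t in cfg.tasks)


def test_zero_discrimination_closed_form():
    """a = 0, c = 0.5, b = 0 gives success probability exactly 0.75, and
    the empirical grand mean lands within 3 MC standard errors."""
    task = TaskConfig("flat", 240, discrimination=0.0, difficulty_sd=0.0)
    p = success_probability(np.zeros(3), np.zeros(3), np.zeros(240), task)
    assert np.allclose(p, 0.75)
    cfg = _cfg(tasks=[task], covariates=[])
    rm, _ = generate_battery(cfg)
    grand = rm.correct.mean()
    se = np.sqrt(0.75 * 0.25 / rm.correct.size)
    assert abs(grand - 0.75) < 3 * se


def test_per_trial_frequency_matches_closed_form():
    """Empirical success frequency of a single trial converges to the
    model probability (binomial z-check at n = 2000)."""
    task = TaskConfig("one", 1, loading=0.0, discrimination=1.5, difficulty_sd=0.0)
    cfg = _cfg(n_subjects=2000, tasks=[task], covariates=[])
    rm, truth = generate_battery(cfg)
    p = success_probability(truth.theta, truth.s["one"].to_numpy(), np.zeros(1), task)
    expected = p.mean()
    observed = rm.correct.mean()
    se = np.sqrt(expected * (1 - expected) / 2000)
    assert abs(observed - expected) < 3 * se


def test_independent_tasks_uncorrelated():
    cfg = _cfg(
        n_subjects=500,
        tasks=[TaskConfig(f"t{i}", 60, loading=0.0) for i in range(3)],
        covariates=[],
    )
    rm, _ = generate_battery(cfg)
    acc = score_accuracy(rm).accuracy
    corr = acc.corr().to_numpy()
    off = corr[~np.eye(3, dtype=bool)]
    assert np.all(np.abs(off) < 3 / np.sqrt(500))


def test_between_task_correlation_monotone_in_loading():
    def mean_offdiag(lam):
        cfg = _cfg(
            n_subjects=1000,
            tasks=[TaskConfig(f"t{i}", 60, loading=lam) for i in range(3)],
            covariates=[],
            seed=5,
        )
        rm, _ = generate_battery(cfg)
        corr = score_accuracy(rm).accuracy.corr().to_numpy()
        return corr[~np.eye(3, dtype=bool)].mean()

    r0, r4, r8 = (mean_offdiag(lam) for lam in (0.0, 0.4, 0.8))
    assert r0 < r4 < r8


def test_split_half_reliability_increases_with_trials():
    """Longer tasks are more reliable (test-length direction)."""
    def mean_z(n_trials):
        cfg = _cfg(
            n_subjects=200,
            tasks=[TaskConfig("t", n_trials, loading=0.5)],
            covariates=[],
            seed=3,
        )
        rm, _ = generate_battery(cfg)
        return split_half_reliability(rm, n_iter=100, n_perm=0, seed=1)["t"].mean_z

    assert mean_z(160) > mean_z(40)


def test_same_seed_identical_csv(tmp_path):
    cfg = _cfg(n_subjects=20, missing_rate=0.05)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    generate_battery(cfg)[0].to_csv(p1)
    generate_battery(cfg)[0].to_csv(p2)
    assert p1.read_bytes() == p2.read_bytes()
    cfg2 = _cfg(n_subjects=20, missing_rate=0.05, seed=1)
    p3 = tmp_path / "c.csv"
    generate_battery(cfg2)[0].to_csv(p3)
    assert p1.read_bytes() != p3.read_bytes()


def test_adding_task_preserves_earlier_draws():
    """Counter-based seed streams: appending a task leaves existing
    tasks' responses and the subject latents untouched."""
    tasks = [TaskConfig("a", 30), TaskConfig("b", 25)]
    rm1, truth1 = generate_battery(_cfg(tasks=list(tasks), covariates=[]))
    rm2, truth2 = generate_battery(
        _cfg(tasks=list(tasks) + [TaskConfig("c", 40)], covariates=[])
    )
    assert np.array_equal(truth1.theta, truth2.theta)
    cols = rm1.task_columns("a").tolist() + rm1.task_columns("b").tolist()
    assert np.array_equal(rm1.correct, rm2.correct[:, : len(cols)])


def test_covariates_reproducible_and_structured():
    cfg = _cfg(
        covariates=[
            CovariateConfig("pure_noise", 0, 0, 1.0),
            CovariateConfig("theta_copy", 1.0, 0.0, 0.0),
        ]
    )
    _, truth = generate_battery(cfg)
    cov1 = generate_covariates(truth, cfg)
    cov2 = generate_covariates(truth, cfg)
    assert np.array_equal(cov1.to_numpy(), cov2.to_numpy())
    # a noiseless general-loading covariate is theta up to standardization
    th = (truth.theta - truth.theta.mean()) / truth.theta.std()
    assert np.allclose(cov1["theta_copy"], th)
    assert abs(np.corrcoef(cov1["pure_noise"], truth.theta)[0, 1]) < 3 / np.sqrt(200)


def test_spatial_correlation_targets_rho():
    cfg = _cfg(n_subjects=5000, spatial_physics_correlation=0.3, covariates=[])
    _, truth = generate_battery(cfg)
    assert abs(np.corrcoef(truth.theta, truth.spatial)[0, 1] - 0.3) < 0.05


def test_config_validation_errors():
    with pytest.raises(ConfigError):
        SyntheticConfig(tasks=[TaskConfig("t", 10, loading=1.2)]).validate()
    with pytest.raises(ConfigError):
        SyntheticConfig(tasks=[TaskConfig("t", 10, discrimination=-1)]).validate()
    with pytest.raises(ConfigError):
        SyntheticConfig(covariates=[CovariateConfig("c", 0, 0, 0)]).validate()


def test_config_round_trip(tmp_path):
    cfg = default_config(n_subjects=33, seed=9)
    for name in ("cfg.yaml", "cfg.json"):
        p = tmp_path / name
        cfg.to_file(p)
        assert SyntheticConfig.from_file(p) == cfg


# ---------------------------------------------------------------------------
# stimulus-design enumeration


def test_stay_or_go_full_factorial_count():
    design = stay_or_go_design()
    assert len(design) == 224  # 14 objects x 4 angles x 4 materials
    assert design.drop_duplicates().shape[0] == 224


def test_collision_trial_count():
    design = collision_design()
    # 30 ordered pairs of distinct weights, filmed twice, shown 4 times
    assert len(design) == 240
    assert design[["incoming", "stationary"]].drop_duplicates().shape[0] == 30


def test_balanced_outcomes_fifty_fifty():
    out = balanced_outcome_design(58, seed=0)
    assert out.sum() == 29 and len(out) == 58
    assert not np.array_equal(out, np.sort(out))  # shuffled, not blocked
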