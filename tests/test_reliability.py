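"""Split-half reliability, permutation p-values, between-task
correlations, and the difference-of-correlations bootstrap."""

import itertools

import numpy as np
import pytest

from physbattery.data import DegenerateDataError, score_accuracy
from physbattery.reliability import (
    between_task_correlations,
    correlation_difference_test,
    permutation_pvalue,
    split_half_reliability,
    split_trials,
)
from physbattery.simulate import SyntheticConfig, TaskConfig, generate_battery

from conftest import make_matrix


# ---------------------------------------------------------------------------
# splitting


def test_split_trials_balanced_even_and_odd():
    rm = make_matrix(
        np.ones((3, 45), dtype=int),
        {"even": [f"e{i}" for i in range(40)], "odd": [f"o{i}" for i in range(5)]},
    )
    split = split_trials(rm, seed=0)
    a, b = split.halves["even"]
    assert len(a) == len(b) == 20 and not set(a) & set(b)
    a, b = split.halves["odd"]
    assert {len(a), len(b)} == {3, 2} and set(a) | set(b) == set(rm.trials_by_task["odd"])


def test_split_trials_seed_behavior():
    rm = make_matrix(np.ones((3, 40), dtype=int), {"T": [f"t{i}" for i in range(40)]})
    s1 = split_trials(rm, seed=5)
    s2 = split_trials(rm, seed=5)
    s3 = split_trials(rm, seed=6)
    assert s1.halves == s2.halves
    assert s1.halves != s3.halves  # collision probability ~ 1/C(40,20)


def test_split_trials_too_few_trials():
    rm = make_matrix(np.ones((3, 1), dtype=int), {"T": ["t0"]})
    with pytest.raises(ValueError, match="fewer than 2"):
        split_trials(rm, seed=0)


# ---------------------------------------------------------------------------
# permutation p


def test_permutation_pvalue_extremes_and_symmetry():
    null = np.arange(999, dtype=float)
    assert permutation_pvalue(1e9, null) == pytest.approx(1 / 1000)
    sym = np.concatenate([np.linspace(-1, 1, 999)])
    assert abs(permutation_pvalue(0.0, sym) - 0.5) < 0.01


def test_permutation_pvalue_exhaustive_subject_oracle():
    """On a 4-subject toy, the p computed from all 24 subject
    permutations equals a direct exhaustive enumeration."""
    rng = np.random.default_rng(3)
    a = rng.random(4)
    b = rng.random(4)
    obs = np.corrcoef(a, b)[0, 1]
    null = [np.corrcoef(a, b[list(perm)])[0, 1] for perm in itertools.permutations(range(4))]
    p = permutation_pvalue(obs, np.array(null))
    exact = (1 + sum(v >= obs for v in null)) / (1 + len(null))
    assert p == pytest.approx(exact)


# ---------------------------------------------------------------------------
# split-half engine


def _exhaustive_split_mean_z(correct):
    """Brute-force mean Fisher z over all balanced ordered splits of a
    single 4-trial task (independent oracle)."""
    zs = []
    for half_a in itertools.combinations(range(4), 2):
        half_b = tuple(i for i in range(4) if i not in half_a)
        for a, b in ((half_a, half_b), (half_b, half_a)):
            acc_a = correct[:, list(a)].mean(axis=1)
            acc_b = correct[:, list(b)].mean(axis=1)
            if acc_a.std() == 0 or acc_b.std() == 0:
                zs.append(np.nan)
            else:
                r = np.clip(np.corrcoef(acc_a, acc_b)[0, 1], -1 + 1e-12, 1 - 1e-12)
                zs.append(np.arctanh(r))
    return np.nanmean(zs)


def test_split_half_matches_exhaustive_enumeration():
    correct = np.array(
        [[1, 1, 0, 0], [1, 0, 1, 0], [0, 1, 1, 1], [0, 0, 0, 1], [1, 1, 1, 0]],
        dtype=np.int8,
    )
    rm = make_matrix(correct, {"T": ["t0", "t1", "t2", "t3"]})
    oracle = _exhaustive_split_mean_z(correct)
    res = split_half_reliability(rm, n_iter=3000, n_perm=0, seed=0)["T"]
    # Monte-Carlo average over uniformly drawn splits converges to the
    # exhaustive average over all 6 ordered balanced splits
    assert res.mean_z == pytest.approx(oracle, abs=0.02)


def test_strong_signal_hits_p_floor():
    cfg = SyntheticConfig(
        n_subjects=300,
        tasks=[TaskConfig(f"t{i}", 48, loading=0.7) for i in range(3)],
        covariates=[],
        missing_rate=0.0,
        seed=21,
    )
    rm, _ = generate_battery(cfg)
    res = split_half_reliability(rm, n_iter=50, n_perm=1000, seed=2)
    for k, r in res.items():
        assert r.mean_z > 0
        assert r.p == pytest.approx(1 / 1001)


def test_null_battery_mean_z_near_zero():
    cfg = SyntheticConfig(n_subjects=150, ability_sd=0.0, missing_rate=0.0, seed=31)
    rm, _ = generate_battery(cfg)
    res = split_half_reliability(rm, n_iter=200, n_perm=100, seed=3)
    comb = res["combined"]
    assert abs(comb.mean_z) < 3 * comb.sd_z + 0.05


def test_ci_brackets_mean():
    cfg = SyntheticConfig(n_subjects=100, seed=8)
    rm, _ = generate_battery(cfg)
    res = split_half_reliability(rm, n_iter=100, n_perm=50, seed=4)
    for r in res.values():
        assert r.ci_low <= r.mean_z <= r.ci_high


def test_degenerate_halves_flagged():
    # all subjects always correct -> zero-variance halves everywhere
    rm = make_matrix(np.ones((5, 8), dtype=int), {"T": [f"t{i}" for i in range(8)]})
    with pytest.raises(DegenerateDataError, match="degenerate"):
        split_half_reliability(rm, n_iter=20, n_perm=10, seed=0)


# ---------------------------------------------------------------------------
# between-task correlations


def test_between_task_hand_computed():
    acc = make_matrix(
        np.array(
            [
                [1, 0, 1, 1, 0, 1],
                [1, 1, 0, 1, 1, 1],
                [0, 0, 1, 0, 0, 1],
                [1, 1, 1, 1, 1, 0],
                [0, 1, 0, 0, 1, 0],
            ],
            dtype=np.int8,
        ),
        {"A": ["a0", "a1", "a2"], "B": ["b0", "b1", "b2"]},
    )
    table = score_accuracy(acc)
    out = between_task_correlations(table, n_boot=200, seed=0)
    x = table.accuracy["A"].to_numpy()
    y = table.accuracy["B"].to_numpy()
    assert out[("A", "B")].r == pytest.approx(np.corrcoef(x, y)[0, 1])
    assert out[("A", "B")].ci_low <= out[("A", "B")].z <= out[("A", "B")].ci_high


def test_between_task_duplicate_column_clamped():
    import pandas as pd

    from physbattery.data import AccuracyTable

    vals = np.linspace(0.2, 0.9, 8)
    acc = AccuracyTable(
        accuracy=pd.DataFrame({"A": vals, "B": vals}),
        n_observed=pd.DataFrame({"A": [10] * 8, "B": [10] * 8}),
    )
    out = between_task_correlations(acc, n_boot=50, seed=0)
    stat = out[("A", "B")]
    assert stat.r == pytest.approx(1.0) and stat.clamped


def test_between_task_ci_covers_zero_under_independence():
    covered = 0
    n_rep = 30
    for s in range(n_rep):
        cfg = SyntheticConfig(
            n_subjects=150,
            tasks=[TaskConfig("a", 40, loading=0.0), TaskConfig("b", 40, loading=0.0),
                   TaskConfig("c", 40, loading=0.0)],
            covariates=[],
            missing_rate=0.0,
            seed=100 + s,
        )
        rm, _ = generate_battery(cfg)
        out = between_task_correlations(score_accuracy(rm), n_boot=400, seed=s)
        stat = out[("a", "b")]
        covered += stat.ci_low <= 0 <= stat.ci_high
    assert covered / n_rep >= 0.85  # ~95% nominal


# ---------------------------------------------------------------------------
# difference of correlations


def test_difference_test_identity_and_antisymmetry():
    rng = np.random.default_rng(0)
    x = rng.random(50)
    y = x + rng.random(50)
    dz, p = correlation_difference_test(x, y, x, y, n_boot=300, seed=0)
    assert dz == 0 and p == 1.0
    z2 = rng.random(50)
    d1, p1 = correlation_difference_test(x, y, x, z2, n_boot=300, seed=1)
    d2, p2 = correlation_difference_test(x, z2, x, y, n_boot=300, seed=1)
    assert d1 == pytest.approx(-d2)
    assert p1 == p2


def test_difference_test_strong_separation():
    rng = np.random.default_rng(5)
    n = 200
    x = rng.standard_normal(n)
    y_strong = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(n)
    y_null = rng.standard_normal(n)
    dz, p = correlation_difference_test(x, y_strong, x, y_null, n_boot=500, seed=2)
    assert dz > 0.8
    assert p == pytest.approx(2 / 501)
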