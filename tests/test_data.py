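"""Response ingestion, accuracy scoring, Fisher-z arithmetic, exclusions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from physbattery.data import (
    DegenerateDataError,
    ExclusionRuleSet,
    IntegrityError,
    apply_exclusions,
    correlation_stats,
    fisher_z,
    load_covariates,
    load_responses,
    score_accuracy,
)
from physbattery.simulate import SyntheticConfig, generate_battery

from conftest import make_matrix


# ---------------------------------------------------------------------------
# ingestion


def _write_csv(path, rows):
    with open(path, "w") as fh:
        fh.write("subject_id,task_id,trial_id,correct,missing\n")
        for r in rows:
            fh.write(",".join(map(str, r)) + "\n")


def test_load_responses_basic(tmp_path):
    rows = [
        ("s1", "T", "t1", 1, False),
        ("s1", "T", "t2", 0, False),
        ("s1", "T", "t3", 1, False),
        ("s2", "T", "t1", 0, False),
        ("s2", "T", "t2", 1, False),
        ("s2", "T", "t3", 1, True),
    ]
    p = tmp_path / "r.csv"
    _write_csv(p, rows)
    rm = load_responses(p, {"T": 0.5})
    assert rm.subjects == ["s1", "s2"]
    assert {t: len(v) for t, v in rm.trials_by_task.items()} == {"T": 3}
    assert rm.missing[1, 2]


def test_load_responses_row_order_invariant(tmp_path):
    rows = [
        ("s1", "T", "t1", 1, False),
        ("s2", "T", "t1", 0, False),
        ("s1", "T", "t2", 0, False),
        ("s2", "T", "t2", 1, False),
    ]
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    _write_csv(p1, rows)
    _write_csv(p2, rows[::-1])
    assert load_responses(p1, {"T": 0.5}).equals(load_responses(p2, {"T": 0.5}))


def test_load_responses_duplicate_key_rejected(tmp_path):
    rows = [("s1", "towers", "t7", 1, False), ("s1", "towers", "t7", 0, False)]
    p = tmp_path / "dup.csv"
    _write_csv(p, rows)
    with pytest.raises(IntegrityError, match="duplicate"):
        load_responses(p, {"towers": 0.5})


def test_load_responses_bad_correct_value(tmp_path):
    p = tmp_path / "bad.csv"
    _write_csv(p, [("s1", "T", "t1", 2, False)])
    with pytest.raises(IntegrityError, match="correct"):
        load_responses(p, {"T": 0.5})


def test_generator_csv_round_trip(tmp_path):
    """Writing a generated battery and loading it back reproduces the
    matrix exactly (up to canonical ordering)."""
    cfg = SyntheticConfig(n_subjects=12, seed=7)
    rm, _ = generate_battery(cfg)
    p = tmp_path / "gen.csv"
    rm.to_csv(p)
    loaded = load_responses(p, rm.chance_by_task)
    assert rm.canonicalize().equals(loaded)


def test_load_covariates(tmp_path):
    p = tmp_path / "cov.csv"
    pd.DataFrame(
        {
            "subject_id": ["s1", "s1", "s2", "s2"],
            "covariate_id": ["mrt", "wm", "mrt", "wm"],
            "score": [0.1, -0.2, 0.5, 0.3],
        }
    ).to_csv(p, index=False)
    wide = load_covariates(p)
    assert list(wide.columns) == ["mrt", "wm"]
    assert wide.loc["s2", "mrt"] == 0.5


# ---------------------------------------------------------------------------
# accuracy


def test_score_accuracy_hand_counts():
    rm = make_matrix([[1, 1, 1, 0]], {"T": ["a", "b", "c", "d"]})
    assert score_accuracy(rm).accuracy.iloc[0, 0] == 0.75


def test_score_accuracy_all_missing_flagged():
    rm = make_matrix(
        [[1, 1], [1, 0]],
        {"T": ["a", "b"]},
        missing=[[True, True], [False, False]],
    )
    acc = score_accuracy(rm)
    assert np.isnan(acc.accuracy.iloc[0, 0])
    assert acc.n_observed.iloc[0, 0] == 0
    assert acc.accuracy.iloc[1, 0] == 0.5


def test_score_accuracy_brute_force_table():
    """3 subjects x 2 tasks with one missing cell: every cell equals a
    hand-enumerated count."""
    correct = [[1, 0, 1, 1, 0, 0], [1, 1, 1, 0, 1, 1], [0, 0, 0, 1, 1, 0]]
    missing = [[False] * 6, [False, False, False, True, False, False], [False] * 6]
    rm = make_matrix(correct, {"X": ["x1", "x2", "x3"], "Y": ["y1", "y2", "y3"]}, missing=missing)
    acc = score_accuracy(rm).accuracy
    expected = [[2 / 3, 1 / 3], [1.0, 1.0], [0.0, 2 / 3]]
    assert np.allclose(acc.to_numpy(), expected)


# ---------------------------------------------------------------------------
# correlation arithmetic


def test_correlation_stats_zero_and_closed_form():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to centered x
    stat = correlation_stats(x, y)
    assert abs(stat.r) < 1e-12 and abs(stat.z) < 1e-12 and stat.r_squared < 1e-20


def test_fisher_z_closed_form():
    z, clamped = fisher_z(0.5)
    assert math.isclose(z, 0.5493061443340549, rel_tol=1e-12)
    assert not clamped


def test_z_to_r_squared_printed_value():
    # a factor-validation Fisher z of 0.64 corresponds to R^2 = 0.32 (2 d.p.)
    assert round(math.tanh(0.64) ** 2, 2) == 0.32


def test_correlation_stats_degenerate_inputs():
    with pytest.raises(DegenerateDataError, match="zero variance in y"):
        correlation_stats([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
    with pytest.raises(DegenerateDataError, match="pairs"):
        correlation_stats([1.0, 2.0], [0.0, 1.0])


def test_fisher_clamp_at_unity():
    z, clamped = fisher_z(1.0)
    assert clamped and np.isfinite(z) and z > 13


@settings(derandomize=True, max_examples=200)
@given(
    r1=st.floats(-0.9999, 0.9999),
    r2=st.floats(-0.9999, 0.9999),
)
def test_fisher_transform_odd_and_monotone(r1, r2):
    z1, _ = fisher_z(r1)
    zneg, _ = fisher_z(-r1)
    assert math.isclose(zneg, -z1, rel_tol=1e-9, abs_tol=1e-12)
    if r1 < r2:
        assert z1 < fisher_z(r2)[0]


# ---------------------------------------------------------------------------
# exclusions


def _battery_with_accuracy(acc_rows, n_trials=20):
    """Subjects with prescribed per-task accuracies (exact counts)."""
    correct = []
    for accs in acc_rows:
        row = []
        for a in accs:
            k = int(round(a * n_trials))
            row.extend([1] * k + [0] * (n_trials - k))
        correct.append(row)
    tasks = {f"T{j}": [f"T{j}_t{i}" for i in range(n_trials)] for j in range(len(acc_rows[0]))}
    return make_matrix(correct, tasks)


def test_below_chance_two_tasks_excluded():
    rm = _battery_with_accuracy(
        [[0.45, 0.45, 0.7], [0.45, 0.7, 0.7], [0.7, 0.7, 0.7]]
    )
    out, report = apply_exclusions(rm, rules=ExclusionRuleSet(uniform_response_excludes=False))
    assert out.subjects == ["s1", "s2"]  # s0 below chance on 2 tasks
    assert [r["rule"] for r in report if r["subject_id"] == "s0"] == ["below_chance_tasks"]


def test_below_chance_strictness_configurable():
    rm = _battery_with_accuracy([[0.5, 0.5, 0.7], [0.7, 0.7, 0.7], [0.6, 0.6, 0.6]])
    strict, _ = apply_exclusions(rm, rules=ExclusionRuleSet(uniform_response_excludes=False))
    assert "s0" in strict.subjects  # 0.50 is not below chance under strict <
    lax, _ = apply_exclusions(
        rm, rules=ExclusionRuleSet(strict_below_chance=False, uniform_response_excludes=False)
    )
    assert "s0" not in lax.subjects


def test_missingness_drops_subject_from_task_only():
    missing = np.zeros((3, 40), dtype=bool)
    missing[0, :12] = True  # 30% of the first task's 40... first task cols 0..19
    rng = np.random.default_rng(1)
    correct = (rng.random((3, 40)) < 0.7).astype(np.int8)
    rm = make_matrix(
        correct,
        {"A": [f"a{i}" for i in range(20)], "B": [f"b{i}" for i in range(20)]},
        missing=missing,
    )
    out, report = apply_exclusions(rm, rules=ExclusionRuleSet(uniform_response_excludes=False))
    assert out.subjects == rm.subjects  # retained everywhere else
    acc = score_accuracy(out).accuracy
    assert np.isnan(acc.loc["s0", "A"]) and not np.isnan(acc.loc["s0", "B"])
    assert any(r["rule"] == "task_missingness" and r["subject_id"] == "s0" for r in report)


def test_wm_rules_from_covariates():
    rm = _battery_with_accuracy([[0.7, 0.7], [0.7, 0.7], [0.7, 0.7]])
    cov = pd.DataFrame(
        {"wm_symmetry": [0.95, 0.80, 0.99], "wm_span": [5, 4, 0]},
        index=pd.Index(["s0", "s1", "s2"], name="subject_id"),
    )
    out, report = apply_exclusions(rm, cov, ExclusionRuleSet(uniform_response_excludes=False))
    assert out.subjects == ["s0"]
    rules = {r["subject_id"]: r["rule"] for r in report}
    assert rules == {"s1": "wm_symmetry", "s2": "wm_zero_span"}


def test_uniform_response_exclusion():
    # accuracy exactly at chance in every task approximates a constant responder
    rm = _battery_with_accuracy([[0.5, 0.5], [0.7, 0.8], [0.65, 0.6]])
    out, report = apply_exclusions(rm, rules=ExclusionRuleSet(below_chance_task_limit=99))
    assert "s0" not in out.subjects
    assert any(r["rule"] == "uniform_response" for r in report)


def test_uniform_response_from_raw_stream():
    rm = _battery_with_accuracy([[0.6, 0.6], [0.7, 0.8]])
    responses = np.ones((2, 40))
    responses[1, ::2] = 0
    rm.responses = responses
    out, _ = apply_exclusions(rm, rules=ExclusionRuleSet(below_chance_task_limit=99))
    assert out.subjects == ["s1"]


def test_apply_exclusions_idempotent():
    rm = _battery_with_accuracy(
        [[0.45, 0.45, 0.7], [0.7, 0.7, 0.7], [0.8, 0.6, 0.9], [0.55, 0.75, 0.85]]
    )
    once, _ = apply_exclusions(rm)
    twice, report2 = apply_exclusions(once)
    assert once.equals(twice)
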