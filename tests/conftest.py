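import numpy as np
import pytest

from physbattery.data import ResponseMatrix
from physbattery.simulate import SyntheticConfig, generate_battery


def make_matrix(correct, trials_by_task, chance=0.5, missing=None, subjects=None):
    """Build a small ResponseMatrix from a dense correctness array."""
    correct = np.asarray(correct, dtype=np.int8)
    if missing is None:
        missing = np.zeros_like(correct, dtype=bool)
    if subjects is None:
        subjects = [f"s{i}" for i in range(correct.shape[0])]
    return ResponseMatrix(
        subjects=subjects,
        tasks=list(trials_by_task),
        trials_by_task={t: list(v) for t, v in trials_by_task.items()},
        correct=correct,
        missing=np.asarray(missing, dtype=bool),
        chance_by_task={t: chance for t in trials_by_task},
    )


@pytest.fixture(scope="session")
def default_battery():
    """A mid-sized battery from the default five-task configuration."""
    cfg = SyntheticConfig(n_subjects=150, seed=42)
    rm, truth = generate_battery(cfg)
    return cfg, rm, truth


@pytest.fixture
def tiny_two_task():
    """2 tasks x 4 trials, 5 subjects, fully deterministic."""
    rng = np.random.default_rng(99)
    correct = (rng.random((5, 8)) < 0.6).astype(np.int8)
    return make_matrix(
        correct, {"alpha": [f"a{i}" for i in range(4)], "beta": [f"b{i}" for i in range(4)]}
    )
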