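import numpy as np
import pytest

from cogavoid.task_model import ExperimentSpec, default_phase, load_template
from cogavoid.sim_engine import AgentParams, run_cohort
from cogavoid.kinematics import summarize_session
from cogavoid.stats import cohort_trial_table
from cogavoid.uxf_io import TrackerTrace


def random_trace(rng: np.random.Generator, n: int = 200, rate: float = 90.0,
                 with_yaw: bool = True) -> TrackerTrace:
    """A random but well-formed head trace for oracle/property tests."""
    times = np.arange(n) / rate
    pos = np.empty((n, 3))
    pos[:, 0] = rng.normal(0, 1.0) + np.cumsum(rng.normal(0, 0.02, n))
    pos[:, 1] = 1.7 + rng.normal(0, 0.01, n)
    pos[:, 2] = rng.normal(-2.5, 1.0) + np.cumsum(rng.normal(0, 0.02, n))
    yaw = rng.uniform(-180, 540, n) if with_yaw else None
    return TrackerTrace(tracker_id="head", times=times, positions=pos, yaw=yaw,
                        nominal_rate=rate)


@pytest.fixture(scope="session")
def exp4_avoider_table():
    """One analysed avoider cohort on the full reinstatement design."""
    spec = load_template("exp4")
    sessions = run_cohort(spec, AgentParams(), 16, seed=11)
    for s in sessions:
        summarize_session(s)
    return cohort_trial_table(sessions)


@pytest.fixture(scope="session")
def avoidance_only_spec():
    return ExperimentSpec(name="avoidance_only",
                          phases=[default_phase("avoidance_learning")])
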