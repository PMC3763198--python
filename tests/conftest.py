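import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import edaflow as ef

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


# 32 Hz keeps Monte-Carlo runs cheap; the 0.6 Hz analysis band is unaffected.
SCALED_RATE = 32.0


@pytest.fixture(scope="session")
def scaled_config() -> ef.SimConfig:
    return ef.SimConfig(seed=7).resampled(SCALED_RATE)


@pytest.fixture(scope="session")
def quiet_config() -> ef.SimConfig:
    """All effect couplings off: the null-hypothesis generator."""
    return ef.SimConfig(
        exposure_scl_delta=0.0,
        exposure_rate_delta=0.0,
        pleasure_scl_slope=0.0,
        familiarity_pleasure_slope=0.0,
        familiarity_arousal_slope=0.0,
        seed=7,
    ).resampled(SCALED_RATE)


@pytest.fixture(scope="session")
def exp1_design() -> ef.DesignSpec:
    return ef.DesignSpec(experiment="exp1")


@pytest.fixture(scope="session")
def exp2_design() -> ef.DesignSpec:
    return ef.DesignSpec(experiment="exp2")


@pytest.fixture(scope="session")
def short_design() -> ef.DesignSpec:
    """A compressed session for fast unit tests: 2 runs x 5 trials."""
    return ef.DesignSpec(
        experiment="exp1",
        trials_per_run=5,
        trial_duration=10.0,
        baseline_duration=20.0,
        inter_trial_gap=5.0,
        n_excerpts=10,
    )


@pytest.fixture(scope="session")
def scaled_subject(scaled_config, exp1_design) -> ef.SubjectDataset:
    return ef.simulate_subject(scaled_config, exp1_design, subject=0, seed=42)


def constant_trace(value: float, duration: float, rate: float) -> ef.RawTrace:
    return ef.RawTrace(np.full(int(duration * rate), value), rate)
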