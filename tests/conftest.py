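import numpy as np
import pytest

from nutricea.synthetic_trial import TrialConfig, generate_trial


@pytest.fixture(scope="session")
def default_config() -> TrialConfig:
    return TrialConfig(seed=20120701)


@pytest.fixture(scope="session")
def default_trial(default_config):
    return generate_trial(default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(987654321)


def make_small_survival(rng, n_per_arm=15, scale_t=400.0, scale_c=400.0, censor=900.0):
    """Random small two-arm survival dataset for oracle cross-checks."""
    t = np.concatenate(
        [rng.exponential(scale_t, n_per_arm), rng.exponential(scale_c, n_per_arm)]
    )
    c = rng.uniform(0, censor, 2 * n_per_arm)
    times = np.minimum(t, c)
    events = (t <= c).astype(int)
    arm = np.array(["treatment"] * n_per_arm + ["control"] * n_per_arm)
    if events.sum() == 0:  # ensure at least one event
        events[0] = 1
    return times, events, arm
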