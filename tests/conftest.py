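import numpy as np
import pytest

import imitkin as ik


@pytest.fixture(scope="session")
def tn_noiseless():
    """Noiseless, jitter-free Normal-tempo trial: 1.25 s, 150 mm, flat."""
    spec = ik.make_condition_spec("TN")
    return ik.simulate_trial(
        spec, ik.GroupEffectSpec(), noise_sd=0.0,
        rng=np.random.default_rng(0), jitter_scale=0.0,
    )


@pytest.fixture(scope="session")
def planted_table():
    """30 x 40 SD table with features {16, 29, 37} planted at effect 2.5."""
    return ik.simulate_feature_table(14, 16, 40, {16, 29, 37}, 2.5, seed=11)


def minjerk_series(duration=1.25, amplitude=150.0, rate=120.0):
    """Pure minimum-jerk position samples over [0, duration], no rest."""
    n = int(round(duration * rate)) + 1
    tau = np.arange(n) / (n - 1)
    return np.arange(n) / rate, amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
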