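import numpy as np
import pytest

from cardiomir.refractory import build_schedule
from cardiomir.simulate import APWaveformParams


@pytest.fixture
def default_schedule():
    """Standard S1-S2 scan: 1000 -> 250 ms, step 50, 20 s blocks at 0.5 Hz."""
    return build_schedule(step=50.0)


@pytest.fixture
def square_ap_params():
    """Noiseless piecewise-linear AP with analytic APD90 = 380 ms."""
    return APWaveformParams(
        baseline=1.0,
        amplitude=1.0,
        upstroke_duration=0.0,
        plateau_duration=200.0,
        repolarization_duration=200.0,
        beat_interval=640.0,
        n_beats=10,
        sampling_interval=1.0,
        noise_sd=0.0,
        drift_per_s=0.0,
        rng_seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
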