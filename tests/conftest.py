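import numpy as np
import pytest

from nirsblock import (
    NoiseModel,
    SimTruth,
    build_schedule,
    default_mbll_params,
    default_montage,
    simulate_recording,
)


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def montage_5hz():
    return default_montage(sampling_rate_hz=5.0)


@pytest.fixture(scope="session")
def schedule():
    return build_schedule(seed=1)


@pytest.fixture(scope="session")
def mbll_params(montage):
    return default_mbll_params(montage)


@pytest.fixture(scope="session")
def noiseless_recording(montage_5hz, schedule):
    """Noise-free forward simulation: one condition map, no motion."""
    truth = SimTruth(seed=11)
    raw, hb, log = simulate_recording(
        truth, NoiseModel.silent(), schedule, montage_5hz, seed=11
    )
    return raw, hb, truth


@pytest.fixture(scope="session")
def noisy_recording(montage_5hz, schedule):
    truth = SimTruth(seed=12)
    raw, hb, log = simulate_recording(truth, NoiseModel(), schedule, montage_5hz, seed=12)
    return raw, hb, truth
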