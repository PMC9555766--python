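import numpy as np
import pytest

from sprintcoord import AnalysisConfig, SimConfig, generate_trial
from sprintcoord.io import AngleSeries, GaitEvent, Trial


@pytest.fixture
def analysis_config():
    return AnalysisConfig()


@pytest.fixture
def unfiltered_config():
    return AnalysisConfig(lowpass_cutoff=None)


@pytest.fixture
def sim_config():
    """Small noise-free cohort for pipeline tests."""
    return SimConfig(
        n_participants=3,
        n_steps=4,
        noise_sd=0.0,
        rng_seed=7,
    )


@pytest.fixture
def trial(sim_config):
    return generate_trial(sim_config, 0)


def make_ramp_trial(duration=1.2, fs=200.0, slope=10.0):
    """Trial whose segments are linear ramps; simple analytic baseline."""
    n = int(duration * fs) + 1
    values = slope * np.arange(n) / fs
    series = {}
    from sprintcoord.io import SEGMENTS

    for i, seg in enumerate(SEGMENTS):
        series[seg] = AngleSeries(seg, fs, values * (1 + 0.1 * i))
    events = [
        GaitEvent("toe_off", 0.10, "right", "TO_0"),
        GaitEvent("touchdown", 0.42, "left", "TD_1"),
        GaitEvent("toe_off", 0.62, "left", "TO_1"),
        GaitEvent("touchdown", 0.70, "right", "TD_2"),
        GaitEvent("toe_off", 0.89, "right", "TO_2"),
    ]
    return Trial("ramp", series, events, front_block_side="right")


@pytest.fixture
def ramp_trial():
    return make_ramp_trial()
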