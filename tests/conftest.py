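"""Shared fixtures: cheap synthetic subjects and recordings.

Recordings default to 500 Hz (instead of the 1 kHz acquisition rate) to
keep the suite fast; rate-sensitive tests set their own rate.
"""

from dataclasses import replace

import numpy as np
import pytest

from cardiovar.synthetic import (
    NoiseLevels,
    make_group_params,
    simulate_baseline_recording,
)


@pytest.fixture(scope="session")
def ctl_params():
    return make_group_params("CTL", seed=1)


@pytest.fixture(scope="session")
def ctl_baseline(ctl_params):
    """CTL baseline recording at default noise, 500 Hz, 180 s."""
    return simulate_baseline_recording(ctl_params, 180.0, 500.0, seed=1)


@pytest.fixture(scope="session")
def quiet_baseline(ctl_params):
    """Noise-free CTL baseline recording (exact-recovery oracle)."""
    params = replace(ctl_params, noise=NoiseLevels.zero())
    return simulate_baseline_recording(params, 180.0, 500.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
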