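"""Shared fixtures: the expensive reference signals are built once."""

import numpy as np
import pytest

import phasegram as ph


@pytest.fixture(scope="session")
def logistic_sweep() -> ph.TimeSeries:
    """The 10 s logistic-map sweep (a: 3.4 -> 3.65) upsampled to 44.1 kHz."""
    return ph.gen_logistic(ph.LogisticSweepSpec())


@pytest.fixture(scope="session")
def lorenz_sweep() -> ph.TimeSeries:
    """The swept Lorenz run (r: 250 -> 28 over 7 s playback, 3 s hold)."""
    return ph.gen_lorenz(ph.LorenzSweepSpec())


@pytest.fixture(scope="session")
def twomass_sweep():
    """Asymmetric (Q=0.51) two-mass run under a 0 -> 2.5 -> 0 kPa ramp."""
    profile = ph.PressureProfile.triangular(2.5, 10.0)
    left, right = ph.simulate(ph.TwoMassParams(q=0.51), profile,
                              duration_s=10.0)
    return left, right, profile


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
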