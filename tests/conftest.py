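import numpy as np
import pytest

from cogrnn import (MaskSet, NetworkSpec, PerceptualDiscrimination,
                    PerceptualDiscriminationConfig, WeightSet)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pd_task():
    """Short perceptual-discrimination task for fast unit tests."""
    return PerceptualDiscrimination(PerceptualDiscriminationConfig(
        coherences=(0.7, 0.5, 0.3, 0.1), fixation_duration=100.0,
        stimulus_duration=400.0, response_duration=100.0))


@pytest.fixture
def integrator_network():
    """Hand-built evidence integrator that solves perceptual discrimination.

    Two rectified units with identity recurrence perfectly accumulate the
    positive part of the momentary evidence for their preferred direction;
    the readout is the unit activity itself.  Synthetic stand-in for a
    trained network in analyses that only need competent, monotonic
    behavior.
    """
    spec = NetworkSpec(n_in=2, n_rec=2, n_out=2, dt=10.0, tau=100.0,
                       sigma_rec=0.0, transfer="relu")
    g = 1.0
    w = WeightSet(
        W_in_raw=np.array([[g, -g], [-g, g]]),
        W_rec_raw=np.eye(2),
        W_out_raw=np.eye(2),
        b_rec=np.zeros(2),
        b_out=np.zeros(2),
        x0=np.zeros(2),
    )
    m = MaskSet.all_to_all(spec)
    return w, m, spec
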