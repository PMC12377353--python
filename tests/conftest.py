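import numpy as np
import pytest

from emgcycle import ActivationModel, MovementProtocol, generate_trial
from emgcycle.kinematics import PHASE_ORDER


@pytest.fixture(scope="session")
def jitterfree_trial():
    """One deterministic 10-cycle trial at 60 bpm with no timing jitter."""
    protocol = MovementProtocol(bpm=60, n_cycles=10, cycle_jitter=0.0)
    return generate_trial(protocol, seed=0)


@pytest.fixture(scope="session")
def uniform_model():
    """Activation model with the same antagonist fraction in every phase."""
    return ActivationModel(
        antagonist_frac={p: 0.5 for p in PHASE_ORDER}, tonic_triceps=0.0, noise_floor=0.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
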