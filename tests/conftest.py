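"""Shared fixtures: synthetic study sessions and a trained regressor.

The heavy fixtures are session-scoped so the regressor is trained once and
reused across the regression, control, protocol and acceptance tests.
"""

import numpy as np
import pytest

import myogym
from myogym.regressor import TrainConfig


@pytest.fixture(scope="session")
def ortho_params():
    """Orthogonal-pattern, low-noise generator settings: the separable
    study condition used for parameter-recovery checks."""
    return myogym.GeneratorParams(
        seed=11, overlap=0.0, noise=0.02, amplitude_jitter=0.0
    )


@pytest.fixture(scope="session")
def ortho_session(ortho_params):
    """Three recording procedures covering all seven movements."""
    return myogym.generate_session(
        ortho_params, list(myogym.MOVEMENTS), n_procedures=3
    )


@pytest.fixture(scope="session")
def trained_model(ortho_session):
    """Regressor trained on the orthogonal-pattern session."""
    recordings = [r for p in ortho_session for r in p.recordings]
    return myogym.train_from_recordings(
        recordings, list(myogym.MOVEMENTS), TrainConfig(seed=5)
    )


@pytest.fixture(scope="session")
def tiny_two_movement_model():
    """A quick two-movement model for cheap behavioural tests."""
    params = myogym.GeneratorParams(
        seed=21, overlap=0.0, noise=0.02, amplitude_jitter=0.0
    )
    movements = ["fine_pinch", "hand_open"]
    session = myogym.generate_session(params, movements, n_procedures=2)
    recordings = [r for p in session for r in p.recordings]
    return myogym.train_from_recordings(
        recordings, movements, TrainConfig(seed=3)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
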