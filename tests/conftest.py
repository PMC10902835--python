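import numpy as np
import pytest

from cavityfluc.forcefield import SolventFrame, mw_params
from cavityfluc.theory import TheoryInputs


@pytest.fixture(scope="session")
def mw():
    return mw_params()


@pytest.fixture
def rng():
    return np.random.default_rng(20230712)


@pytest.fixture(scope="session")
def ambient():
    """mW water at 25 °C and 1 atm with the fitted interface parameters."""
    return TheoryInputs(gamma=66.3, delta=0.83)


@pytest.fixture
def frame_factory(rng):
    """Random frames with a comfortably large box for minimum-image safety."""

    def make(n_particles: int, box: float = 12.0, seed=None) -> SolventFrame:
        r = np.random.default_rng(seed) if seed is not None else rng
        return SolventFrame(
            positions=r.uniform(0.0, box, size=(n_particles, 3)),
            box_lengths=np.full(3, box),
            cavity_center=np.full(3, box / 2.0),
        )

    return make
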