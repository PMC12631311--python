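import numpy as np
import pytest

from mutadyn.synthetic import TwoStateSpec, gen_two_state_trajectory, synthetic_basis_set


@pytest.fixture(scope="session")
def basis3():
    return synthetic_basis_set("synthetic-3")


@pytest.fixture(scope="session")
def basis6():
    return synthetic_basis_set("synthetic-6")


@pytest.fixture(scope="session")
def small_two_state():
    """40-frame noiseless two-state trajectory with ground-truth labels."""
    spec = TwoStateSpec(n_frames=40, seed=3, noise_sigma=0.0, distance_sd=0.0)
    traj, states = gen_two_state_trajectory(spec)
    return spec, traj, states


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
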