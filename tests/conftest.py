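import numpy as np
import pytest

import apjbias as ab


@pytest.fixture(scope="session")
def toy_receptor():
    return ab.make_toy_receptor(n_residues=60, pair_distance_A=3.0)


@pytest.fixture(scope="session")
def short_traj(toy_receptor):
    spec = ab.TrajectorySpec(n_frames=200, pair_mean_A=3.0, pair_sd_A=0.1,
                             seed=7)
    return ab.make_trajectory(spec, toy_receptor)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
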