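import numpy as np
import pytest
from hypothesis import settings

import unfoldscape as u

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """30-residue toy native: (topology, coords, segment labels)."""
    return u.make_toy_native(30, seed=0)


@pytest.fixture(scope="session")
def small_scenario():
    return u.UnfoldingScenario(native_frames=60, exit_frame=60,
                               plateau_frames=100, disorder_frames=140,
                               frame_interval=0.1, seed=1)


@pytest.fixture(scope="session")
def unfolding_fixture(toy, small_scenario):
    """Small planted unfolding trajectory: (traj, ground_truth, native)."""
    top, native, seg = toy
    traj, truth = u.make_unfolding_trajectory(native, top, small_scenario, seg)
    return traj, truth, native


@pytest.fixture(scope="session")
def embedded_fixture(unfolding_fixture):
    """(distance matrix, embedding, step vectors) of the small trajectory."""
    traj, truth, native = unfolding_fixture
    D = u.pairwise_rmsd_matrix(traj)
    emb = u.classical_mds(D, k=3)
    steps = u.step_vectors(emb, traj.frame_interval)
    return D, emb, steps
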