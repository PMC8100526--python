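"""Shared fixtures: tiny hand-placed complexes with exactly controlled
hydrogen-bond geometry, and the bundled occupancy datasets."""

import numpy as np
import pytest

from mechbond.traj_io import Topology, Trajectory


def make_hbond_trajectory(da_distance, deviation_deg, n_frames=1):
    """Two-chain toy with one candidate N-H...O hydrogen bond at an exactly
    prescribed donor-acceptor distance (Å) and D-H...A deviation (deg).

    Chain A: GLY with donor N at the origin and H at (0, 1, 0).
    Chain B: GLY whose acceptor O sits so that the H→A direction makes the
    requested angle with D→H and |D−A| equals the requested distance.
    """
    gamma = np.radians(deviation_deg)
    h = np.array([0.0, 1.0, 0.0])
    u = np.array([np.sin(gamma), np.cos(gamma), 0.0])
    # solve |h + s·u| = d for s > 0
    b = 2.0 * np.dot(h, u)
    s = (-b + np.sqrt(b * b - 4.0 * (1.0 - da_distance**2))) / 2.0
    acceptor = h + s * u
    if deviation_deg == 0.0:
        acceptor = np.array([0.0, float(da_distance), 0.0])  # exact fp distance
    names = ["N", "H", "CA", "O", "C", "CA"]
    elements = ["N", "H", "C", "O", "C", "C"]
    chains = ["A", "A", "A", "B", "B", "B"]
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            h,
            [0.0, -1.5, 0.0],
            acceptor,
            acceptor + [0.0, 1.3, 0.0],
            acceptor + [0.0, 2.5, 0.5],
        ]
    )
    top = Topology(names, elements, ["GLY"] * 6, [1, 1, 1, 2, 2, 2], chains)
    return Trajectory(top, np.repeat(coords[None], n_frames, axis=0))


def make_salt_bridge_trajectory(on_distance, oxygen_name="OD1", use_backbone_o=False):
    """ASP (chain A) / LYS (chain B) pair with the O–NZ distance prescribed.

    ``use_backbone_o=True`` puts the oxygen at the backbone O position/name
    instead of the side-chain carboxylate, to exercise the side-chain-only
    rule.
    """
    o_name = "O" if use_backbone_o else oxygen_name
    names_a = ["N", "CA", "CB", "CG", o_name]
    elements_a = ["N", "C", "C", "C", "O"]
    coords_a = np.array(
        [[0.0, -3.0, 0.0], [0.0, -2.0, 0.0], [0.0, -1.0, 0.0], [0.5, 0.0, 0.0], [0.0, 0.0, 0.0]]
    )
    names_b = ["NZ", "CE", "CA"]
    elements_b = ["N", "C", "C"]
    coords_b = np.array(
        [[0.0, on_distance, 0.0], [0.0, on_distance + 1.4, 0.0], [0.0, on_distance + 2.8, 0.0]]
    )
    top = Topology(
        names_a + names_b,
        elements_a + elements_b,
        ["ASP"] * 5 + ["LYS"] * 3,
        [1] * 5 + [2] * 3,
        ["A"] * 5 + ["B"] * 3,
    )
    return Trajectory(top, np.concatenate([coords_a, coords_b])[None])


def random_rigid_motion(rng):
    """A uniformly random proper rotation and a random translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.normal(0.0, 50.0, size=3)
    return R, t


@pytest.fixture(scope="session")
def model_table():
    from mechbond.datasets import load_model_occupancies

    return load_model_occupancies()


@pytest.fixture(scope="session")
def force_panel():
    from mechbond.datasets import load_force_panel

    return load_force_panel()


@pytest.fixture()
def toy_trajectory():
    from mechbond.synthetic import BondSpec, gen_interface_trajectory

    traj, truth = gen_interface_trajectory(
        [BondSpec(0.6, switching_rate=0.8), BondSpec(0.3, switching_rate=0.8)],
        n_frames=50,
        seed=11,
    )
    return traj, truth
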