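import numpy as np
import pytest

import memgate as mg


@pytest.fixture(scope="session")
def gating_traj():
    """Two-state gating trajectory with well-separated states."""
    params = mg.GatingParams(n_frames=600, seed=11)
    traj, truth = mg.gen_gating_trajectory(params)
    return traj, truth, params


@pytest.fixture(scope="session")
def funnel_traj():
    params = mg.FunnelParams(seed=7)
    traj, truth = mg.gen_funnel_bilayer(params)
    return traj, truth, params


@pytest.fixture(scope="session")
def phantom():
    structure, truth = mg.gen_tunnel_phantom(bore_radius=3.0)
    return structure, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20)


def random_rotation(rng):
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def random_structure(rng, n_atoms=60):
    """Random structure with varied names/resnames/chains for selection tests."""
    names = rng.choice(["CA", "CB", "OW", "N", "CH2", "FE"], size=n_atoms)
    resnames = rng.choice(["ALA", "TRP", "HOH", "HEM"], size=n_atoms)
    chains = rng.choice(["A", "B"], size=n_atoms)
    atoms = [
        mg.AtomRecord(
            i + 1, str(names[i]), str(resnames[i]), int(rng.integers(1, 40)),
            str(chains[i]), "C", 1.7,
        )
        for i in range(n_atoms)
    ]
    return mg.Structure(atoms, rng.normal(scale=10.0, size=(n_atoms, 3)))
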