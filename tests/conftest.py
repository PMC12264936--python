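import numpy as np
import pytest

from vligand.backends import SyntheticSurfaceSpec
from vligand.descriptors import builtin_ligand_db
from vligand.geometry import MolecularGeometry
from vligand.vl_model import DEFAULT_BOUNDS


@pytest.fixture(scope="session")
def phosphine_db():
    return builtin_ligand_db()


@pytest.fixture(scope="session")
def bounds():
    return DEFAULT_BOUNDS


@pytest.fixture
def affine_spec():
    """Exact-oracle descriptor surface: affine G, pure quadratic objective."""
    return SyntheticSurfaceSpec(n=3, m=16, seed=1)


@pytest.fixture
def warped_spec():
    """Mildly nonlinear descriptor surface (quadratic warp)."""
    return SyntheticSurfaceSpec(n=3, m=16, warp=0.3, seed=4)


@pytest.fixture
def bump_spec():
    """Objective with a smooth bump so a quadratic surrogate degrades away
    from its anchor; minimum near the center of the standard bounds."""
    return SyntheticSurfaceSpec(
        n=3, m=16, bump_amplitude=2.0, center=[1.5, 2.6, 2.1],
        offset=-25.0, seed=7,
    )


def make_pcl3_geometry(n_env=4, seed=3, env_shift=(0.0, 0.0, 4.0)):
    """A PCl*3 core with a few randomly placed environment atoms."""
    rng = np.random.default_rng(seed)
    p = np.zeros(3)
    cl = np.array([[1.6, 0.1, -0.2], [0.3, 1.5, 0.4], [-0.9, -0.8, 1.2]])
    env = rng.uniform(-4, 4, (n_env, 3)) + np.asarray(env_shift)
    coords = np.vstack([p, cl, env])
    symbols = ["P", "Cl", "Cl", "Cl"] + ["C"] * n_env
    return MolecularGeometry(symbols, coords, 0, (1, 2, 3))


@pytest.fixture
def pcl3_geometry():
    return make_pcl3_geometry()
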