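import numpy as np
import pytest

from earmorph.io_formats import parse_newick
from earmorph.synthetic import MorphoArchetype, simulate_tree


def analytic_spiral(T, r0=2.0, k=0.3, H=4.0, n=1300, u=0.0):
    """Noiseless conical-exponential spiral sampled uniformly in s."""
    s = np.linspace(0.0, 1.0, n)
    theta = 2.0 * np.pi * T * s
    r = r0 * np.exp(-k * s)
    z = H * s
    if u:
        basal = s <= 1.0 / T
        z = z + np.where(basal, u * np.sin(2.0 * np.pi * T * s), 0.0)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def random_rotation(rng):
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def balanced_tree():
    return parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture(scope="session")
def tree33():
    return simulate_tree(33, seed=11, root_age=75.0)


@pytest.fixture(scope="session")
def archetype():
    return MorphoArchetype(name="t", turns=2.5, basal_radius=1.5,
                           radius_decay=0.4, height=3.5, tube_radius0=0.55,
                           tube_taper=0.45, undulation=0.12)
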