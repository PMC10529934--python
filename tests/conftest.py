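import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cagefield import CageSpec, gen_cage_system

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cage():
    """A compact synthetic cage system shared across read-only tests."""
    spec = CageSpec(seed=7, n_frames=6, n_cage_dipoles=10, n_solvent=8)
    atoms, traj, truth = gen_cage_system(spec)
    return spec, atoms, traj, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform random proper rotation matrix (QR with sign fix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
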