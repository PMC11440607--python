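import numpy as np
import pytest
from hypothesis import settings

from tcagedyn import BodyRange, RigidBodySpec, SimSpec, generate_hinge_trajectory

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def two_body_spec() -> RigidBodySpec:
    """Two 30-residue rigid bodies joined by an 8-residue flexible linker."""
    return RigidBodySpec(
        bodies=[BodyRange(1, 30, 0.2), BodyRange(39, 68, 0.2)],
        linkers=[BodyRange(31, 38, 3.0)],
        hinge_amplitude=30.0,
    )


@pytest.fixture
def two_body_traj(two_body_spec):
    return generate_hinge_trajectory(two_body_spec, SimSpec(n_frames=200, seed=7))


def k_body_spec(k: int, body_jitter: float = 0.2,
                linker_jitter: float = 3.0) -> RigidBodySpec:
    """K 30-residue bodies with 8-residue flexible linkers between them."""
    return RigidBodySpec(
        bodies=[BodyRange(1 + 39 * i, 30 + 39 * i, body_jitter)
                for i in range(k)],
        linkers=[BodyRange(31 + 39 * i, 38 + 39 * i, linker_jitter)
                 for i in range(k - 1)],
        hinge_amplitude=30.0,
    )


def random_symmetric_matrix(rng: np.random.Generator, n: int,
                            scale: float = 5.0) -> np.ndarray:
    """Random non-negative symmetric matrix with zero diagonal."""
    m = rng.uniform(0.0, scale, size=(n, n))
    m = np.triu(m, 1)
    m = m + m.T
    return m
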