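import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

import mtoligo as m


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def straight_path():
    """500-nm plus-polarity z-axis filament, 7-nm spacing."""
    return m.straight_path(500.0, 7.0, filament_id=0, polarity="plus")


@pytest.fixture(scope="session")
def paper_fixture():
    """The seeded sparse-ring fixture used by the headline analyses."""
    return m.make_fixture("paper-like", n_filaments=20, rng_seed=42,
                          filament_length=500.0)


@pytest.fixture(scope="session")
def paper_results(paper_fixture):
    return m.OligomerChainModel(paper_fixture.table, paper_fixture.paths).fit()


def random_rotations(rng, n):
    """Uniform random rotation matrices without scipy (for oracle independence)."""
    # quaternion method
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y**2 + z**2), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
            np.stack([2 * (x * y + z * w), 1 - 2 * (x**2 + z**2), 2 * (y * z - x * w)], -1),
            np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x**2 + y**2)], -1),
        ],
        axis=1,
    )
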