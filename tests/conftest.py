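import numpy as np
import pytest

from spineret.synthetic import SyntheticSpec, make_dataset


@pytest.fixture(scope="session")
def cervical_dataset():
    """Small cervical dataset shared by pipeline-level tests."""
    return make_dataset(SyntheticSpec(region="cervical", per_class=3, seed=7))


@pytest.fixture(scope="session")
def lumbar_dataset():
    return make_dataset(SyntheticSpec(region="lumbar", per_class=5, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_smooth_contour(rng, n=64, base_radius=10.0):
    """Random star-shaped smooth closed contour (low-order harmonics)."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = base_radius * (
        1.0
        + 0.25 * rng.uniform(-1, 1) * np.cos(2 * t + rng.uniform(0, 2 * np.pi))
        + 0.15 * rng.uniform(-1, 1) * np.cos(3 * t + rng.uniform(0, 2 * np.pi))
        + 0.10 * rng.uniform(-1, 1) * np.cos(5 * t + rng.uniform(0, 2 * np.pi))
    )
    center = rng.uniform(-5, 5, size=2)
    return np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])
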