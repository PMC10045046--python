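import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    from lungcad import phantoms

    return phantoms.make_dataset(12, 0.5, image_size=48, seed=7)


def disk_mask(radius: int, size: int | None = None) -> np.ndarray:
    size = size or (2 * radius + 8)
    c = size / 2.0 - 0.5
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2
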