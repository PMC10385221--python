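import numpy as np
import pytest

from ripecolor import FixtureSpec, StageTable


@pytest.fixture
def table() -> StageTable:
    return StageTable()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230907)


@pytest.fixture
def small_spec() -> FixtureSpec:
    """Thumbnail-size fixtures keep the unit suite fast."""
    return FixtureSpec(image_size=96)


@pytest.fixture
def clean_spec() -> FixtureSpec:
    """Bias-free, noise-free fixtures for exact round-trip oracles."""
    return FixtureSpec(image_size=96, theta_jitter_sd=0.0, freckle_density=0.0,
                       camera_bias_deg=0.0, noise_sd=0.0)


def random_rgb(rng: np.random.Generator, h: int = 24, w: int = 24) -> np.ndarray:
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
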