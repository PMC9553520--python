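import numpy as np
import pytest

from octspeckle import (
    PhantomConfig,
    Region,
    RodSpec,
    TubeSpec,
    default_phantom_config,
    generate_phantom,
)


def _scaled_down_config(seed: int = 0) -> PhantomConfig:
    """A geometrically shrunken phantom (small tube/rod, fewer repeats) for
    fast unit tests; region speckle models are the packaged defaults."""
    base = default_phantom_config()
    return PhantomConfig(
        volume_shape=(60, 80, 24, 8),
        voxel_pitch=base.voxel_pitch,
        surface_depth=60.0,
        noise_floor_depth=375.0,
        tube=TubeSpec(center_depth=225.0, center_fast=180.0,
                      inner_diameter=120.0, outer_diameter=260.0),
        rod=RodSpec(center_depth=150.0, center_fast=450.0, diameter=140.0),
        region_models=dict(base.region_models),
        seed=seed,
    )


@pytest.fixture(scope="session")
def paper_config() -> PhantomConfig:
    return default_phantom_config()


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    return _scaled_down_config()


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return generate_phantom(small_config, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def rayleigh_sample(
    rng: np.random.Generator, n: int, b: float = 1.0, c: float = 0.0
) -> np.ndarray:
    """Shifted Rayleigh draws via the modulus of a complex Gaussian."""
    return c + b * np.hypot(*rng.standard_normal((2, n)))
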