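from __future__ import annotations

import numpy as np
import pytest

from ihf3d.phantoms import PhantomConfig, build_fixture
from ihf3d.preprocess import PreprocessConfig
from ihf3d.volume_io import Volume


@pytest.fixture(scope="session")
def small_phantom_config() -> PhantomConfig:
    """Reduced-size phantom grid used by most tests to keep the suite fast."""
    return PhantomConfig(shape=(32, 32, 24))


@pytest.fixture(scope="session")
def mri_pre() -> PreprocessConfig:
    return PreprocessConfig(modality="MRI")


@pytest.fixture(scope="session")
def small_fixture(small_phantom_config):
    """A small frozen challenge fixture: 20 train / 12 ID test / 12 OOD (intensity shift)."""
    return build_fixture(small_phantom_config, 20, 12, 12, "intensity_shift", None, base_seed=123)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_volume(rng: np.random.Generator, shape=(6, 5, 4), spacing=(1.0, 1.0, 1.5)) -> Volume:
    return Volume(data=rng.normal(size=shape), spacing=spacing)
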