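"""Shared fixtures: small random profiles, generator configs, reference data."""

from pathlib import Path

import numpy as np
import pytest

from nucloc.io_formats import Profile
from nucloc.profile_kernel import KernelParams
from nucloc.synthetic_data import GeneratorConfig

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_profile(rng: np.random.Generator, length: int = 8, pid: str = "p", scale: float = 1.0) -> Profile:
    return Profile(pid, rng.uniform(0.0, 2.0 * scale, size=(length, 20)))


@pytest.fixture
def small_params() -> KernelParams:
    return KernelParams(k=2, sigma=1.5)


@pytest.fixture
def tiny_gen_config() -> GeneratorConfig:
    """Scaled-down study conditions for fast unit tests."""
    return GeneratorConfig(n_classes=4, n_per_class=6, profile_length=40, seed=7)


@pytest.fixture
def study_config() -> GeneratorConfig:
    """The full synthetic study conditions (13 classes x 20 proteins)."""
    return GeneratorConfig(seed=1)
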