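import numpy as np
import pytest

from forkspeed import GenomeGeometry, ReplisomeModel
from forkspeed.presets import reference_k, reference_model


@pytest.fixture(scope="session")
def mini_geometry() -> GenomeGeometry:
    """200-kbp toy circle: 20 bins, origin off-center so both arms differ."""
    return GenomeGeometry(length_bp=200_000.0, origin_bp=60_000.0, bin_bp=10_000.0)


@pytest.fixture(scope="session")
def full_geometry() -> GenomeGeometry:
    from forkspeed import MG1655

    return MG1655


@pytest.fixture(scope="session")
def model_37() -> ReplisomeModel:
    return reference_model(37)


@pytest.fixture(scope="session")
def k_37() -> float:
    return reference_k(37)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
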