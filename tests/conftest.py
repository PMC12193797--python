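import numpy as np
import pytest

from luces.raster import RasterGrid
from luces.synth import SyntheticConfig, generate_landscape


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(shape=(64, 64), seed=11)


@pytest.fixture(scope="session")
def landscape(small_config):
    """One 64x64 synthetic landscape shared by read-only tests."""
    return generate_landscape(small_config)


@pytest.fixture
def toy_lulc() -> RasterGrid:
    """Deterministic 10x10 categorical map covering all six classes."""
    rng = np.random.default_rng(5)
    vals = rng.integers(1, 7, size=(10, 10)).astype(np.int16)
    return RasterGrid(vals, cell_size_m=100.0, nodata=0, categorical=True)
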