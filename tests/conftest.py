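import numpy as np
import pytest

from plvnet.atlas import NetworkAtlas, ROIEntry
from plvnet.bands import DEFAULT_BANDS


@pytest.fixture
def toy_atlas() -> NetworkAtlas:
    """Six ROIs: 3 DMN, 2 FPN, 1 SMN (per-network sizes {3, 2, 1})."""
    return NetworkAtlas(
        [
            ROIEntry("A1", "DMN", "L"),
            ROIEntry("A2", "DMN", "R"),
            ROIEntry("A3", "DMN", "L"),
            ROIEntry("B1", "FPN", "L"),
            ROIEntry("B2", "FPN", "R"),
            ROIEntry("C1", "SMN", "L"),
        ]
    )


@pytest.fixture
def alpha_only():
    """Single-band list, used where one planted band is enough."""
    return tuple(b for b in DEFAULT_BANDS if b.name == "alpha")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
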