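import numpy as np
import pytest

from chromamotion import stimulus


@pytest.fixture(scope="session")
def uniform_calib():
    """Spatially uniform display calibration with the standard 2.3 scale."""
    return stimulus.CalibrationMap.uniform()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
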