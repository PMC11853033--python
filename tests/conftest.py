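import numpy as np
import pytest

from lumipath import (
    LuminanceBand,
    LuminanceMap,
    MeasurementField,
    fixture_lmax_table2,
)
from lumipath.phantom import FIXTURE_THRESHOLDS


@pytest.fixture
def lesion_band():
    return LuminanceBand("neoplastic", 630.0, 2000.0, (0, 0, 220))


@pytest.fixture
def healthy_band():
    return LuminanceBand("no_lesions", 0.0, 630.0, (0, 170, 0))


@pytest.fixture
def two_bands(healthy_band, lesion_band):
    return [healthy_band, lesion_band]


@pytest.fixture
def fixture_records():
    return fixture_lmax_table2()


@pytest.fixture
def fixture_thresholds():
    return FIXTURE_THRESHOLDS


@pytest.fixture
def uniform_map():
    """10x10 constant 500 cd/m² map with a whole-image field."""
    lum = LuminanceMap(np.full((10, 10), 500.0))
    return lum, MeasurementField.whole_image(lum)


def make_map(values, **kwargs):
    return LuminanceMap(np.asarray(values, dtype=float), **kwargs)
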