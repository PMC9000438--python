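import numpy as np
import pytest

from irpreclass import (
    SpectralDataset,
    default_axis,
    make_cartilage_spectrum,
    make_water_reference,
)


@pytest.fixture(scope="session")
def axis():
    """Full instrument axis: 400–4000 cm⁻¹ at 1.0292 cm⁻¹ spacing."""
    return default_axis()


@pytest.fixture(scope="session")
def short_axis():
    """Fingerprint-plus-noise-window axis for fast tests."""
    return default_axis(650.0, 2200.0)


@pytest.fixture(scope="session")
def water_ref(short_axis):
    return make_water_reference(short_axis)


@pytest.fixture(scope="session")
def cartilage_sig(short_axis):
    return make_cartilage_spectrum(short_axis)


@pytest.fixture()
def toy_dataset():
    """3 spectra × 5 channels with easily recognisable values."""
    ax = np.array([800.0, 900.0, 1000.0, 1100.0, 1200.0])
    m = np.arange(15, dtype=float).reshape(3, 5) / 10.0
    return SpectralDataset(ax, m, ["s1", "s2", "s3"])
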