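import numpy as np
import pytest

from mnalci.spectra_io import RawSpectrum


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def gaussian_spectrum(
    center: float = 180.16,
    fwhm: float = 0.3,
    height: float = 100.0,
    grid_step: float = 0.05,
    mz_lo: float = 100.0,
    mz_hi: float = 1000.0,
    sample_id: str = "S1",
    matrix_tag: str = "GNS",
) -> RawSpectrum:
    """Noise-free Gaussian peak on a uniform grid."""
    mz = np.arange(mz_lo, mz_hi + grid_step / 2, grid_step)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    intensity = height * np.exp(-0.5 * ((mz - center) / sigma) ** 2)
    return RawSpectrum(sample_id=sample_id, matrix_tag=matrix_tag, mz=mz, intensity=intensity)
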