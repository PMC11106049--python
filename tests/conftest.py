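import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from osmactools.ecd_sim import BandShapeParams, SpectrumGrid


@pytest.fixture
def coarse_params() -> BandShapeParams:
    """Band-shape parameters on a 1 nm grid, fast enough for loops."""
    return BandShapeParams(grid_step=1.0)


@pytest.fixture
def gaussian_spectrum():
    """Factory for analytic Gaussian-band spectra on a shared grid."""

    def make(centers, amplitudes, width_nm=4.0, grid=(190.0, 320.0, 0.5)):
        lo, hi, step = grid
        wl = np.arange(lo, hi + step / 2, step)
        vals = np.zeros_like(wl)
        for c, a in zip(centers, amplitudes):
            vals += a * np.exp(-(((wl - c) / width_nm) ** 2))
        return SpectrumGrid(wl, vals, {"provenance": "synthetic"})

    return make
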