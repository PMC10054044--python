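import numpy as np
import pytest

from adlsfc import ChannelGeometry, FlowConfig, PupilSpec
from adlsfc.units import UM


@pytest.fixture(scope="session")
def geom():
    return ChannelGeometry()


@pytest.fixture(scope="session")
def flow():
    """Paper bench point: Qj = Qs = 1 uL/h, mean-channel velocity model."""
    return FlowConfig.from_ul_per_h(1.0, 1.0)


@pytest.fixture(scope="session")
def flow_fast():
    """High-throughput bench point: Qj = Qs = 20 uL/h."""
    return FlowConfig.from_ul_per_h(20.0, 20.0)


@pytest.fixture(scope="session")
def spec256():
    """Small pupil grid for fast Fourier-optics tests (no axicon defocus)."""
    return PupilSpec(grid_size=256)


@pytest.fixture(scope="session")
def spec512_bg():
    """Full-size grid with the Gaussian Bessel-Gaussian envelope."""
    return PupilSpec(grid_size=512, envelope_waist=0.6 * 2.5e-3)


@pytest.fixture(scope="session")
def calibrated_axicon(spec512_bg):
    """tan(alpha) tuned once per session for a 0.8 um lobe at z_w = 85 um."""
    from adlsfc.optics import calibrate_axicon

    return calibrate_axicon(spec512_bg, 0.8 * UM, 85 * UM)


def fwhm_1d(profile: np.ndarray, step: float = 1.0) -> float:
    """Brute-force half-max width of a 1D profile (test oracle)."""
    p = np.asarray(profile, dtype=float)
    j = int(np.argmax(p))
    half = p[j] / 2.0
    a = j
    while a > 0 and p[a] > half:
        a -= 1
    b = j
    while b < len(p) - 1 and p[b] > half:
        b += 1
    xa = a + (half - p[a]) / (p[a + 1] - p[a])
    xb = b - (half - p[b]) / (p[b - 1] - p[b])
    return (xb - xa) * step
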