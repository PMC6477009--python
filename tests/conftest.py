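import numpy as np
import pytest

from mapkit.mapping import MotorMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def gaussian_disc_map(spacing: float, area_cm2: float = 4.0,
                      sigma: float = 8.0, extent: float = 40.0,
                      criterion: float = 50.0) -> MotorMap:
    """Planar map sampling a Gaussian amplitude field whose
    super-threshold (>= criterion) footprint is a disc of known area."""
    r_c = np.sqrt(area_cm2 / np.pi) * 10.0      # contour radius, mm
    a_max = criterion * np.exp(r_c ** 2 / (2 * sigma ** 2))
    n = int(extent // spacing) + 1
    off = (np.arange(n) - (n - 1) / 2) * spacing
    xx, yy = np.meshgrid(off, off)
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    r = np.hypot(pts[:, 0], pts[:, 1])
    amp = a_max * np.exp(-r ** 2 / (2 * sigma ** 2))
    amp[amp < 20.0] = 0.0                        # generator noise floor
    return MotorMap("disc", "L", "APB", pts, amp)


@pytest.fixture
def disc_map():
    return gaussian_disc_map
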