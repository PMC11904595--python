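import numpy as np
import pytest

from golgiredox.calibration import fit_calibration
from golgiredox.synth import simulate_calibration_plate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def exact_curve():
    """Saturating calibration fitted to noiseless points from
    (r0=1, r_max=5, k_half=2 mM)."""
    points = simulate_calibration_plate(
        1.0,
        5.0,
        2.0e-3,
        concentrations=[0.25e-3, 0.5e-3, 1e-3, 2e-3, 4e-3, 8e-3],
        rel_noise=0.0,
        seed=0,
    )
    return fit_calibration(points)


def disk_image(shape, centers, radius, value, background=0.0):
    """Test image: disks of a given value on a flat background."""
    img = np.full(shape, float(background))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = value
    return img


@pytest.fixture
def make_disks():
    return disk_image
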