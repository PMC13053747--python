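import numpy as np
import pytest

from lidwiper.maps import MapMetadata, ThicknessMap
from lidwiper.zernike import basis_matrix, n_terms


def disk_grid(radius=2.5, step=0.1):
    """Cartesian grid restricted to the closed disk of the given radius."""
    axis = np.arange(-radius, radius + step / 2, step)
    xx, yy = np.meshgrid(axis, axis)
    keep = np.hypot(xx, yy) <= radius
    return xx[keep], yy[keep]


def make_map(values, x, y, eye="OD", subject="S000", date="2024-01-01",
             frame="native", scan="0", mask=None):
    meta = MapMetadata(subject_id=subject, eye=eye, date=date, device="test",
                       frame=frame, scan_id=scan)
    if mask is None:
        mask = np.isfinite(np.asarray(values, dtype=float))
    return ThicknessMap(x=x, y=y, values=values, mask=mask, metadata=meta)


def render_map(coeffs, x, y, zone_radius=2.5, baseline=0.0, **kwargs):
    """Map whose thickness is an exact Zernike combination (plus a constant)."""
    coeffs = np.asarray(coeffs, dtype=float)
    A = basis_matrix(x, y, zone_radius, 5)
    return make_map(A @ coeffs + baseline, x, y, **kwargs)


@pytest.fixture(scope="session")
def zone_grid():
    return disk_grid(radius=2.5, step=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
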