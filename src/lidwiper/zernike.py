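"""ANSI/OSA-convention Zernike basis on the unit disk and NaN-aware map fitting.

The thickness map over the analytical zone is modelled as a linear combination
of normalized Zernike polynomials,

    T(rho, theta) = sum_j c_j Z_j(rho, theta),   rho = r / R_zone in [0, 1],

with the single-index ordering j = (n(n+2) + m) / 2 and the normalization
N(n, m) = sqrt(2(n+1) / (1 + [m == 0])), so that the basis is orthonormal
under the area-averaged inner product on the unit disk.  Negative azimuthal
frequencies are sine terms, positive are cosine terms.

Coefficients carry the units of the fitted field (micrometres here).  Fitting
is ordinary least squares over the valid samples inside the zone: masks and
irregular sampling break analytic orthogonality, but LSQ recovers in-span
signals exactly regardless of the sampling pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ZernikeIndex",
    "CoefficientVector",
    "ansi_index",
    "ansi_index_from_j",
    "ansi_indices",
    "n_terms",
    "zernike_value",
    "basis_matrix",
    "fit_map",
    "fit_samples",
    "reconstruct",
    "reconstruct_values",
]


@dataclass(frozen=True)
class ZernikeIndex:
    """Radial order ``n``, signed azimuthal frequency ``m``, ANSI index ``j``."""

    n: int
    m: int
    j: int

    def __post_init__(self) -> None:
        _validate_nm(self.n, self.m)
        expected = (self.n * (self.n + 2) + self.m) // 2
        if self.j != expected:
            raise ValueError(
                f"inconsistent ANSI index: (n={self.n}, m={self.m}) implies "
                f"j={expected}, got j={self.j}"
            )


def _validate_nm(n: int, m: int) -> None:
    if n < 0:
        raise ValueError(f"radial order must be >= 0, got n={n}")
    if abs(m) > n:
        raise ValueError(f"azimuthal frequency out of range: (n={n}, m={m}) has |m| > n")
    if (n - abs(m)) % 2 != 0:
        raise ValueError(f"invalid parity: (n={n}, m={m}) needs n - |m| even")


def ansi_index(n: int, m: int) -> ZernikeIndex:
    """Build the ANSI single-index triple for radial order ``n``, frequency ``m``."""
    _validate_nm(n, m)
    return ZernikeIndex(n=n, m=m, j=(n * (n + 2) + m) // 2)


def ansi_index_from_j(j: int) -> ZernikeIndex:
    """Inverse lookup: ANSI single index ``j`` back to the ``(n, m)`` pair."""
    if j < 0:
        raise ValueError(f"ANSI index must be >= 0, got j={j}")
    n = int(math.ceil((-3.0 + math.sqrt(9.0 + 8.0 * j)) / 2.0))
    m = 2 * j - n * (n + 2)
    return ZernikeIndex(n=n, m=m, j=j)


def n_terms(max_order: int) -> int:
    """Number of Zernike terms with radial order <= ``max_order``."""
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    return (max_order + 1) * (max_order + 2) // 2


def ansi_indices(max_order: int) -> list[ZernikeIndex]:
    """All indices with n <= max_order, in ANSI order j = 0, 1, 2, ..."""
    return [ansi_index_from_j(j) for j in range(n_terms(max_order))]


def _radial_poly(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    """R_n^|m|(rho) by the explicit factorial sum."""
    out = np.zeros_like(rho, dtype=float)
    for k in range((n - m_abs) // 2 + 1):
        coef = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m_abs) // 2 - k)
                * math.factorial((n - m_abs) // 2 - k)
            )
        )
        out += coef * rho ** (n - 2 * k)
    return out


def zernike_value(idx: ZernikeIndex, rho, theta):
    """Evaluate the normalized Zernike polynomial Z_j at (rho, theta [rad]).

    Accepts scalars or arrays; rho must lie in [0, 1].
    """
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1 + 1e-12):
        raise ValueError("normalized radius rho must lie in [0, 1]")
    n, m = idx.n, idx.m
    norm = math.sqrt(2.0 * (n + 1) / (1.0 + (1.0 if m == 0 else 0.0)))
    radial = _radial_poly(n, abs(m), np.clip(rho, 0.0, 1.0))
    if m > 0:
        angular = np.cos(m * theta)
    elif m < 0:
        angular = np.sin(abs(m) * theta)
    else:
        angular = np.ones_like(theta)
    val = norm * radial * angular
    return val if val.ndim else float(val)


def basis_matrix(x, y, zone_radius: float, max_order: int) -> np.ndarray:
    """Design matrix of basis values at Cartesian (x, y) mm; shape (npts, nterms)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    rho = np.hypot(x, y) / zone_radius
    theta = np.arctan2(y, x)
    cols = [zernike_value(idx, rho, theta) for idx in ansi_indices(max_order)]
    return np.column_stack(cols)


@dataclass
class CoefficientVector:
    """ANSI-ordered Zernike coefficients (um) for one map plus fit quality.

    ``coeffs[j]`` multiplies the normalized polynomial Z_j; for max_order 5
    there are 21 entries.  ``rmse`` is the root mean square residual of the
    fit (um) over the samples that participated; ``n_samples`` their count.
    """

    coeffs: np.ndarray
    zone_radius: float = 2.5
    max_order: int = 5
    rmse: float = 0.0
    n_samples: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float).ravel()
        expected = n_terms(self.max_order)
        if self.coeffs.size != expected:
            raise ValueError(
                f"expected {expected} coefficients for max_order={self.max_order}, "
                f"got {self.coeffs.size}"
            )
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")

    def coefficient(self, n: int, m: int) -> float:
        """Coefficient of the (n, m) term, in um."""
        return float(self.coeffs[ansi_index(n, m).j])


# Small cache of pseudo-inverses keyed by grid geometry so repeated fits on a
# shared grid (simulated cohorts) solve once.
_PINV_CACHE: dict[tuple, np.ndarray] = {}
_PINV_CACHE_MAX = 8


def _cached_pinv(x: np.ndarray, y: np.ndarray, zone_radius: float, max_order: int) -> np.ndarray:
    key = (hash(x.tobytes()), hash(y.tobytes()), x.size, round(zone_radius, 9), max_order)
    pinv = _PINV_CACHE.get(key)
    if pinv is None:
        A = basis_matrix(x, y, zone_radius, max_order)
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[1]:
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < {A.shape[1]} terms); "
                "sample the zone more densely or lower max_order"
            )
        pinv = np.linalg.pinv(A)
        if len(_PINV_CACHE) >= _PINV_CACHE_MAX:
            _PINV_CACHE.pop(next(iter(_PINV_CACHE)))
        _PINV_CACHE[key] = pinv
    return pinv


def fit_samples(
    x,
    y,
    values,
    zone_radius: float = 2.5,
    max_order: int = 5,
    metadata: dict | None = None,
) -> CoefficientVector:
    """Least-squares Zernike fit to scattered samples.

    Samples with non-finite value or radius > zone_radius are dropped row-wise.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    values = np.asarray(values, dtype=float).ravel()
    keep = np.isfinite(values) & (np.hypot(x, y) <= zone_radius + 1e-12)
    x, y, values = x[keep], y[keep], values[keep]
    k = n_terms(max_order)
    if x.size <= k:
        raise ValueError(
            f"need more than {k} valid in-zone samples to fit {k} coefficients, "
            f"got {x.size}"
        )
    pinv = _cached_pinv(x, y, zone_radius, max_order)
    coeffs = pinv @ values
    A = basis_matrix(x, y, zone_radius, max_order)
    resid = values - A @ coeffs
    rmse = float(np.sqrt(np.mean(resid**2)))
    return CoefficientVector(
        coeffs=coeffs,
        zone_radius=zone_radius,
        max_order=max_order,
        rmse=rmse,
        n_samples=int(x.size),
        metadata=dict(metadata or {}),
    )


def fit_map(tmap, zone_radius: float = 2.5, max_order: int = 5) -> CoefficientVector:
    """Fit a ThicknessMap (see :mod:`lidwiper.maps`); masked-out samples ignored."""
    values = np.where(tmap.mask, tmap.values, np.nan)
    meta = tmap.metadata.as_dict() if hasattr(tmap.metadata, "as_dict") else dict(tmap.metadata or {})
    return fit_samples(tmap.x, tmap.y, values, zone_radius, max_order, metadata=meta)


def reconstruct_values(coeffs: CoefficientVector, x, y) -> np.ndarray:
    """Evaluate the fitted surface at positions (x, y) mm inside the zone."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    r = np.hypot(x, y)
    if np.any(r > coeffs.zone_radius + 1e-12):
        raise ValueError(
            f"positions outside the {coeffs.zone_radius} mm zone cannot be reconstructed"
        )
    A = basis_matrix(x, y, coeffs.zone_radius, coeffs.max_order)
    return A @ coeffs.coeffs


def reconstruct(coeffs: CoefficientVector, x, y):
    """Reconstruct a ThicknessMap from coefficients on the given grid."""
    from .maps import MapMetadata, ThicknessMap

    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    values = reconstruct_values(coeffs, x, y)
    md = coeffs.metadata
    meta = MapMetadata(
        subject_id=str(md.get("subject_id", "reconstruction")),
        eye=str(md.get("eye", "OD")),
        date=str(md.get("date", "")),
        device=str(md.get("device", "zernike")),
        frame=str(md.get("frame", "right-eye-frame")),
    )
    return ThicknessMap(x=x, y=y, values=values, mask=np.ones(x.size, dtype=bool), metadata=meta)
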