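"""Lid-wiper biomarkers: tilt/coma vectors, population axes, scalar
projections, centroids, circular dispersion and confidence ellipses.

The upper eyelid wipes the cornea along a roughly fixed direction during
blinking, imprinting a first-order-asymmetric signature on the epithelial
thickness map.  The two lowest-order Zernike pairs with single angular
frequency capture it:

* tilt  (n=1, m=+/-1): an overall planar slope of the map;
* primary coma (n=3, m=+/-1): an asymmetric paracentral focal pattern.

Each eye's pair is read as a Cartesian vector, (X-tilt, Y-tilt) = (c(1,1),
c(1,-1)) and, sign-flipped to match the tilt convention, (-c(3,1), -c(3,-1))
for coma.  The population lid-wiper axis (LWA) is the direction of the
cohort mean vector; per-eye scalar biomarkers are the projections

    lid-wiper gradient = |tilt| * cos(theta_tilt - LWA_tilt) / r   [um/mm]
    lid-wiper coma     = |coma| * cos(theta_coma - LWA_coma)       [um]

with r the analytical zone radius (2.5 mm).  Angles are degrees,
counterclockwise from the nasal (+x) axis, wrapped to [0, 360).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .zernike import CoefficientVector

__all__ = [
    "PolarVector",
    "LidWiperAxes",
    "BiomarkerRecord",
    "EllipseSpec",
    "wrap_angle",
    "tilt_vector",
    "coma_vector",
    "lwa_from_means",
    "lwa_standard_error",
    "lid_wiper_gradient",
    "lid_wiper_coma",
    "centroid",
    "circular_sd",
    "confidence_ellipse",
    "population_axes",
    "compute_biomarkers",
    "population_summary",
]

DEFAULT_ZONE_RADIUS_MM = 2.5


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to [0, 360)."""
    return float(np.mod(deg, 360.0))


@dataclass(frozen=True)
class PolarVector:
    """Magnitude (um) and angle (degrees CCW from +x, in [0, 360))."""

    magnitude: float
    angle_deg: float
    degenerate: bool = False  # zero-magnitude vector: angle is a placeholder

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        object.__setattr__(self, "angle_deg", wrap_angle(self.angle_deg))

    @classmethod
    def from_cartesian(cls, x: float, y: float) -> "PolarVector":
        mag = math.hypot(x, y)
        if mag == 0.0:
            return cls(magnitude=0.0, angle_deg=0.0, degenerate=True)
        return cls(magnitude=mag, angle_deg=wrap_angle(math.degrees(math.atan2(y, x))))

    def to_cartesian(self) -> tuple[float, float]:
        a = math.radians(self.angle_deg)
        return (self.magnitude * math.cos(a), self.magnitude * math.sin(a))


@dataclass(frozen=True)
class LidWiperAxes:
    """Population axes (degrees) with circular SDs of the per-eye directions."""

    tilt_lwa: float
    coma_lwa: float
    tilt_circ_sd: float
    coma_circ_sd: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "tilt_lwa", wrap_angle(self.tilt_lwa))
        object.__setattr__(self, "coma_lwa", wrap_angle(self.coma_lwa))
        if self.tilt_circ_sd < 0 or self.coma_circ_sd < 0:
            raise ValueError("circular SDs must be >= 0")


@dataclass(frozen=True)
class BiomarkerRecord:
    """Per-eye signed lid-wiper biomarkers and the underlying vectors."""

    subject_id: str
    eye: str
    date: str
    tilt: PolarVector
    coma: PolarVector
    lid_wiper_gradient: float  # um/mm
    lid_wiper_coma: float  # um


@dataclass(frozen=True)
class EllipseSpec:
    """Confidence ellipse: center, semi-axis lengths, orientation, level."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]  # (major, minor)
    orientation_deg: float  # of the major axis, CCW from +x
    level: float

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError("confidence level must lie in (0, 1)")
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be > 0")

    def contains(self, point) -> bool:
        """Whether the point lies inside (or on) the ellipse."""
        dx = np.asarray(point, dtype=float) - np.asarray(self.center)
        a = math.radians(self.orientation_deg)
        rot = np.array([[math.cos(a), math.sin(a)], [-math.sin(a), math.cos(a)]])
        u = rot @ dx
        sa, sb = self.semi_axes
        return bool((u[0] / sa) ** 2 + (u[1] / sb) ** 2 <= 1.0 + 1e-12)


def tilt_vector(coeffs: CoefficientVector) -> PolarVector:
    """Per-eye tilt vector (X-tilt, Y-tilt) = (c(1,1), c(1,-1)) in polar form."""
    return PolarVector.from_cartesian(coeffs.coefficient(1, 1), coeffs.coefficient(1, -1))


def coma_vector(coeffs: CoefficientVector) -> PolarVector:
    """Per-eye coma vector, sign-flipped to the tilt convention: (-c(3,1), -c(3,-1)).

    A positive tilt along some axis means the epithelium thickens toward that
    direction; flipping coma makes its vector point the same way for the
    matching focal pattern, so both biomarkers share one angular convention.
    """
    return PolarVector.from_cartesian(-coeffs.coefficient(3, 1), -coeffs.coefficient(3, -1))


def _as_xy(vectors) -> np.ndarray:
    arr = np.array(
        [v.to_cartesian() if isinstance(v, PolarVector) else tuple(v) for v in vectors],
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of 2-vectors")
    return arr


def lwa_from_means(vectors) -> float:
    """Population lid-wiper axis: atan2 of the componentwise mean vector, degrees.

    Accepts Cartesian pairs or PolarVectors.  Undefined (error) when the mean
    vector vanishes.
    """
    xy = _as_xy(vectors)
    mx, my = xy.mean(axis=0)
    if math.hypot(mx, my) == 0.0:
        raise ValueError("mean vector is zero; the lid-wiper axis is undefined")
    return wrap_angle(math.degrees(math.atan2(my, mx)))


def lwa_standard_error(vectors) -> float:
    """Delta-method standard error (degrees) of the mean-vector direction.

    Var(atan2(ybar, xbar)) ~= u' S u / (n |mu|^2) with u the unit vector
    perpendicular to the mean direction and S the sample covariance.
    """
    xy = _as_xy(vectors)
    n = xy.shape[0]
    if n < 3:
        raise ValueError("need at least 3 vectors")
    mean = xy.mean(axis=0)
    norm = np.hypot(*mean)
    if norm == 0:
        raise ValueError("mean vector is zero")
    u = np.array([-mean[1], mean[0]]) / norm
    S = np.cov(xy, rowvar=False, ddof=1)
    var = float(u @ S @ u) / (n * norm**2)
    return math.degrees(math.sqrt(var))


def lid_wiper_gradient(
    tilt: PolarVector,
    lwa_deg: float,
    zone_radius: float = DEFAULT_ZONE_RADIUS_MM,
) -> float:
    """Signed thickness slope (um/mm) along the tilt lid-wiper axis."""
    if zone_radius <= 0:
        raise ValueError("zone radius must be > 0")
    dtheta = math.radians(tilt.angle_deg - lwa_deg)
    return tilt.magnitude * math.cos(dtheta) / zone_radius


def lid_wiper_coma(coma: PolarVector, lwa_deg: float) -> float:
    """Signed focal-pattern magnitude (um) along the coma lid-wiper axis."""
    dtheta = math.radians(coma.angle_deg - lwa_deg)
    return coma.magnitude * math.cos(dtheta)


def centroid(vectors) -> PolarVector:
    """Componentwise mean of 2-D vectors, as magnitude and angle."""
    xy = _as_xy(vectors)
    mx, my = xy.mean(axis=0)
    return PolarVector.from_cartesian(mx, my)


def circular_sd(angles_deg) -> float:
    """Circular standard deviation (degrees): sqrt(-2 ln Rbar), Mardia form.

    Rbar is the mean resultant length of the unit vectors at the given angles.
    """
    angles = np.radians(np.asarray(angles_deg, dtype=float))
    if angles.size < 2:
        raise ValueError("need at least 2 angles")
    rbar = float(np.hypot(np.mean(np.cos(angles)), np.mean(np.sin(angles))))
    if rbar <= 1e-15:
        raise ValueError("mean resultant length is zero; circular SD undefined")
    rbar = min(rbar, 1.0)
    return math.degrees(math.sqrt(-2.0 * math.log(rbar)))


def confidence_ellipse(points, level: float = 0.95, of_mean: bool = False) -> EllipseSpec:
    """Bivariate-normal confidence ellipse of a 2-D point cloud.

    With sample covariance S, the data ellipse uses S and covers the stated
    fraction of draws from N(mean, S); the centroid ellipse (``of_mean``)
    uses S/n and covers the true mean at the stated confidence.  Semi-axes
    are sqrt(q * eigenvalue) with q the chi-square(2) quantile at ``level``.
    """
    xy = _as_xy(points)
    n = xy.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a confidence ellipse")
    S = np.cov(xy, rowvar=False, ddof=1)
    if of_mean:
        S = S / n
    evals, evecs = np.linalg.eigh(S)
    if evals.min() <= 1e-15 * max(evals.max(), 1.0):
        raise ValueError("sample covariance is singular; ellipse undefined")
    q = float(sps.chi2.ppf(level, df=2))
    order = np.argsort(evals)[::-1]  # major axis first
    evals, evecs = evals[order], evecs[:, order]
    semi = tuple(float(math.sqrt(q * ev)) for ev in evals)
    orient = wrap_angle(math.degrees(math.atan2(evecs[1, 0], evecs[0, 0])))
    center = tuple(float(c) for c in xy.mean(axis=0))
    return EllipseSpec(center=center, semi_axes=semi, orientation_deg=orient, level=level)


def population_axes(tilt_vectors, coma_vectors) -> LidWiperAxes:
    """Population axes from cohort mean vectors, with per-eye angular spread.

    The axis itself comes from the mean Cartesian vector (not the circular
    mean of per-eye axes); the circular SD summarizes the spread of the
    per-eye vector directions.
    """
    tilt_xy = _as_xy(tilt_vectors)
    coma_xy = _as_xy(coma_vectors)
    tilt_angles = np.degrees(np.arctan2(tilt_xy[:, 1], tilt_xy[:, 0]))
    coma_angles = np.degrees(np.arctan2(coma_xy[:, 1], coma_xy[:, 0]))
    return LidWiperAxes(
        tilt_lwa=lwa_from_means(tilt_xy),
        coma_lwa=lwa_from_means(coma_xy),
        tilt_circ_sd=circular_sd(tilt_angles),
        coma_circ_sd=circular_sd(coma_angles),
    )


def compute_biomarkers(
    coeff_vectors: list[CoefficientVector],
    zone_radius: float = DEFAULT_ZONE_RADIUS_MM,
) -> tuple[list[BiomarkerRecord], LidWiperAxes]:
    """Per-eye biomarkers against the axes derived from this same cohort."""
    tilts = [tilt_vector(cv) for cv in coeff_vectors]
    comas = [coma_vector(cv) for cv in coeff_vectors]
    axes = population_axes(tilts, comas)
    records = []
    for cv, t, c in zip(coeff_vectors, tilts, comas):
        md = cv.metadata
        records.append(
            BiomarkerRecord(
                subject_id=str(md.get("subject_id", "")),
                eye=str(md.get("eye", "")),
                date=str(md.get("date", "")),
                tilt=t,
                coma=c,
                lid_wiper_gradient=lid_wiper_gradient(t, axes.tilt_lwa, zone_radius),
                lid_wiper_coma=lid_wiper_coma(c, axes.coma_lwa),
            )
        )
    return records, axes


def population_summary(
    records: list[BiomarkerRecord],
    axes: LidWiperAxes,
    zone_radius: float = DEFAULT_ZONE_RADIUS_MM,
    ellipse_level: float = 0.95,
) -> dict:
    """Cohort-level summary: axes, centroids, dispersions, confidence ellipses.

    The gradient centroid is the mean of the per-eye tilt vectors scaled by
    1/r, reported as magnitude (um/mm) and angle; the coma centroid is the
    mean flipped-coma vector (um).  Thinning directions are the antipodes of
    the axes.
    """
    tilt_xy = np.array([r.tilt.to_cartesian() for r in records]) / zone_radius
    coma_xy = np.array([r.coma.to_cartesian() for r in records])
    grad_centroid = centroid(tilt_xy)
    coma_centroid = centroid(coma_xy)
    grads = np.array([r.lid_wiper_gradient for r in records])
    comas = np.array([r.lid_wiper_coma for r in records])

    def ellipse_dict(e: EllipseSpec) -> dict:
        return {
            "center": list(e.center),
            "semi_axes": list(e.semi_axes),
            "orientation_deg": e.orientation_deg,
            "level": e.level,
        }

    summary = {
        "n_eyes": len(records),
        "zone_radius_mm": zone_radius,
        "axes": {
            "tilt_lwa_deg": axes.tilt_lwa,
            "coma_lwa_deg": axes.coma_lwa,
            "tilt_circ_sd_deg": axes.tilt_circ_sd,
            "coma_circ_sd_deg": axes.coma_circ_sd,
            "tilt_thinning_direction_deg": wrap_angle(axes.tilt_lwa - 180.0),
            "coma_thinning_direction_deg": wrap_angle(axes.coma_lwa - 180.0),
        },
        "lid_wiper_gradient": {
            "centroid_magnitude_um_per_mm": grad_centroid.magnitude,
            "centroid_angle_deg": grad_centroid.angle_deg,
            "mean_um_per_mm": float(grads.mean()),
            "sd_um_per_mm": float(grads.std(ddof=1)) if grads.size > 1 else 0.0,
        },
        "lid_wiper_coma": {
            "centroid_magnitude_um": coma_centroid.magnitude,
            "centroid_angle_deg": coma_centroid.angle_deg,
            "mean_um": float(comas.mean()),
            "sd_um": float(comas.std(ddof=1)) if comas.size > 1 else 0.0,
        },
    }
    if len(records) >= 3:
        try:
            summary["ellipses"] = {
                "gradient_data": ellipse_dict(confidence_ellipse(tilt_xy, ellipse_level)),
                "gradient_centroid": ellipse_dict(
                    confidence_ellipse(tilt_xy, ellipse_level, of_mean=True)
                ),
                "coma_data": ellipse_dict(confidence_ellipse(coma_xy, ellipse_level)),
                "coma_centroid": ellipse_dict(
                    confidence_ellipse(coma_xy, ellipse_level, of_mean=True)
                ),
            }
        except ValueError:
            summary["ellipses"] = None  # degenerate cohort (e.g. identical eyes)
    return summary
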