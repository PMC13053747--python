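"""Synthetic cohorts of epithelial thickness maps.

Each eye draws a true Zernike coefficient vector from a multivariate normal
whose defaults reproduce the normative tilt/coma moments (see
:mod:`lidwiper.reference`).  Maps are rendered from those coefficients on a
square Cartesian grid in the right-eye frame; eyes assigned OS are stored
mirrored (x -> -x) so the analysis pipeline must undo the laterality, and
each scan adds independent per-pixel Gaussian measurement noise.

The generator emulates the statistical structure the analysis assumes —
between-eye coefficient variation, laterality mixing, scan repetition,
pixel noise — not device optics: no radial A-scan geometry, speckle, or
tear-film layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .maps import EyeRecord, MapMetadata, ThicknessMap
from .zernike import ansi_index, n_terms

__all__ = ["GridSpec", "PopulationSpec", "TruthRecord", "generate_cohort",
           "degrade_with_artifacts", "cohort_to_map_table", "truth_to_table"]


@dataclass(frozen=True)
class GridSpec:
    """Square Cartesian sampling grid, centred on the zone centre."""

    extent_mm: float = 6.0
    spacing_mm: float = 0.05

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0 or self.extent_mm <= 0:
            raise ValueError("grid extent and spacing must be > 0")

    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        half = self.extent_mm / 2.0
        axis = np.arange(-half, half + self.spacing_mm / 2.0, self.spacing_mm)
        xx, yy = np.meshgrid(axis, axis)
        return xx.ravel(), yy.ravel()


@dataclass
class PopulationSpec:
    """Generating distribution and cohort shape for a synthetic population.

    Defaults mirror the normative study conditions: 69 subjects contributing
    both eyes with repeated same-day scans, tilt/coma coefficient moments at
    the normative values, and pixel noise matched to the typical Zernike fit
    residual (0.35 um).
    """

    n_subjects: int = reference.N_SUBJECTS
    eyes_per_subject: int = 2
    scans_per_eye: int = 2
    od_fraction: float = 0.5  # laterality mix when eyes_per_subject == 1
    mean_coeffs: np.ndarray = field(default_factory=reference.mean_coefficients)
    coeff_cov: np.ndarray | None = None  # default: diag(coefficient_sds**2)
    tilt_coma_corr: float = 0.0  # correlation injected between matched tilt/coma terms
    pixel_noise_sd_um: float = reference.FIT_RMSE_MEAN_UM
    grid: GridSpec = field(default_factory=GridSpec)
    zone_radius_mm: float = 2.5
    max_order: int = 5
    seed: int = 0

    def covariance(self) -> np.ndarray:
        k = n_terms(self.max_order)
        if self.coeff_cov is not None:
            cov = np.asarray(self.coeff_cov, dtype=float)
            if cov.shape != (k, k):
                raise ValueError(f"coefficient covariance must be {k}x{k}")
        else:
            sds = reference.coefficient_sds(self.max_order)
            cov = np.diag(sds**2)
            if self.tilt_coma_corr:
                for mpair in (-1, 1):
                    jt = ansi_index(1, mpair).j
                    jc = ansi_index(3, mpair).j
                    c = self.tilt_coma_corr * sds[jt] * sds[jc]
                    cov[jt, jc] = cov[jc, jt] = c
        if not np.allclose(cov, cov.T):
            raise ValueError("coefficient covariance must be symmetric")
        evals = np.linalg.eigvalsh(cov)
        if evals.min() < -1e-10 * max(evals.max(), 1.0):
            raise ValueError("coefficient covariance is not positive semi-definite")
        return cov

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.eyes_per_subject not in (1, 2):
            raise ValueError("eyes_per_subject must be 1 or 2")
        if self.scans_per_eye < 1:
            raise ValueError("need at least one scan per eye")
        if not (0.0 <= self.od_fraction <= 1.0):
            raise ValueError("od_fraction must lie in [0, 1]")
        if self.pixel_noise_sd_um < 0:
            raise ValueError("pixel noise SD must be >= 0")
        mean = np.asarray(self.mean_coeffs, dtype=float)
        if mean.size != n_terms(self.max_order):
            raise ValueError(
                f"mean_coeffs must have {n_terms(self.max_order)} entries"
            )
        self.covariance()


@dataclass(frozen=True)
class TruthRecord:
    """Generating coefficients of one synthetic eye (right-eye frame, um)."""

    subject_id: str
    eye: str
    date: str
    true_coeffs: np.ndarray


def generate_cohort(
    spec: PopulationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[list[EyeRecord], list[TruthRecord]]:
    """Draw a synthetic cohort; deterministic for a fixed spec (and its seed).

    Maps are rendered in the right-eye frame and stored in each eye's native
    frame: OS maps have their x coordinates negated, exactly as a left eye's
    scan would arrive from the device.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cov = spec.covariance()
    mean = np.asarray(spec.mean_coeffs, dtype=float)
    x, y = spec.grid.positions()
    records: list[EyeRecord] = []
    truths: list[TruthRecord] = []
    date = "2024-01-01"
    A_zone = _extended_basis(x, y, spec.zone_radius_mm, spec.max_order)
    for s in range(spec.n_subjects):
        subject_id = f"S{s:03d}"
        if spec.eyes_per_subject == 2:
            eyes = ["OD", "OS"]
        else:
            eyes = ["OD" if rng.random() < spec.od_fraction else "OS"]
        for eye in eyes:
            c_true = rng.multivariate_normal(mean, cov, method="eigh")
            clean = A_zone @ c_true
            maps = []
            for scan in range(spec.scans_per_eye):
                vals = clean + rng.normal(0.0, spec.pixel_noise_sd_um, size=clean.size) \
                    if spec.pixel_noise_sd_um > 0 else clean.copy()
                sx = -x if eye == "OS" else x
                meta = MapMetadata(subject_id=subject_id, eye=eye, date=date,
                                   device="synthetic", frame="native",
                                   scan_id=str(scan))
                maps.append(ThicknessMap(x=sx.copy(), y=y.copy(), values=vals,
                                         mask=np.ones(vals.size, dtype=bool),
                                         metadata=meta))
            records.append(EyeRecord(subject_id=subject_id, eye=eye, date=date,
                                     device="synthetic", maps=maps))
            truths.append(TruthRecord(subject_id=subject_id, eye=eye, date=date,
                                      true_coeffs=c_true))
    return records, truths


def _extended_basis(x, y, zone_radius, max_order) -> np.ndarray:
    """Basis matrix normalized to the analysis zone but evaluated everywhere.

    Zernike polynomials are ordinary polynomials in (x, y); outside the unit
    disk they are extended polynomially so that a full square grid can be
    rendered and later cropped to the zone without a seam.
    """
    from .zernike import ansi_indices, _radial_poly  # reuse internals
    import math as _math

    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    rho = np.hypot(x, y) / zone_radius
    theta = np.arctan2(y, x)
    cols = []
    for idx in ansi_indices(max_order):
        n, m = idx.n, idx.m
        norm = _math.sqrt(2.0 * (n + 1) / (1.0 + (1.0 if m == 0 else 0.0)))
        radial = _radial_poly(n, abs(m), rho)
        if m > 0:
            ang = np.cos(m * theta)
        elif m < 0:
            ang = np.sin(abs(m) * theta)
        else:
            ang = np.ones_like(theta)
        cols.append(norm * radial * ang)
    return np.column_stack(cols)


def degrade_with_artifacts(
    records: list[EyeRecord],
    fraction: float,
    magnitude_um: float,
    patch_radius_mm: float = 0.6,
    rng: np.random.Generator | None = None,
) -> tuple[list[EyeRecord], list[tuple[str, str, str]]]:
    """Inject localized implausible thickness patches into a random subset.

    Emulates segmentation artifacts for QC testing: a Gaussian bump of the
    given peak magnitude at a random in-zone location is added to every scan
    of each corrupted eye.  Returns (records, corrupted keys); the input list
    is modified in place.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(0)
    n_corrupt = int(round(fraction * len(records)))
    idx = rng.choice(len(records), size=n_corrupt, replace=False) if n_corrupt else []
    corrupted = []
    for i in idx:
        rec = records[i]
        r = rng.uniform(0.0, 1.8)
        a = rng.uniform(0.0, 2 * np.pi)
        cx, cy = r * np.cos(a), r * np.sin(a)
        for m in rec.maps:
            # artifact is applied in the native frame of the stored scan
            d2 = (m.x - cx) ** 2 + (m.y - cy) ** 2
            m.values = m.values + magnitude_um * np.exp(-d2 / (2 * patch_radius_mm**2))
        corrupted.append(rec.key)
    return records, corrupted


def cohort_to_map_table(records: list[EyeRecord]) -> pd.DataFrame:
    """Long-format map table: one row per sample per scan."""
    frames = []
    for rec in records:
        for m in rec.maps:
            frames.append(pd.DataFrame({
                "subject_id": rec.subject_id,
                "eye": rec.eye,
                "date": rec.date,
                "device": rec.device,
                "scan_id": m.metadata.scan_id,
                "x_mm": m.x,
                "y_mm": m.y,
                "thickness_um": np.where(m.mask, m.values, np.nan),
            }))
    return pd.concat(frames, ignore_index=True)


def truth_to_table(truths: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truths:
        row = {"subject_id": t.subject_id, "eye": t.eye, "date": t.date}
        row.update({f"c_j{j}": c for j, c in enumerate(t.true_coeffs)})
        rows.append(row)
    return pd.DataFrame(rows)
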