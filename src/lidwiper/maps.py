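"""Per-scan map handling: laterality normalization, same-day averaging, zone
cropping, and outlier flagging.

Left- and right-eye corneas are nasal-temporal mirror images about the
vertical meridian, so left-eye (OS) maps are mirrored (x -> -x) into a common
right-eye frame before pooling: +x nasal, +y superior.  In that frame the
superotemporal quadrant sits at angles between 90 and 180 degrees and the
inferonasal quadrant between 270 and 360.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .zernike import fit_map

__all__ = [
    "MapMetadata",
    "ThicknessMap",
    "EyeRecord",
    "ExclusionList",
    "NATIVE_FRAME",
    "RIGHT_EYE_FRAME",
    "mirror_to_right_frame",
    "average_same_day",
    "crop_zone",
    "flag_outliers",
    "normalize_cohort",
    "coefficient_table",
]

NATIVE_FRAME = "native"
RIGHT_EYE_FRAME = "right-eye-frame"


@dataclass(frozen=True)
class MapMetadata:
    subject_id: str
    eye: str  # OD | OS
    date: str
    device: str = "unknown"
    frame: str = NATIVE_FRAME
    scan_id: str = "0"

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"eye must be 'OD' or 'OS', got {self.eye!r}")
        if self.frame not in (NATIVE_FRAME, RIGHT_EYE_FRAME):
            raise ValueError(f"unknown frame tag {self.frame!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.eye, self.date)

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "eye": self.eye,
            "date": self.date,
            "device": self.device,
            "frame": self.frame,
            "scan_id": self.scan_id,
        }


@dataclass
class ThicknessMap:
    """Epithelial thickness samples (um) at Cartesian (x, y) mm positions.

    ``mask`` marks valid samples; masked-out entries (segmentation dropouts,
    cropped pixels) never participate in fitting or averaging.
    """

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    metadata: MapMetadata

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool).ravel()
        n = self.x.size
        if not (self.y.size == self.values.size == self.mask.size == n):
            raise ValueError("x, y, values and mask must have equal length")
        # non-finite samples can never be valid
        self.mask &= np.isfinite(self.values)

    @property
    def radius(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def validate_physical(self) -> None:
        """Reject masked-in thickness values that are not strictly positive."""
        vals = self.values[self.mask]
        if vals.size and np.any(vals <= 0):
            raise ValueError(
                f"map {self.metadata.key} has {int(np.sum(vals <= 0))} non-positive "
                "masked-in thickness values"
            )

    def same_grid(self, other: "ThicknessMap", tol: float = 1e-9) -> bool:
        return (
            self.x.size == other.x.size
            and np.allclose(self.x, other.x, atol=tol)
            and np.allclose(self.y, other.y, atol=tol)
        )


@dataclass
class EyeRecord:
    """All scans of one eye on one day."""

    subject_id: str
    eye: str
    date: str
    device: str
    maps: list[ThicknessMap] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.eye, self.date)


@dataclass
class ExclusionList:
    """Keys (subject, eye, date) excluded from analysis, each with a reason."""

    entries: dict[tuple[str, str, str], str] = field(default_factory=dict)

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        return tuple(key) in self.entries

    def add(self, subject_id: str, eye: str, date: str, reason: str) -> None:
        self.entries[(subject_id, eye, date)] = reason

    def validate_against(self, cohort_keys) -> None:
        known = {tuple(k) for k in cohort_keys}
        missing = [k for k in self.entries if k not in known]
        if missing:
            raise ValueError(f"exclusion keys not present in the cohort: {missing}")

    @classmethod
    def from_csv(cls, path) -> "ExclusionList":
        df = pd.read_csv(path, dtype=str)
        out = cls()
        for row in df.itertuples(index=False):
            out.add(row.subject_id, row.eye, row.date, getattr(row, "reason", ""))
        return out

    def to_csv(self, path) -> None:
        rows = [
            {"subject_id": s, "eye": e, "date": d, "reason": r}
            for (s, e, d), r in self.entries.items()
        ]
        pd.DataFrame(rows, columns=["subject_id", "eye", "date", "reason"]).to_csv(
            path, index=False
        )


def mirror_to_right_frame(tmap: ThicknessMap) -> ThicknessMap:
    """Map a native-frame scan into the pooled right-eye frame.

    OD scans pass through unchanged apart from the frame tag; OS scans are
    mirrored about the vertical meridian (x -> -x).  Thickness values are
    untouched.  Re-normalizing an already-normalized map is refused to guard
    against double mirroring.
    """
    if tmap.metadata.frame != NATIVE_FRAME:
        raise ValueError(
            f"map {tmap.metadata.key} is already in {tmap.metadata.frame}; "
            "refusing to mirror twice"
        )
    x = -tmap.x if tmap.metadata.eye == "OS" else tmap.x.copy()
    meta = replace(tmap.metadata, frame=RIGHT_EYE_FRAME)
    return ThicknessMap(x=x, y=tmap.y.copy(), values=tmap.values.copy(),
                        mask=tmap.mask.copy(), metadata=meta)


def average_same_day(maps: list[ThicknessMap]) -> ThicknessMap:
    """Pointwise mean of repeated same-day scans of one eye.

    A sample is valid in the average iff it is valid in at least one scan;
    the mean is taken over the scans where it is valid.
    """
    if not maps:
        raise ValueError("need at least one map to average")
    first = maps[0]
    for m in maps[1:]:
        if m.metadata.key != first.metadata.key:
            raise ValueError(
                f"cannot average scans of different eyes/days: "
                f"{first.metadata.key} vs {m.metadata.key}"
            )
        if not first.same_grid(m):
            raise ValueError(
                f"mismatched grids between scans "
                f"{first.metadata.scan_id!r} and {m.metadata.scan_id!r} "
                f"of {first.metadata.key}"
            )
        if m.metadata.frame != first.metadata.frame:
            raise ValueError("cannot average maps in different frames")
    stack = np.vstack([np.where(m.mask, m.values, np.nan) for m in maps])
    counts = np.sum(np.isfinite(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    mask = counts > 0
    mean = np.where(mask, mean, np.nan)
    meta = replace(first.metadata, scan_id="avg")
    return ThicknessMap(x=first.x.copy(), y=first.y.copy(), values=mean,
                        mask=mask, metadata=meta)


def crop_zone(tmap: ThicknessMap, diameter: float = 5.0) -> ThicknessMap:
    """Mask out samples outside the central optical zone of the given diameter (mm)."""
    if diameter <= 0:
        raise ValueError("zone diameter must be > 0")
    mask = tmap.mask & (tmap.radius <= diameter / 2.0 + 1e-12)
    if not mask.any():
        raise ValueError(
            f"cropping {tmap.metadata.key} to {diameter} mm removed every sample"
        )
    return ThicknessMap(x=tmap.x.copy(), y=tmap.y.copy(), values=tmap.values.copy(),
                        mask=mask, metadata=tmap.metadata)


def flag_outliers(
    coeff_table: pd.DataFrame,
    terms: list[int] | None = None,
    k: float = 3.0,
) -> list[tuple[str, str, str]]:
    """Advisory flags for eyes whose coefficients stray far from the cohort.

    An eye is flagged when, for any listed term j, |c_j - mean| > k * SD over
    the cohort.  Flags prompt manual review; exclusion happens only through an
    :class:`ExclusionList`.  Terms default to the single-angular-frequency
    quartet (tilt and primary coma: j = 1, 2, 7, 8).
    """
    if terms is None:
        terms = [1, 2, 7, 8]
    if len(coeff_table) < 3:
        raise ValueError("need at least 3 eyes to define cohort outliers")
    flagged: list[tuple[str, str, str]] = []
    cols = [f"c_j{j}" for j in terms]
    means = coeff_table[cols].mean()
    sds = coeff_table[cols].std(ddof=1)
    for _, row in coeff_table.iterrows():
        for col in cols:
            sd = sds[col]
            if sd > 0 and abs(row[col] - means[col]) > k * sd:
                flagged.append((str(row["subject_id"]), str(row["eye"]), str(row["date"])))
                break
    return flagged


def normalize_cohort(
    records: list[EyeRecord],
    zone_diameter: float = 5.0,
) -> list[ThicknessMap]:
    """Mirror, same-day-average and crop every eye record; one map per eye-date."""
    out = []
    for rec in records:
        mirrored = [
            m if m.metadata.frame == RIGHT_EYE_FRAME else mirror_to_right_frame(m)
            for m in rec.maps
        ]
        averaged = average_same_day(mirrored)
        out.append(crop_zone(averaged, zone_diameter))
    return out


def coefficient_table(
    maps: list[ThicknessMap],
    zone_radius: float = 2.5,
    max_order: int = 5,
) -> pd.DataFrame:
    """Fit every map and tabulate coefficients: one row per eye-date.

    Columns: subject_id, eye, date, device, c_j0..c_jK (um), rmse_um, n_samples.
    """
    rows = []
    for m in maps:
        cv = fit_map(m, zone_radius=zone_radius, max_order=max_order)
        row = {
            "subject_id": m.metadata.subject_id,
            "eye": m.metadata.eye,
            "date": m.metadata.date,
            "device": m.metadata.device,
        }
        row.update({f"c_j{j}": c for j, c in enumerate(cv.coeffs)})
        row["rmse_um"] = cv.rmse
        row["n_samples"] = cv.n_samples
        rows.append(row)
    return pd.DataFrame(rows)
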