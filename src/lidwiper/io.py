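"""CSV/JSON interchange for map tables, coefficient tables and biomarkers.

All files are plain text.  Units are fixed across the package: thicknesses
in micrometres, lengths in millimetres, angles in degrees CCW from the
nasal (+x) axis wrapped to [0, 360).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .maps import EyeRecord, MapMetadata, ThicknessMap
from .metrics import BiomarkerRecord

__all__ = [
    "read_map_table",
    "write_map_table",
    "map_table_to_records",
    "records_from_csv",
    "biomarkers_to_table",
]

MAP_COLUMNS = ["subject_id", "eye", "date", "device", "x_mm", "y_mm", "thickness_um"]


def read_map_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "eye": str, "date": str,
                                  "device": str, "scan_id": str},
                     comment="#")
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"map table {path} is missing columns: {missing}")
    if "scan_id" not in df.columns:
        df["scan_id"] = "0"
    return df


def write_map_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# units: x_mm/y_mm in mm, thickness_um in um\n")
        df.to_csv(fh, index=False)


def map_table_to_records(df: pd.DataFrame) -> list[EyeRecord]:
    """Group a long-format map table into per-eye-per-day records of scans."""
    records = []
    for (subject, eye, date), eye_df in df.groupby(["subject_id", "eye", "date"], sort=True):
        device = str(eye_df["device"].iloc[0])
        maps = []
        for scan_id, scan_df in eye_df.groupby("scan_id", sort=True):
            meta = MapMetadata(subject_id=str(subject), eye=str(eye), date=str(date),
                               device=device, frame="native", scan_id=str(scan_id))
            vals = scan_df["thickness_um"].to_numpy(dtype=float)
            maps.append(ThicknessMap(
                x=scan_df["x_mm"].to_numpy(dtype=float),
                y=scan_df["y_mm"].to_numpy(dtype=float),
                values=vals,
                mask=np.isfinite(vals),
                metadata=meta,
            ))
        records.append(EyeRecord(subject_id=str(subject), eye=str(eye),
                                 date=str(date), device=device, maps=maps))
    return records


def records_from_csv(path) -> list[EyeRecord]:
    return map_table_to_records(read_map_table(path))


def biomarkers_to_table(records: list[BiomarkerRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id,
            "eye": r.eye,
            "date": r.date,
            "tilt_mag_um": r.tilt.magnitude,
            "tilt_angle_deg": r.tilt.angle_deg,
            "coma_mag_um": r.coma.magnitude,
            "coma_angle_deg": r.coma.angle_deg,
            "lid_wiper_gradient_um_per_mm": r.lid_wiper_gradient,
            "lid_wiper_coma_um": r.lid_wiper_coma,
        })
    return pd.DataFrame(rows)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
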