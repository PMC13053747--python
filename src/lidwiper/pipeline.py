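"""End-to-end analysis pipeline.

Stages, in order: load -> mirror to the right-eye frame -> same-day average
-> crop to the analytical zone -> Zernike fit -> outlier QC / exclusions ->
lid-wiper biomarkers -> statistical battery -> report artifacts.  The
pipeline is a pure function of (inputs, config, seed); artifacts are stamped
with a config hash so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from . import maps as lmaps
from . import metrics as lmetrics
from . import stats as lstats
from .zernike import CoefficientVector, ansi_index, n_terms

logger = logging.getLogger("lidwiper")

__all__ = ["AnalysisConfig", "PipelineResult", "run_pipeline", "coefficients_from_table"]


@dataclass
class AnalysisConfig:
    zone_diameter_mm: float = 5.0
    max_order: int = 5
    normality_alpha: float = 0.05
    bonferroni_family: int = 4
    ellipse_level: float = 0.95
    outlier_k: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.zone_diameter_mm <= 0:
            raise ValueError("zone diameter must be > 0")
        if self.max_order < 1:
            raise ValueError("max radial order must be >= 1")
        if not (0.0 < self.ellipse_level < 1.0):
            raise ValueError("ellipse level must lie in (0, 1)")

    @property
    def zone_radius_mm(self) -> float:
        return self.zone_diameter_mm / 2.0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    coeff_table: pd.DataFrame
    biomarker_table: pd.DataFrame
    summary: dict
    stats_report: dict
    flagged: list
    excluded: list


def coefficients_from_table(df: pd.DataFrame, zone_radius: float, max_order: int
                            ) -> list[CoefficientVector]:
    """Rehydrate CoefficientVectors from a coefficient table."""
    k = n_terms(max_order)
    out = []
    for _, row in df.iterrows():
        out.append(CoefficientVector(
            coeffs=np.array([row[f"c_j{j}"] for j in range(k)], dtype=float),
            zone_radius=zone_radius,
            max_order=max_order,
            rmse=float(row.get("rmse_um", 0.0)),
            n_samples=int(row.get("n_samples", 0)),
            metadata={"subject_id": row["subject_id"], "eye": row["eye"],
                      "date": row["date"]},
        ))
    return out


def run_pipeline(
    records: list[lmaps.EyeRecord],
    config: AnalysisConfig | None = None,
    exclusions: lmaps.ExclusionList | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on a cohort of eye records.

    When ``out_dir`` is given, writes coefficient and biomarker CSVs plus the
    population-summary and stats-report JSONs, each stamped with the config
    hash and seed.
    """
    config = config or AnalysisConfig()
    stage = "load"
    try:
        n_scans = sum(len(r.maps) for r in records)
        logger.info("load: %d eye-records, %d scans", len(records), n_scans)
        if not records:
            raise ValueError("no input records")

        stage = "normalize"
        cohort_maps = lmaps.normalize_cohort(records, config.zone_diameter_mm)
        logger.info("normalize: %d per-eye maps after mirror/average/crop",
                    len(cohort_maps))

        stage = "fit"
        coeff_table = lmaps.coefficient_table(
            cohort_maps, zone_radius=config.zone_radius_mm, max_order=config.max_order)
        logger.info("fit: %d coefficient rows, mean rmse %.3f um",
                    len(coeff_table), coeff_table["rmse_um"].mean())

        stage = "qc"
        flagged = lmaps.flag_outliers(coeff_table, k=config.outlier_k) \
            if len(coeff_table) >= 3 else []
        excluded = []
        if exclusions is not None:
            keys = list(zip(coeff_table["subject_id"], coeff_table["eye"],
                            coeff_table["date"]))
            exclusions.validate_against(keys)
            keep = [k not in exclusions for k in keys]
            excluded = [k for k in keys if tuple(k) in exclusions]
            coeff_table = coeff_table.loc[keep].reset_index(drop=True)
        logger.info("qc: %d flagged, %d excluded, %d eyes analyzed",
                    len(flagged), len(excluded), len(coeff_table))

        stage = "biomarkers"
        cvs = coefficients_from_table(coeff_table, config.zone_radius_mm,
                                      config.max_order)
        bio_records, axes = lmetrics.compute_biomarkers(cvs, config.zone_radius_mm)
        summary = lmetrics.population_summary(
            bio_records, axes, config.zone_radius_mm, config.ellipse_level)
        bio_table = lio.biomarkers_to_table(bio_records)

        stage = "stats"
        stats_report = _stats_battery(coeff_table, cvs, bio_records, config)

        stage = "report"
        summary["config_hash"] = config.digest()
        summary["seed"] = config.seed
        stats_report["config_hash"] = config.digest()
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            header = (f"# units: um/mm/degrees; angles CCW from nasal axis in "
                      f"[0,360); config={config.digest()} seed={config.seed}\n")
            for name, df in (("coefficients.csv", coeff_table),
                             ("biomarkers.csv", bio_table)):
                with open(out / name, "w") as fh:
                    fh.write(header)
                    df.to_csv(fh, index=False)
            lio.write_json(summary, out / "population_summary.json")
            lio.write_json(stats_report, out / "stats_report.json")

        return PipelineResult(coeff_table=coeff_table, biomarker_table=bio_table,
                              summary=summary, stats_report=stats_report,
                              flagged=flagged, excluded=excluded)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _stats_battery(coeff_table, cvs, bio_records, config) -> dict:
    """One-sample tests on the tilt/coma quartet plus the three regressions."""
    term_labels = {
        "Y-tilt": ansi_index(1, -1).j,
        "X-tilt": ansi_index(1, 1).j,
        "Y-coma": ansi_index(3, -1).j,
        "X-coma": ansi_index(3, 1).j,
    }
    tests = {}
    for label, j in term_labels.items():
        try:
            res = lstats.gated_one_sample_test(
                coeff_table[f"c_j{j}"].to_numpy(), term=label,
                alpha_normality=config.normality_alpha,
                family_size=config.bonferroni_family)
            tests[label] = asdict(res)
        except ValueError as err:
            tests[label] = {"error": str(err)}

    grad = np.array([r.lid_wiper_gradient for r in bio_records])
    coma = np.array([r.lid_wiper_coma for r in bio_records])
    rss_ast = np.array([lstats.rss_astigmatism(cv) for cv in cvs])
    rss_hoa = np.array([lstats.rss_hoa_excluding_coma(cv) for cv in cvs])
    regressions = {}
    for name, y in (("coma_on_gradient", coma),
                    ("rss_astigmatism_on_gradient", rss_ast),
                    ("rss_hoa_on_gradient", rss_hoa)):
        try:
            regressions[name] = asdict(lstats.biomarker_regression(grad, y))
        except ValueError as err:
            regressions[name] = {"error": str(err)}
    return {"one_sample_tests": tests, "regressions": regressions,
            "fit_rmse_um": {"mean": float(coeff_table["rmse_um"].mean()),
                            "sd": float(coeff_table["rmse_um"].std(ddof=1))
                            if len(coeff_table) > 1 else 0.0}}
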