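"""Cohort-level orchestration: features -> deltas -> comparisons -> report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .adc import compute_adc
from .config import AnalysisConfig
from .errors import WbdwiError
from .response_stats import ComparisonReport, run_comparisons
from .tumor_load import DELTA_COLUMNS, FEATURE_COLUMNS, delta_table, extract_patient_features
from .volumes import TIMEPOINTS, CohortManifest, read_series

logger = logging.getLogger(__name__)

ALL_MODES = ("predict_interim", "predict_eot", "assess_interim", "assess_eot")


@dataclass
class AnalysisReport:
    """Everything one run produces, with the configuration echoed for audit."""

    config: AnalysisConfig
    features: pd.DataFrame
    deltas: pd.DataFrame
    comparisons: dict[str, ComparisonReport]
    completeness: pd.DataFrame  # per patient/timepoint extraction outcome
    excluded_patients: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        sig = {
            mode: rep.significant["feature"].tolist()
            for mode, rep in self.comparisons.items()
        }
        return {
            "config": self.config.to_dict(),
            "n_feature_records": int(len(self.features)),
            "n_delta_records": int(len(self.deltas)),
            "excluded_patients": self.excluded_patients,
            "significant_features": sig,
        }

    def write(self, out_dir: str | Path) -> Path:
        """Write feature/delta/result CSVs and a JSON report header."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(out_dir / "features.csv", index=False)
        self.deltas.to_csv(out_dir / "deltas.csv", index=False)
        self.completeness.to_csv(out_dir / "completeness.csv", index=False)
        for mode, rep in self.comparisons.items():
            rep.results.to_csv(out_dir / f"results_{mode}_all.csv", index=False)
            rep.significant.to_csv(out_dir / f"results_{mode}.csv", index=False)
            if len(rep.skipped):
                rep.skipped.to_csv(out_dir / f"skipped_{mode}.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
        return out_dir


def extract_cohort_features(
    manifest: CohortManifest, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Feature table for every patient/timepoint in a manifest.

    Returns ``(features, completeness, excluded)``: patients for whom any
    timepoint fails extraction are excluded entirely (a longitudinal analysis
    needs all three timepoints) with the reason logged per timepoint.
    """
    config = config or AnalysisConfig()
    frames: dict[str, list[pd.DataFrame]] = {}
    completeness: list[dict] = []
    excluded: list[str] = []
    for patient in manifest:
        ok = True
        patient_frames = []
        for t in TIMEPOINTS:
            try:
                series = read_series(patient.series_paths[t], patient.patient_id, t)
                adc = compute_adc(series, config.b_low, config.b_high)
                feats = extract_patient_features(series, config=config, adc=adc)
                patient_frames.append(feats)
                completeness.append(
                    {
                        "patient_id": patient.patient_id,
                        "timepoint": t,
                        "status": "ok",
                        "negative_adc_fraction": adc.negative_fraction,
                        "n_empty_masks": int(feats["value"].isna().sum() // 8)
                        if feats["value"].isna().any() else 0,
                        "reason": "",
                    }
                )
            except (WbdwiError, OSError, KeyError) as exc:
                ok = False
                completeness.append(
                    {
                        "patient_id": patient.patient_id,
                        "timepoint": t,
                        "status": "failed",
                        "negative_adc_fraction": float("nan"),
                        "n_empty_masks": 0,
                        "reason": f"{type(exc).__name__}: {exc}",
                    }
                )
                logger.warning("excluding %s: T%d failed: %s", patient.patient_id, t, exc)
        if ok:
            frames[patient.patient_id] = patient_frames
        else:
            excluded.append(patient.patient_id)
    if frames:
        features = pd.concat(
            [f for fl in frames.values() for f in fl], ignore_index=True
        )
    else:
        features = pd.DataFrame(columns=FEATURE_COLUMNS)
    return features, pd.DataFrame(completeness), excluded


def run_pipeline(
    manifest: CohortManifest,
    config: AnalysisConfig | None = None,
    modes: tuple[str, ...] = ALL_MODES,
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Full analysis: features, percentage changes, all comparison modes.

    Deterministic given (data, config): no randomness enters after
    simulation.  Optionally writes all tables under ``out_dir``.
    """
    config = config or AnalysisConfig()
    features, completeness, excluded = extract_cohort_features(manifest, config)
    deltas = delta_table(features) if len(features) else pd.DataFrame(columns=DELTA_COLUMNS)
    kept = CohortManifest([p for p in manifest if p.patient_id not in set(excluded)])
    comparisons = {
        mode: run_comparisons(features, deltas, kept, mode, config) for mode in modes
    }
    report = AnalysisReport(
        config=config,
        features=features,
        deltas=deltas,
        comparisons=comparisons,
        completeness=completeness,
        excluded_patients=excluded,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
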