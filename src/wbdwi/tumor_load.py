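"""Total tumor load: threshold masks, diffusion volume, ADC histogram features.

This is the re-implemented core of the automatic whole-body tumor-load
procedure: on the high-b-value (b800) image a family of percentage-threshold
masks is defined, with **no** subsequent editing — no morphology, no
connected-component filtering, no manual exclusion of physiologically
hyperintense organs.  For each mask the pipeline reports the diffusion
volume (DV, cm^3) and eight first-order statistics of the ADC values inside
the mask, then longitudinal percentage changes between timepoints.

Feature notation follows the field convention ``f^T_th%``: superscript T is
the timepoint (0 baseline, 1 interim, 2 end of treatment), subscript th% the
segmentation threshold.

Threshold semantics
-------------------
A voxel enters the mask when its b800 intensity is at least
``threshold_percent/100 x reference_intensity``.  The reference defaults to a
robust maximum — the 99.9th percentile of strictly positive voxel
intensities — so an isolated hot voxel cannot shift every mask; absolute max
and mean + k*sd are available alternatives.  The reference is computed per
volume (per timepoint), since each acquisition has its own arbitrary
intensity scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .adc import ADCMap, compute_adc
from .config import AnalysisConfig
from .errors import EmptyMaskError, EmptyReferenceError, ParameterError
from .volumes import DWISeries, ImageVolume

#: The nine per-threshold features: diffusion volume plus eight ADC
#: histogram statistics.
FEATURE_NAMES = (
    "DV",
    "ADCmean",
    "ADCsd",
    "ADCmd",
    "ADC5p",
    "ADC95p",
    "ADCsk",
    "ADCkurt",
    "ADCentr",
)

#: Inter-timepoint percentage-change pairs: (earlier, later) -> column tag.
DELTA_PAIRS = {"01": (0, 1), "02": (0, 2), "12": (1, 2)}

FEATURE_COLUMNS = [
    "patient_id", "timepoint", "threshold_percent", "feature_name", "value", "n_voxels",
]
DELTA_COLUMNS = ["patient_id", "pair", "threshold_percent", "feature_name", "value"]


@dataclass
class ThresholdMask:
    """A percentage-threshold mask on the high-b-value image (unedited)."""

    mask: np.ndarray
    threshold_percent: float
    reference_intensity: float
    source_b: int = 800

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class FeatureRecord:
    """One feature value f^T_th% for one patient, timepoint and threshold."""

    patient_id: str
    timepoint: int
    threshold_percent: float
    feature_name: str
    value: float
    n_voxels: int


def reference_intensity(volume: ImageVolume, config: AnalysisConfig | None = None) -> float:
    """Scalar the segmentation percentages are applied to."""
    config = config or AnalysisConfig()
    data = np.asarray(volume.data, dtype=np.float64)
    positive = data[data > 0]
    if positive.size == 0:
        raise EmptyReferenceError("volume has no positive voxels; threshold reference undefined")
    if config.reference_rule == "robust_max":
        return float(np.percentile(positive, config.reference_percentile))
    if config.reference_rule == "max":
        return float(positive.max())
    # mean + k*sd over positive voxels
    return float(positive.mean() + config.reference_k * positive.std(ddof=1))


def segment_threshold(
    b_high_volume: ImageVolume,
    threshold_percent: float,
    config: AnalysisConfig | None = None,
    reference: float | None = None,
) -> ThresholdMask:
    """Mask of voxels with intensity >= (threshold_percent/100) * reference.

    No editing of any kind is applied to the result.  ``reference`` can be
    passed to reuse one value across thresholds of the same volume.
    """
    config = config or AnalysisConfig()
    if not (0.0 < threshold_percent <= 100.0):
        raise ParameterError(f"threshold_percent must lie in (0, 100], got {threshold_percent}")
    ref = reference_intensity(b_high_volume, config) if reference is None else float(reference)
    cut = (threshold_percent / 100.0) * ref
    mask = np.asarray(b_high_volume.data, dtype=np.float64) >= cut
    return ThresholdMask(mask, float(threshold_percent), ref, config.b_high)


def diffusion_volume(mask: ThresholdMask, spacing: Sequence[float]) -> float:
    """Mask volume (DV) in cm^3: voxel count x voxel volume / 1000."""
    dx, dy, dz = spacing
    return mask.n_voxels * dx * dy * dz / 1000.0


def _entropy_bits(values: np.ndarray, bins: int, rng: tuple[float, float]) -> float:
    """Base-2 Shannon entropy of the binned value distribution.

    Values outside the fixed range are clamped into the edge bins, so the
    support (and hence the log2(bins) upper bound) is identical for every
    patient and timepoint.
    """
    lo, hi = rng
    clamped = np.clip(values, lo, hi)
    counts, _ = np.histogram(clamped, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / values.size
    return float(-(p * np.log2(p)).sum())


def histogram_features(
    adc: ADCMap,
    mask: ThresholdMask,
    config: AnalysisConfig | None = None,
    context: str = "",
) -> dict[str, float]:
    """The eight ADC histogram statistics over valid masked voxels.

    mean; sample sd (n-1); median; 5th/95th percentiles with linear
    interpolation; Fisher-Pearson skewness and Fisher excess kurtosis
    (population moments, no small-sample bias correction); Shannon entropy in
    bits over ``config.entropy_bins`` bins spanning ``config.adc_range``.

    Statistics that need more voxels than available (sd: 2, skewness: 3,
    kurtosis: 4) — or whose denominator sd is zero — are returned as NaN;
    the rest are still computed.
    """
    config = config or AnalysisConfig()
    if mask.mask.shape != adc.volume.shape:
        raise ParameterError("mask and ADC map do not share a grid")
    values = adc.valid_values(mask.mask)
    if config.clip_negative_adc:
        values = np.maximum(values, 0.0)
    n = values.size
    if n == 0:
        raise EmptyMaskError(
            f"no valid masked voxels at th={mask.threshold_percent:g}%"
            + (f" ({context})" if context else "")
        )
    out: dict[str, float] = {
        "ADCmean": float(values.mean()),
        "ADCmd": float(np.median(values)),
        "ADC5p": float(np.percentile(values, 5)),
        "ADC95p": float(np.percentile(values, 95)),
        "ADCentr": _entropy_bits(values, config.entropy_bins, config.adc_range),
    }
    sd = float(values.std(ddof=1)) if n >= 2 else math.nan
    out["ADCsd"] = sd
    degenerate = not (sd > 0)
    out["ADCsk"] = (
        float(sps.skew(values, bias=True)) if n >= 3 and not degenerate else math.nan
    )
    out["ADCkurt"] = (
        float(sps.kurtosis(values, fisher=True, bias=True)) if n >= 4 and not degenerate else math.nan
    )
    return out


def pct_change(f_later: float, f_earlier: float) -> float:
    """Percentage change 100 * (f_later - f_earlier) / f_earlier."""
    if f_earlier == 0:
        raise ZeroDivisionError("percentage change undefined for a zero earlier value")
    return 100.0 * (f_later - f_earlier) / f_earlier


def extract_patient_features(
    series: DWISeries,
    thresholds: Iterable[float] | None = None,
    config: AnalysisConfig | None = None,
    adc: ADCMap | None = None,
) -> pd.DataFrame:
    """Full per-timepoint feature set: DV + 8 ADC statistics per threshold.

    ADC is computed once per series; the six default thresholds yield
    6 x 9 = 54 records.  Returns a long-format frame with columns
    ``patient_id, timepoint, threshold_percent, feature_name, value, n_voxels``.
    """
    config = config or AnalysisConfig()
    thresholds = tuple(thresholds) if thresholds is not None else config.thresholds
    if adc is None:
        adc = compute_adc(series, config.b_low, config.b_high)
    b_high_vol = series.volumes[config.b_high]
    ref = reference_intensity(b_high_vol, config)
    ctx = f"{series.patient_id}/T{series.timepoint}"

    rows: list[tuple] = []
    for th in thresholds:
        mask = segment_threshold(b_high_vol, th, config, reference=ref)
        dv = diffusion_volume(mask, series.spacing)
        n_valid = int((mask.mask & adc.valid).sum())
        rows.append((series.patient_id, series.timepoint, th, "DV", dv, n_valid))
        try:
            feats = histogram_features(adc, mask, config, context=ctx)
        except EmptyMaskError:
            feats = dict.fromkeys(set(FEATURE_NAMES) - {"DV"}, math.nan)
        for name in FEATURE_NAMES[1:]:
            rows.append((series.patient_id, series.timepoint, th, name, feats[name], n_valid))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def delta_table(features: pd.DataFrame, pairs: Iterable[str] = ("01", "02", "12")) -> pd.DataFrame:
    """Inter-timepoint percentage changes for every feature and threshold.

    ``pair`` is the two-digit tag of (earlier, later): "01" and "02" are
    changes from baseline, "12" from interim.  A change whose earlier value
    is zero or undefined is carried as NaN (flagged missing) rather than
    dropped, so completeness is auditable downstream.
    """
    wide = features.pivot_table(
        index=["patient_id", "threshold_percent", "feature_name"],
        columns="timepoint",
        values="value",
        aggfunc="first",
        dropna=False,
    )
    out: list[pd.DataFrame] = []
    for tag in pairs:
        t_earlier, t_later = DELTA_PAIRS[tag]
        if t_earlier not in wide.columns or t_later not in wide.columns:
            continue
        earlier = wide[t_earlier]
        later = wide[t_later]
        value = 100.0 * (later - earlier) / earlier.where(earlier != 0)
        frame = value.rename("value").reset_index()
        frame.insert(1, "pair", tag)
        out.append(frame)
    if not out:
        return pd.DataFrame(columns=DELTA_COLUMNS)
    return pd.concat(out, ignore_index=True)[DELTA_COLUMNS]
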