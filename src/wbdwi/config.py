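"""Run configuration: one dataclass, YAML-loadable, echoed into every report."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

DEFAULT_THRESHOLDS = (5.0, 10.0, 20.0, 40.0, 60.0, 80.0)


@dataclass
class AnalysisConfig:
    """All tunables of the feature-extraction and statistics stages.

    Attributes
    ----------
    thresholds : tuple of float
        Segmentation thresholds in percent of the reference intensity.
    b_low, b_high : int
        The acquired b-value pair (s/mm^2) used for ADC mapping.
    reference_rule : {"robust_max", "max", "mean_sd"}
        What the threshold percentage is relative to on the b_high image.
    reference_percentile : float
        Percentile of positive voxels used by "robust_max".
    reference_k : float
        k in mean + k*sd for the "mean_sd" rule.
    entropy_bins : int
        Histogram bins for ADC entropy (base-2 Shannon).
    adc_range : (float, float)
        Fixed ADC histogram range in 1e-6 mm^2/s; out-of-range values are
        clamped to the edge bins so entropy is comparable across timepoints.
    clip_negative_adc : bool
        If True, negative ADC values are clipped to 0 before histogramming;
        by default they are retained.
    alpha : float
        Significance level gating both test selection and ROC construction.
    exact_mw_max_n : int
        Combined sample size at or below which the Mann-Whitney p-value is
        computed by exact enumeration (when tie-free).
    """

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    b_low: int = 50
    b_high: int = 800
    reference_rule: str = "robust_max"
    reference_percentile: float = 99.9
    reference_k: float = 3.0
    entropy_bins: int = 1024
    adc_range: tuple[float, float] = (0.0, 4000.0)
    clip_negative_adc: bool = False
    alpha: float = 0.05
    exact_mw_max_n: int = 14

    def __post_init__(self) -> None:
        self.thresholds = tuple(float(t) for t in self.thresholds)
        if any(not (0.0 < t <= 100.0) for t in self.thresholds):
            raise ParameterError(f"thresholds must lie in (0, 100]: {self.thresholds}")
        if self.b_high <= self.b_low:
            raise ParameterError("b_high must exceed b_low")
        if self.entropy_bins < 2:
            raise ParameterError("entropy_bins must be >= 2")
        lo, hi = self.adc_range
        if not hi > lo:
            raise ParameterError(f"empty adc_range {self.adc_range}")
        if self.reference_rule not in ("robust_max", "max", "mean_sd"):
            raise ParameterError(f"unknown reference_rule {self.reference_rule!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["adc_range"] = list(self.adc_range)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path
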