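"""Apparent diffusion coefficient (ADC) mapping.

The two-point mono-exponential signal model ``S(b) = S0 * exp(-b * ADC)``
gives, for an acquired pair of b-values,

    ADC = ln(S_low / S_high) / (b_high - b_low)

ADC is reported in units of 1e-6 mm^2/s throughout the pipeline (so water at
body temperature is ~3000, hypercellular lymphoma ~600-1000).  The low
b-value is the acquired b = 50 s/mm^2, not an idealized b = 0: the pair is
used as acquired, which also suppresses the perfusion contribution to the
decay estimate.

Voxels with nonpositive signal at either b-value carry no diffusion
information and are marked invalid; negative ADC values (possible in noise)
are retained by default and only summarized, since downstream histogramming
decides how to treat them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .volumes import DWISeries, ImageVolume

logger = logging.getLogger(__name__)


@dataclass
class ADCMap:
    """Voxelwise ADC with a validity grid.

    Attributes
    ----------
    volume : ImageVolume
        ADC values in 1e-6 mm^2/s; invalid voxels hold 0.
    valid : ndarray of bool
        True where both input signals were strictly positive.
    b_pair : (int, int)
        The (b_low, b_high) pair used, in s/mm^2.
    negative_fraction : float
        Fraction of valid voxels with ADC < 0 (noise indicator).
    """

    volume: ImageVolume
    valid: np.ndarray
    b_pair: tuple[int, int]
    negative_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.valid.shape != self.volume.shape:
            raise ParameterError("validity grid does not match ADC volume shape")
        if not np.all(np.isfinite(self.volume.data[self.valid])):
            raise ParameterError("defined ADC values must be finite")

    def valid_values(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Valid ADC values, optionally restricted to a boolean mask."""
        sel = self.valid if mask is None else (self.valid & mask)
        return self.volume.data[sel]


def compute_adc(series: DWISeries, b_low: int = 50, b_high: int = 800) -> ADCMap:
    """Compute the ADC map of a series from its (b_low, b_high) pair.

    Parameters
    ----------
    series : DWISeries
        Must contain both requested b-values.
    b_low, b_high : int
        Diffusion weightings in s/mm^2 with ``b_high > b_low``.

    Returns
    -------
    ADCMap
        ADC in 1e-6 mm^2/s on the input grid.  Scale-invariant: multiplying
        both signal volumes by one positive constant leaves it unchanged.
    """
    if b_high <= b_low:
        raise ParameterError(f"b_high must exceed b_low, got ({b_low}, {b_high})")
    for b in (b_low, b_high):
        if b not in series.volumes:
            raise KeyError(f"series {series.patient_id}/T{series.timepoint} has no b={b}")

    s_low = np.asarray(series.volumes[b_low].data, dtype=np.float64)
    s_high = np.asarray(series.volumes[b_high].data, dtype=np.float64)

    valid = (s_low > 0) & (s_high > 0)
    adc = np.zeros_like(s_low)
    np.divide(s_low, s_high, out=adc, where=valid)
    np.log(adc, out=adc, where=valid)
    adc[valid] *= 1.0e6 / (b_high - b_low)
    adc[~valid] = 0.0

    n_valid = int(valid.sum())
    neg_frac = float((adc[valid] < 0).sum() / n_valid) if n_valid else 0.0
    if neg_frac > 0:
        logger.info(
            "ADC %s/T%d: %.2f%% of valid voxels negative (retained, flagged)",
            series.patient_id, series.timepoint, 100 * neg_frac,
        )
    return ADCMap(
        volume=series.volumes[b_low].like(adc),
        valid=valid,
        b_pair=(b_low, b_high),
        negative_fraction=neg_frac,
    )


def ingest_adc(volume: ImageVolume, b_pair: tuple[int, int] = (50, 800)) -> ADCMap:
    """Wrap a precomputed (e.g. scanner-side) ADC volume as an :class:`ADCMap`.

    Non-finite voxels are marked invalid; everything else is taken as-is.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    valid = np.isfinite(data)
    clean = np.where(valid, data, 0.0)
    neg = float((clean[valid] < 0).sum() / valid.sum()) if valid.any() else 0.0
    return ADCMap(volume.like(clean), valid, tuple(b_pair), neg)
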