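"""Onset-relative windowing, fixed-length resampling, and outlier filtering.

The prediction task uses a 5-minute feature-extraction window ("required
time", 360 s to 60 s before onset) separated from the onset by a 60 s
forecast gap: a classifier that succeeds on the required window predicts
the arrhythmia a minute ahead. Window membership is decided by an
interval's cumulative end-time, half-open on the forecast side, so counts
are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .datatypes import LabeledRecording, RRSeries


class WindowingError(ValueError):
    """The series cannot supply the requested onset-relative window."""


class ResamplingError(ValueError):
    """The series is too short to resample."""


@dataclass(frozen=True)
class WindowConfig:
    """Onset-relative window geometry, seconds before onset.

    ``required_start=360, required_end=60`` selects the 5-minute feature
    window; ``target_length`` is the fixed CNN input length.
    """

    required_start: float = 360.0
    required_end: float = 60.0
    forecast_span: float = 60.0
    target_length: int = 1000

    def validate(self) -> None:
        if not (self.required_start > self.required_end >= 0):
            raise ValueError("need required_start > required_end >= 0")
        if self.target_length < 2:
            raise ValueError("target_length must be >= 2")


def extract_required_window(series: RRSeries, cfg: WindowConfig | None = None) -> RRSeries:
    """Return the sub-series whose end-times fall in
    ``(-required_start, -required_end]`` relative to the onset anchor.

    Intervals straddling a boundary are assigned by their end-time; the
    half-open side sits at the onset-distal boundary, so an interval ending
    exactly ``required_end`` seconds before onset is the last one kept (it
    lies entirely outside the forecast gap). Raises
    :class:`WindowingError` if the series has no onset anchor or is shorter
    than ``required_start``.
    """
    cfg = cfg or WindowConfig()
    cfg.validate()
    if series.onset_time is None:
        raise WindowingError(f"{series.record_id or 'series'}: no onset anchor set")
    if series.duration < cfg.required_start:
        raise WindowingError(
            f"{series.record_id or 'series'}: duration {series.duration:.1f} s "
            f"shorter than required_start {cfg.required_start:.0f} s"
        )
    rel_end = series.cumulative_time - series.onset_time
    mask = (rel_end > -cfg.required_start) & (rel_end <= -cfg.required_end)
    return RRSeries(
        series.intervals[mask],
        onset_time=None,
        record_id=series.record_id,
        patient_id=series.patient_id,
    )


def resample_to_length(
    series: RRSeries | np.ndarray, target_length: int = 1000, kind: str = "linear"
) -> np.ndarray:
    """Interpolate the interval sequence against its index onto exactly
    ``target_length`` points.

    The abscissa is the beat index 0..N-1 mapped linearly onto the output
    grid, so the first and last outputs equal the first and last intervals.
    ``kind`` is ``"linear"`` (default; outputs stay within the input range)
    or ``"cubic"`` (spline, may overshoot).
    """
    values = series.intervals if isinstance(series, RRSeries) else np.asarray(series, float)
    if values.size < 2:
        raise ResamplingError("need at least 2 intervals to resample")
    if target_length < 2:
        raise ResamplingError("target_length must be >= 2")
    x_old = np.arange(values.size, dtype=float)
    x_new = np.linspace(0.0, values.size - 1.0, target_length)
    if kind == "linear":
        return np.interp(x_new, x_old, values)
    if kind == "cubic":
        return CubicSpline(x_old, values)(x_new)
    raise ValueError(f"unknown interpolation kind {kind!r}")


def remove_dc(vector: np.ndarray) -> np.ndarray:
    """Subtract the mean so the output has zero DC offset."""
    vector = np.asarray(vector, dtype=float)
    if vector.size == 0:
        raise ValueError("cannot remove DC offset of an empty vector")
    return vector - vector.mean()


def filter_by_lfhf(
    dataset: Sequence[LabeledRecording],
    threshold: float = 11.6,
    spectral_cfg=None,
) -> Tuple[List[LabeledRecording], int]:
    """Drop recordings whose LF/HF ratio exceeds ``threshold``.

    LF/HF outside roughly 1.1-11.6 is physiologically implausible for the
    control population, so high-ratio recordings are treated as outliers.
    Recordings with undefined LF/HF (zero HF power) are removed as
    degenerate. Returns ``(kept, removed_count)`` with order preserved.
    """
    from . import features  # local import: features depends on remove_dc above

    kept: List[LabeledRecording] = []
    removed = 0
    for rec in dataset:
        rr = rec.values
        _, _, _, lf_hf = features.band_powers(rr, spectral_cfg)
        if np.isnan(lf_hf) or lf_hf > threshold:
            removed += 1
        else:
            kept.append(rec)
    return kept, removed
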