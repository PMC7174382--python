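"""Core containers for RR-interval recordings and HRV feature vectors.

The raw signal throughout the package is the RR (equivalently NN) interval
series: the time between successive R peaks of the ECG, in milliseconds.
Recordings are labeled either ``"vta"`` (the series ends at the onset of a
ventricular tachyarrhythmia episode) or ``"control"`` (normal sinus rhythm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

VTA = "vta"
CONTROL = "control"
LABELS = (VTA, CONTROL)

#: Canonical order of the 11 HRV features.
FEATURE_NAMES = (
    "mean_nn",
    "sdnn",
    "rmssd",
    "pnn50",
    "vlf",
    "lf",
    "hf",
    "lf_hf",
    "sd1",
    "sd2",
    "sd1_sd2",
)


@dataclass(frozen=True)
class RRSeries:
    """An ordered RR-interval series in milliseconds.

    Parameters
    ----------
    intervals
        RR intervals in ms, in recording order. All strictly positive.
    onset_time
        Cumulative time (seconds) of the arrhythmia onset anchor. For
        pre-onset recordings this is by convention the end of the series.
    record_id, patient_id
        Provenance identifiers.
    """

    intervals: np.ndarray
    onset_time: Optional[float] = None
    record_id: str = ""
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if arr.size and not np.all(arr > 0):
            bad = int(np.flatnonzero(arr <= 0)[0])
            raise ValueError(
                f"RR intervals must be positive; interval {bad} is {arr[bad]!r} ms"
            )
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def cumulative_time(self) -> np.ndarray:
        """End time of each interval in seconds from the series start."""
        return np.cumsum(self.intervals) / 1000.0

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return float(self.intervals.sum() / 1000.0)

    def with_onset_at_end(self) -> "RRSeries":
        return replace(self, onset_time=self.duration)


@dataclass(frozen=True)
class LabeledRecording:
    """An RR series (or fixed-length resampled vector) plus its class label.

    ``augmentation_index`` is 0 for an original recording and positive for a
    circular-shift copy; ``pair_id`` groups a VTA recording with its matched
    control.
    """

    data: Union[RRSeries, np.ndarray]
    label: str
    pair_id: str = ""
    augmentation_index: int = 0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.augmentation_index < 0:
            raise ValueError("augmentation_index must be >= 0")
        if not isinstance(self.data, RRSeries):
            object.__setattr__(self, "data", np.asarray(self.data, dtype=float))

    @property
    def values(self) -> np.ndarray:
        """The underlying numeric sequence (intervals or resampled vector)."""
        if isinstance(self.data, RRSeries):
            return self.data.intervals
        return self.data

    @property
    def is_series(self) -> bool:
        return isinstance(self.data, RRSeries)

    def with_data(self, data, augmentation_index: Optional[int] = None) -> "LabeledRecording":
        idx = self.augmentation_index if augmentation_index is None else augmentation_index
        return LabeledRecording(data, self.label, self.pair_id, idx)


@dataclass(frozen=True)
class HRVFeatureVector:
    """The 11 classical HRV features.

    Time domain: ``mean_nn`` (ms), ``sdnn`` (ms), ``rmssd`` (ms), ``pnn50``
    (%). Frequency domain (tachogram spectral power, ms^2): ``vlf``
    (0-0.04 Hz), ``lf`` (0.04-0.15 Hz), ``hf`` (0.15-0.4 Hz) and the
    ``lf_hf`` ratio. Poincare plot: ``sd1``, ``sd2`` (ms) and ``sd1_sd2``.
    Ratios are NaN when their denominator is zero.
    """

    mean_nn: float
    sdnn: float
    rmssd: float
    pnn50: float
    vlf: float
    lf: float
    hf: float
    lf_hf: float
    sd1: float
    sd2: float
    sd1_sd2: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}
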