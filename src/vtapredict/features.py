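"""The eleven classical HRV features.

Time domain
-----------
MeanNN = (1/N) * sum RR_i                          (ms)
SDNN   = population standard deviation of RR       (ms)
RMSSD  = sqrt(mean of squared successive diffs)    (ms)
pNN50  = 100 * #{|RR_{i+1} - RR_i| > 50 ms} / N    (%)

The pNN50 denominator is the total interval count N (a convention flag
switches to the N-1 successive-difference count).

Frequency domain
----------------
The RR series is converted to an evenly sampled tachogram by cubic-spline
resampling at 4 Hz (the dominant HRV convention for spectral analysis),
DC-corrected, and analysed with Welch's periodogram (Hann window, 256-point
segments, 50% overlap). Band powers integrate the PSD over VLF (0-0.04 Hz),
LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz); LF/HF is their ratio, an index of
sympathovagal balance.

Poincare nonlinear
------------------
SD1 = sqrt(0.5 * Var(RR_i - RR_{i+1}))   dispersion across the identity line
SD2 = sqrt(2*SDNN^2 - 0.5*SD1^2)         dispersion along it

Variances are population variances throughout; a negative SD2 radicand is
clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch

from .datatypes import FEATURE_NAMES, HRVFeatureVector, RRSeries
from .preprocess import remove_dc

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


class SpectralError(ValueError):
    """The signal is too short for the configured Welch analysis."""


@dataclass(frozen=True)
class SpectralConfig:
    """Welch periodogram settings for the tachogram PSD."""

    resample_rate: float = 4.0  # Hz
    segment_length: int = 256  # samples per Welch segment
    overlap_fraction: float = 0.5
    window_shape: str = "hann"

    def validate(self) -> None:
        if self.segment_length < 8:
            raise ValueError("segment_length must be >= 8")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.resample_rate <= 0:
            raise ValueError("resample_rate must be positive")


def _as_intervals(rr: Union[RRSeries, np.ndarray]) -> np.ndarray:
    if isinstance(rr, RRSeries):
        return rr.intervals
    return np.asarray(rr, dtype=float)


def mean_nn(rr) -> float:
    """Arithmetic mean RR interval, ms."""
    x = _as_intervals(rr)
    if x.size == 0:
        raise ValueError("mean_nn of an empty series")
    return float(x.mean())


def sdnn(rr, *, population: bool = True) -> float:
    """Standard deviation of the RR intervals, ms (population by default)."""
    x = _as_intervals(rr)
    if x.size == 0:
        raise ValueError("sdnn of an empty series")
    if x.size == 1:
        return 0.0
    return float(x.std(ddof=0 if population else 1))


def rmssd(rr) -> float:
    """Root mean square of successive RR differences, ms."""
    x = _as_intervals(rr)
    if x.size < 2:
        raise ValueError("rmssd needs at least 2 intervals")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d**2)))


def pnn50(rr, *, denominator: str = "total") -> float:
    """Percentage of successive differences strictly exceeding 50 ms.

    ``denominator="total"`` divides by N intervals (the convention used
    here); ``"diffs"`` divides by the N-1 difference count.
    """
    x = _as_intervals(rr)
    if x.size < 2:
        raise ValueError("pnn50 needs at least 2 intervals")
    count = int(np.sum(np.abs(np.diff(x)) > 50.0))
    denom = x.size if denominator == "total" else x.size - 1
    return 100.0 * count / denom


def rr_to_tachogram(rr, resample_rate: float = 4.0) -> np.ndarray:
    """Cubic-spline resample the beat-indexed RR series onto an even time
    grid at ``resample_rate`` Hz. Interval end-times are the abscissa."""
    x = _as_intervals(rr)
    if x.size < 4:
        raise SpectralError("need at least 4 intervals to build a tachogram")
    t = np.cumsum(x) / 1000.0
    grid = np.arange(t[0], t[-1], 1.0 / resample_rate)
    return CubicSpline(t, x)(grid)


def band_powers_from_tachogram(
    tachogram: np.ndarray, cfg: SpectralConfig | None = None
) -> Tuple[float, float, float, float]:
    """Welch band powers (VLF, LF, HF, LF/HF) of an evenly sampled tachogram.

    The tachogram is DC-corrected before the PSD is estimated; band power is
    the PSD integrated over each band. LF/HF is NaN when HF power is zero.
    """
    cfg = cfg or SpectralConfig()
    cfg.validate()
    x = np.asarray(tachogram, dtype=float)
    if x.size < cfg.segment_length:
        raise SpectralError(
            f"tachogram has {x.size} samples; Welch needs >= {cfg.segment_length}"
        )
    x = remove_dc(x)
    freqs, psd = welch(
        x,
        fs=cfg.resample_rate,
        window=cfg.window_shape,
        nperseg=cfg.segment_length,
        noverlap=int(cfg.segment_length * cfg.overlap_fraction),
        detrend=False,
        scaling="density",
    )
    df = freqs[1] - freqs[0]

    def band(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs < hi)
        return float(psd[mask].sum() * df)

    vlf = band(*VLF_BAND)
    lf = band(*LF_BAND)
    hf = band(*HF_BAND)
    lf_hf = lf / hf if hf > 0 else float("nan")
    return vlf, lf, hf, lf_hf


def band_powers(rr, cfg: SpectralConfig | None = None) -> Tuple[float, float, float, float]:
    """Band powers of a beat-indexed RR series; see
    :func:`band_powers_from_tachogram`."""
    cfg = cfg or SpectralConfig()
    return band_powers_from_tachogram(rr_to_tachogram(rr, cfg.resample_rate), cfg)


def poincare_sd(rr) -> Tuple[float, float, float]:
    """Poincare plot dispersions ``(sd1, sd2, sd1/sd2)`` in ms.

    SD1 (short-term variability) comes from the population variance of the
    successive-difference sequence; SD2 (long-term) from the identity
    ``SD2^2 = 2*SDNN^2 - 0.5*SD1^2``, with a negative radicand clamped to 0.
    The ratio is NaN when SD2 is zero.
    """
    x = _as_intervals(rr)
    if x.size < 2:
        raise ValueError("poincare_sd needs at least 2 intervals")
    d = x[:-1] - x[1:]
    sd1 = float(np.sqrt(0.5 * d.var(ddof=0)))
    radicand = 2.0 * sdnn(x) ** 2 - 0.5 * sd1**2
    sd2 = float(np.sqrt(max(radicand, 0.0)))
    ratio = sd1 / sd2 if sd2 > 0 else float("nan")
    return sd1, sd2, ratio


def extract_features(rr, cfg: SpectralConfig | None = None) -> HRVFeatureVector:
    """All 11 HRV features of a required-window RR series, in the canonical
    order of :data:`~vtapredict.datatypes.FEATURE_NAMES`."""
    x = _as_intervals(rr)
    vlf, lf, hf, lf_hf = band_powers(x, cfg)
    sd1, sd2, sd1_sd2 = poincare_sd(x)
    return HRVFeatureVector(
        mean_nn=mean_nn(x),
        sdnn=sdnn(x),
        rmssd=rmssd(x),
        pnn50=pnn50(x),
        vlf=vlf,
        lf=lf,
        hf=hf,
        lf_hf=lf_hf,
        sd1=sd1,
        sd2=sd2,
        sd1_sd2=sd1_sd2,
    )


def feature_table(recordings, cfg: SpectralConfig | None = None):
    """Feature matrix for a list of labeled recordings as a DataFrame with
    the 11 feature columns plus ``label`` and ``pair_id``."""
    import pandas as pd

    rows = []
    for rec in recordings:
        feats = extract_features(rec.values, cfg).as_dict()
        feats["label"] = rec.label
        feats["pair_id"] = rec.pair_id
        rows.append(feats)
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["label", "pair_id"])
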