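"""Synthetic RR-interval recordings with class-conditional HRV structure.

The generator is an integral-pulse-style discrete beat model: each interval
is a class mean plus two sinusoidal modulations (a ~0.1 Hz "LF" component
reflecting baroreflex-scale oscillation and a ~0.25 Hz "HF" component at
respiratory frequency) sampled at the cumulative beat time, plus white
jitter:

    RR_i = mean_nn + lf_amp * sin(2*pi*0.1*t_i) + hf_amp * sin(2*pi*0.25*t_i) + eps_i

with t_i the cumulative time of beat i and eps_i ~ N(0, noise_sd^2). The
class defaults put the VTA group at a shorter mean interval (faster rate)
and a lower LF/HF sinusoid-power ratio than the control group, matching the
direction and magnitude of the class statistics the pipeline is designed to
separate. This is an artifact convention for exercising the pipeline, not a
physiological model of autonomic control.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np

from .datatypes import CONTROL, VTA, LabeledRecording, RRSeries

LF_FREQ_HZ = 0.1
HF_FREQ_HZ = 0.25
#: hard positivity floor applied after noise, ms
INTERVAL_FLOOR_MS = 200.0


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic beat model.

    Parameters
    ----------
    class_label
        ``"vta"`` or ``"control"``.
    mean_nn
        Class-level mean RR interval, ms.
    mean_sd
        Between-recording standard deviation of the recording-level mean
        RR interval, ms. Each generated recording draws its own mean from
        ``N(mean_nn, mean_sd^2)``, so class distributions overlap the way
        cohort summary statistics (mean +- SD across recordings) describe.
    lf_amp, hf_amp
        Amplitudes (ms) of the 0.1 Hz and 0.25 Hz sinusoidal modulations.
    noise_sd
        Standard deviation (ms) of the white beat-to-beat jitter.
    duration
        Target cumulative duration, seconds. The default 420 s leaves room
        for both the 300 s feature window and the 60 s forecast gap.
    seed
        Seed for the jitter; the series is deterministic given it.
    """

    class_label: str = CONTROL
    mean_nn: float = 775.15
    mean_sd: float = 0.0
    lf_amp: float = 40.0
    hf_amp: float = 30.0
    noise_sd: float = 70.0
    duration: float = 420.0
    seed: int = 0

    def validate(self) -> None:
        if self.class_label not in (VTA, CONTROL):
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if self.mean_nn <= 0:
            raise ValueError("mean_nn must be positive")
        if self.lf_amp < 0 or self.hf_amp < 0 or self.noise_sd < 0 or self.mean_sd < 0:
            raise ValueError("amplitudes, noise_sd and mean_sd must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def _noise_sd_for_target(sdnn_target: float, lf_amp: float, hf_amp: float) -> float:
    # total interval variance = lf_amp^2/2 + hf_amp^2/2 + noise_sd^2
    resid = sdnn_target**2 - 0.5 * lf_amp**2 - 0.5 * hf_amp**2
    return float(np.sqrt(max(resid, 0.0)))


def vta_params(seed: int = 0, **overrides) -> GeneratorParams:
    """Default VTA-class parameters: mean NN 684.45 +- 125.47 ms across
    recordings, SDNN target 74.34 ms, equal LF/HF sinusoid amplitudes
    (power ratio 1.0)."""
    p = GeneratorParams(
        class_label=VTA,
        mean_nn=684.45,
        mean_sd=125.47,
        lf_amp=30.0,
        hf_amp=30.0,
        noise_sd=_noise_sd_for_target(74.34, 30.0, 30.0),
        seed=seed,
    )
    return replace(p, **overrides) if overrides else p


def control_params(seed: int = 0, **overrides) -> GeneratorParams:
    """Default control-class parameters: mean NN 775.15 +- 107.61 ms across
    recordings, SDNN target 79.04 ms, LF/HF sinusoid-power ratio
    (40/30)^2 ~ 1.78."""
    p = GeneratorParams(
        class_label=CONTROL,
        mean_nn=775.15,
        mean_sd=107.61,
        lf_amp=40.0,
        hf_amp=30.0,
        noise_sd=_noise_sd_for_target(79.04, 40.0, 30.0),
        seed=seed,
    )
    return replace(p, **overrides) if overrides else p


def generate_rr_series(params: GeneratorParams) -> RRSeries:
    """Generate one RR series from the beat model.

    The onset anchor is placed at the series end (pre-onset convention).
    Intervals are floored at 200 ms after noise so the series is always a
    valid positive tachogram. Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    base_mean = params.mean_nn
    if params.mean_sd > 0:
        # recording-level mean heterogeneity; floor keeps the rate plausible
        base_mean = max(base_mean + rng.normal(0.0, params.mean_sd), 350.0)
    intervals: List[float] = []
    t = 0.0  # cumulative seconds
    while t < params.duration:
        rr = (
            base_mean
            + params.lf_amp * np.sin(2 * np.pi * LF_FREQ_HZ * t)
            + params.hf_amp * np.sin(2 * np.pi * HF_FREQ_HZ * t)
        )
        if params.noise_sd > 0:
            rr += rng.normal(0.0, params.noise_sd)
        rr = max(rr, INTERVAL_FLOOR_MS)
        intervals.append(rr)
        t += rr / 1000.0
    series = RRSeries(
        np.asarray(intervals),
        record_id=f"sim-{params.class_label}-{params.seed}",
    )
    return series.with_onset_at_end()


def generate_dataset(
    n_vta: int,
    n_control: int,
    vta_params_: Optional[GeneratorParams] = None,
    control_params_: Optional[GeneratorParams] = None,
    seed: int = 0,
) -> List[LabeledRecording]:
    """Generate a labeled dataset of ``n_vta`` + ``n_control`` recordings.

    Per-recording seeds are derived from the master seed with a counter-based
    ``SeedSequence`` scheme, so the dataset is reproducible and each
    recording is independent of the others' order.
    """
    if n_vta < 0 or n_control < 0:
        raise ValueError("recording counts must be non-negative")
    base_vta = vta_params_ if vta_params_ is not None else vta_params()
    base_control = control_params_ if control_params_ is not None else control_params()
    recordings: List[LabeledRecording] = []
    for i in range(n_vta + n_control):
        sub = int(np.random.SeedSequence((seed, i)).generate_state(1)[0] % (2**31))
        if i < n_vta:
            params = replace(base_vta, seed=sub)
            pair = f"pair-{i:04d}"
        else:
            params = replace(base_control, seed=sub)
            pair = f"pair-{i - n_vta:04d}"
        series = generate_rr_series(params)
        series = replace(series, record_id=f"sim-{params.class_label}-{i:04d}")
        recordings.append(
            LabeledRecording(series, params.class_label, pair_id=pair)
        )
    return recordings
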