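"""Circular-shift data augmentation.

Rolling an RR sequence by a random offset preserves the value multiset (so
MeanNN and SDNN are exactly unchanged) while reordering the sequence, which
perturbs order-sensitive features; class membership is preserved. The
default multiplicity of 6 (one original plus five shifted copies) grows a
261-recording dataset to 1566.

``pre_split`` mode augments the whole dataset before cross-validation
splitting (the simpler design, at the cost of shifted near-duplicates
leaking between train and test folds); ``fold_safe`` defers augmentation
to the training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .datatypes import LabeledRecording, RRSeries

PRE_SPLIT = "pre_split"
FOLD_SAFE = "fold_safe"


@dataclass(frozen=True)
class AugmentConfig:
    """multiplicity = total copies per original (original included)."""

    multiplicity: int = 6
    seed: int = 0
    mode: str = PRE_SPLIT

    def validate(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.mode not in (PRE_SPLIT, FOLD_SAFE):
            raise ValueError(f"mode must be {PRE_SPLIT!r} or {FOLD_SAFE!r}")


def circular_shift(values: Sequence[float] | np.ndarray, k: int) -> np.ndarray:
    """Roll ``values`` so the element at position i moves to (i + k) mod N;
    elements rolled past the end re-enter at the front."""
    arr = np.asarray(values)
    if arr.size == 0:
        return arr.copy()
    return np.roll(arr, k)


def augment_dataset(
    dataset: Sequence[LabeledRecording], cfg: AugmentConfig | None = None
) -> List[LabeledRecording]:
    """Expand each recording into ``multiplicity`` recordings: the original
    (augmentation_index 0) plus shifted copies with nonzero random offsets
    drawn uniformly from 1..N-1. Deterministic given ``cfg.seed``; labels
    and pair ids are preserved."""
    cfg = cfg or AugmentConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    out: List[LabeledRecording] = []
    for rec in dataset:
        values = rec.values
        out.append(rec.with_data(rec.data, augmentation_index=0))
        n = values.size
        for j in range(1, cfg.multiplicity):
            k = int(rng.integers(1, n)) if n > 1 else 0
            shifted = circular_shift(values, k)
            if rec.is_series:
                data = RRSeries(shifted, record_id=f"{rec.data.record_id}-aug{j}")
                data = data.with_onset_at_end()
            else:
                data = shifted
            out.append(rec.with_data(data, augmentation_index=j))
    return out
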