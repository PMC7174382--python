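"""Reading and writing RR-interval recordings and dataset manifests.

Formats
-------
plain
    One RR value per line; blank lines ignored. Canonical unit is
    milliseconds. Files whose median value is below 10 are assumed to be in
    seconds (the unit the PhysioNet MVTDB distributes) and are converted to
    ms with a warning.
csv
    A header line with an ``rr_ms`` column.
manifest
    CSV with columns ``path,label,pair_id`` pointing at per-recording files.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .datatypes import CONTROL, VTA, LabeledRecording, RRSeries

SECONDS_MEDIAN_THRESHOLD = 10.0  # median interval below this => file is in seconds


class RRParseError(ValueError):
    """A token in an RR file could not be parsed."""


class RRValidationError(ValueError):
    """A parsed RR value violates the series invariants."""


def _maybe_seconds_to_ms(values: np.ndarray, origin: str) -> np.ndarray:
    if values.size and float(np.median(values)) < SECONDS_MEDIAN_THRESHOLD:
        warnings.warn(
            f"{origin}: median interval {np.median(values):.3g} < "
            f"{SECONDS_MEDIAN_THRESHOLD}; interpreting values as seconds and "
            "converting to ms",
            stacklevel=3,
        )
        return values * 1000.0
    return values


def read_rr_series(path, format: str = "plain", record_id: str | None = None) -> RRSeries:
    """Read an RR series from ``path``.

    Raises :class:`RRParseError` naming the offending line for non-numeric
    tokens and :class:`RRValidationError` for non-positive intervals.
    """
    path = Path(path)
    if format == "plain":
        values = []
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            token = raw.strip()
            if not token:
                continue
            try:
                value = float(token)
            except ValueError:
                raise RRParseError(
                    f"{path}: line {lineno}: non-numeric RR value {token!r}"
                ) from None
            if value <= 0:
                raise RRValidationError(
                    f"{path}: line {lineno}: non-positive RR interval {value}"
                )
            values.append(value)
        arr = np.asarray(values, dtype=float)
    elif format == "csv":
        frame = pd.read_csv(path)
        if "rr_ms" not in frame.columns:
            raise RRParseError(f"{path}: CSV file lacks an 'rr_ms' column")
        arr = frame["rr_ms"].to_numpy(dtype=float)
        if arr.size and not np.all(arr > 0):
            bad = int(np.flatnonzero(arr <= 0)[0])
            raise RRValidationError(
                f"{path}: row {bad + 1}: non-positive RR interval {arr[bad]}"
            )
    else:
        raise ValueError(f"unknown format {format!r}")
    arr = _maybe_seconds_to_ms(arr, str(path))
    return RRSeries(arr, record_id=record_id or path.stem)


def write_rr_series(series: RRSeries, path, format: str = "plain") -> Path:
    """Write ``series`` so that :func:`read_rr_series` recovers it to
    0.001 ms precision. Returns the path written."""
    path = Path(path)
    if format == "plain":
        lines = "\n".join(f"{v:.3f}" for v in series.intervals)
        path.write_text(lines + ("\n" if len(series) else ""))
    elif format == "csv":
        pd.DataFrame({"rr_ms": np.round(series.intervals, 3)}).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def write_manifest(recordings: Sequence[LabeledRecording], out_dir, name: str = "manifest.csv") -> Path:
    """Write per-recording plain files plus a ``path,label,pair_id`` manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(recordings):
        if rec.is_series:
            series = rec.data
        else:
            series = RRSeries(rec.values)
        rid = (series.record_id or f"rec-{i:04d}") if rec.is_series else f"rec-{i:04d}"
        fname = f"{rid}.txt"
        write_rr_series(series, out_dir / fname)
        rows.append({"path": fname, "label": rec.label, "pair_id": rec.pair_id})
    manifest = out_dir / name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path) -> List[LabeledRecording]:
    """Load recordings listed in a ``path,label,pair_id`` manifest CSV."""
    manifest_path = Path(manifest_path)
    frame = pd.read_csv(manifest_path, keep_default_na=False)
    recordings = []
    for _, row in frame.iterrows():
        series = read_rr_series(manifest_path.parent / row["path"])
        series = series.with_onset_at_end()
        recordings.append(
            LabeledRecording(series, row["label"], pair_id=str(row["pair_id"]))
        )
    return recordings


class MVTDBLoadError(RuntimeError):
    """The directory does not look like an MVTDB-style tree."""


def _classify(path: Path) -> str | None:
    tokens = {t.lower() for part in path.parts for t in part.replace("-", "_").split("_")}
    stem = path.stem.lower()
    if tokens & {"control", "nsr", "sinus"}:
        return CONTROL
    if tokens & {"vt", "vf", "vta"} or stem[:2] in ("vt", "vf"):
        return VTA
    return None


def load_mvtdb(root_dir) -> List[LabeledRecording]:
    """Load an MVTDB-style directory of paired pre-onset and control RR files.

    The reader scans ``root_dir`` recursively for ``.txt`` RR files and
    classifies each as VTA or control from path tokens (``vt``/``vf`` versus
    ``control``/``nsr``); pairing is by shared file stem after stripping the
    class token. Repeated control records (identical interval sequences) are
    deduplicated, matching the convention by which a shared control period
    serves several episodes. Files in seconds are converted to ms.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise MVTDBLoadError(f"{root}: not a directory")
    files = sorted(root.rglob("*.txt"))
    if not files:
        raise MVTDBLoadError(f"{root}: no .txt RR files found")
    recordings: List[LabeledRecording] = []
    seen_controls: List[np.ndarray] = []
    for f in files:
        label = _classify(f.relative_to(root))
        if label is None:
            continue
        series = read_rr_series(f).with_onset_at_end()
        if label == CONTROL:
            if any(
                prev.shape == series.intervals.shape and np.array_equal(prev, series.intervals)
                for prev in seen_controls
            ):
                continue
            seen_controls.append(series.intervals)
        pair = f.stem
        for token in ("vt", "vf", "vta", "control", "nsr"):
            pair = pair.replace(token, "")
        recordings.append(LabeledRecording(series, label, pair_id=pair.strip("_-")))
    if not recordings:
        raise MVTDBLoadError(
            f"{root}: no files could be classified as VTA or control"
        )
    return recordings
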