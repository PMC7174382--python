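"""End-to-end study orchestration, statsmodels-style.

:class:`VTAStudy` is the model object: it holds the labeled RR recordings
and the configuration of every stage (windowing, resampling, augmentation,
outlier filtering, spectral analysis, classifiers). ``fit()`` executes

    window -> resample -> augment -> LF/HF filter -> features -> CV

and returns a :class:`StudyResults` carrying per-algorithm cross-validated
metrics, the cross-algorithm ANOVA, per-feature t-tests, stage-by-stage
record counts, and a ``summary()`` table. A single master seed fans out to
per-stage seeds so every stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import synthetic
from .augment import FOLD_SAFE, PRE_SPLIT, AugmentConfig, augment_dataset, circular_shift
from .datatypes import CONTROL, VTA, LabeledRecording
from .evaluation import EvaluationReport, StatsReport, compare_algorithms, cross_validate, feature_ttest
from .features import SpectralConfig, feature_table
from .models import build_ann, build_baseline, build_cnn
from .nn import CNNSpec, SpecificationError, TrainConfig, shape_trace
from .preprocess import WindowConfig, extract_required_window, filter_by_lfhf, resample_to_length

logger = logging.getLogger("vtapredict")

ALGORITHMS = ("cnn", "ann", "svm", "knn")


@dataclass
class PipelineConfig:
    """All stage configurations plus the master seed."""

    window: WindowConfig = field(default_factory=WindowConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    cnn_spec: CNNSpec = field(default_factory=CNNSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    algorithms: Sequence[str] = ALGORITHMS
    k_folds: int = 10
    lfhf_threshold: float = 11.6
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        order = ("simulate", "augment", "cv")
        return int(
            np.random.SeedSequence((self.seed, order.index(stage))).generate_state(1)[0]
            % (2**31)
        )


def validate_config(cfg: PipelineConfig) -> List[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    violations: List[str] = []
    try:
        cfg.window.validate()
    except ValueError as exc:
        violations.append(f"window: {exc}")
    try:
        cfg.augment.validate()
    except ValueError as exc:
        violations.append(f"augment.multiplicity/mode: {exc}")
    try:
        cfg.spectral.validate()
    except ValueError as exc:
        violations.append(f"spectral: {exc}")
    try:
        cfg.train.validate()
    except ValueError as exc:
        violations.append(f"train: {exc}")
    try:
        trace_spec = replace(cfg.cnn_spec, input_length=cfg.window.target_length)
        shape_trace(trace_spec)
    except SpecificationError as exc:
        violations.append(f"cnn_spec: {exc}")
    if cfg.k_folds < 2:
        violations.append("k_folds: must be >= 2")
    unknown = set(cfg.algorithms) - set(ALGORITHMS)
    if unknown:
        violations.append(f"algorithms: unknown {sorted(unknown)}")
    return violations


@dataclass
class StudyResults:
    """Fitted-study results: metrics, statistics, and stage counts."""

    config: PipelineConfig
    reports: Dict[str, EvaluationReport]
    stats: StatsReport
    counts: Dict[str, int]
    feature_frame: pd.DataFrame

    def summary(self) -> str:
        """Formatted per-algorithm metric table plus the ANOVA line."""
        lines = [
            "VTA onset prediction study",
            "=" * 62,
            f"{'records':>22}: "
            + ", ".join(f"{k}={v}" for k, v in self.counts.items()),
            "-" * 62,
            f"{'Algorithm':<10}{'Sens (%)':>12}{'Spec (%)':>12}{'Acc (%)':>12}{'AUC':>8}",
        ]
        for name, rep in self.reports.items():
            se, ss, ac = rep.sensitivity, rep.specificity, rep.accuracy
            lines.append(
                f"{name:<10}{se[0]:>7.1f}±{se[1]:<4.1f}{ss[0]:>7.1f}±{ss[1]:<4.1f}"
                f"{ac[0]:>7.1f}±{ac[1]:<4.1f}{rep.auc:>8.3f}"
            )
        if self.stats.anova is not None:
            f_stat, dfb, dfw, p = self.stats.anova
            lines.append("-" * 62)
            lines.append(f"one-way ANOVA on fold accuracies: F({dfb}, {dfw}) = {f_stat:.2f}, p = {p:.3g}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        out = {
            "counts": self.counts,
            "reports": {k: v.as_dict() for k, v in self.reports.items()},
        }
        if self.stats.anova is not None:
            f_stat, dfb, dfw, p = self.stats.anova
            out["anova"] = {"F": f_stat, "df_between": dfb, "df_within": dfw, "p": p}
        if self.stats.posthoc is not None:
            out["posthoc"] = self.stats.posthoc
        if self.stats.per_feature_p is not None:
            out["feature_ttest_p"] = self.stats.per_feature_p
        return out

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(self.as_dict(), indent=2, sort_keys=True))
        self.feature_frame.to_csv(out / "features.csv", index=False)
        rows = []
        for name, rep in self.reports.items():
            for fpr, tpr in rep.roc_points:
                rows.append({"algorithm": name, "fpr": fpr, "tpr": tpr})
        pd.DataFrame(rows).to_csv(out / "roc_points.csv", index=False)
        return out

    def plot_roc(self, ax=None):
        """ROC curves of all evaluated algorithms on one axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, rep in self.reports.items():
            if rep.roc_points:
                fpr, tpr = zip(*rep.roc_points)
                ax.plot(fpr, tpr, label=f"{name} (AUC {rep.auc:.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend()
        return ax


class VTAStudy:
    """The study model: recordings plus configuration; ``fit()`` evaluates.

    Build from existing recordings, or via :meth:`from_synthetic` to
    generate a class-conditional synthetic cohort.
    """

    def __init__(self, recordings: Sequence[LabeledRecording], config: Optional[PipelineConfig] = None):
        self.recordings = list(recordings)
        self.config = config or PipelineConfig()
        violations = validate_config(self.config)
        if violations:
            raise ValueError("invalid configuration: " + "; ".join(violations))

    @classmethod
    def from_synthetic(
        cls,
        n_vta: int,
        n_control: int,
        config: Optional[PipelineConfig] = None,
        vta_params: Optional[synthetic.GeneratorParams] = None,
        control_params: Optional[synthetic.GeneratorParams] = None,
    ) -> "VTAStudy":
        config = config or PipelineConfig()
        recordings = synthetic.generate_dataset(
            n_vta,
            n_control,
            vta_params_=vta_params,
            control_params_=control_params,
            seed=config.stage_seed("simulate"),
        )
        return cls(recordings, config)

    # ------------------------------------------------------------------ fit

    def _prepare(self):
        """Window, augment (circular-shift of the raw windowed series) and
        LF/HF-filter the recordings.

        Augmentation and the outlier filter operate on the raw
        required-window RR series, not the 1000-point resampled vectors:
        index-resampling stretches the tachogram time axis, which would
        shift the LF/HF band contents and make the filter meaningless.
        Resampling to the fixed CNN input length happens afterwards, per
        kept recording.
        """
        cfg = self.config
        counts = {"original": len(self.recordings)}
        windowed = []
        for rec in self.recordings:
            series = extract_required_window(rec.data, cfg.window)
            windowed.append(rec.with_data(series))
        logger.info("windowed %d recordings to the required time", len(windowed))

        aug_cfg = replace(cfg.augment, seed=cfg.stage_seed("augment"))
        if aug_cfg.mode == PRE_SPLIT:
            augmented = augment_dataset(windowed, aug_cfg)
        else:
            augmented = windowed
        counts["augmented"] = len(augmented)
        logger.info("augmentation: %d -> %d recordings", len(windowed), len(augmented))

        kept, removed = filter_by_lfhf(augmented, cfg.lfhf_threshold, cfg.spectral)
        counts["lfhf_removed"] = removed
        counts["final"] = len(kept)
        logger.info("LF/HF filter (> %.1f): removed %d, kept %d",
                    cfg.lfhf_threshold, removed, len(kept))
        return kept, counts

    def fit(self) -> StudyResults:
        """Run every stage and cross-validate each configured algorithm."""
        cfg = self.config
        kept, counts = self._prepare()
        frame = feature_table(kept, cfg.spectral)
        X_feat = frame[list(frame.columns[:11])].to_numpy(float)
        X_cnn = np.stack(
            [resample_to_length(rec.values, cfg.window.target_length) for rec in kept]
        )
        y = np.array([1 if rec.label == VTA else 0 for rec in kept])

        cv_seed = cfg.stage_seed("cv")
        fold_safe = cfg.augment.mode == FOLD_SAFE

        def vector_augment(X_tr, y_tr, seed):
            rng = np.random.default_rng(seed)
            xs, ys = [X_tr], [y_tr]
            for _ in range(cfg.augment.multiplicity - 1):
                shifts = rng.integers(1, X_tr.shape[1], size=X_tr.shape[0])
                xs.append(np.stack([circular_shift(row, int(k)) for row, k in zip(X_tr, shifts)]))
                ys.append(y_tr)
            return np.concatenate(xs), np.concatenate(ys)

        builders = {
            "cnn": lambda s: build_cnn(
                replace(cfg.cnn_spec, input_length=cfg.window.target_length),
                replace(cfg.train, seed=s),
                seed=s,
            ),
            "ann": lambda s: build_ann(seed=s),
            "svm": lambda s: build_baseline("svm", seed=s),
            "knn": lambda s: build_baseline("knn", seed=s),
        }
        reports: Dict[str, EvaluationReport] = {}
        for name in cfg.algorithms:
            X = X_cnn if name == "cnn" else X_feat
            # fold-safe augmentation shifts the CNN's input vectors only;
            # the 11 HRV features are order-aggregated, so shifting their
            # rows would be meaningless
            use_aug = fold_safe and name == "cnn"
            reports[name] = cross_validate(
                builders[name],
                X,
                y,
                k=cfg.k_folds,
                seed=cv_seed,
                algorithm_id=name,
                augment_fn=vector_augment if use_aug else None,
                augment_mode=FOLD_SAFE if use_aug else PRE_SPLIT,
            )
            logger.info("%s: accuracy %.1f%%, AUC %.3f", name,
                        reports[name].accuracy[0], reports[name].auc)

        stats = StatsReport()
        if len(reports) >= 2:
            stats = compare_algorithms([r.fold_accuracies for r in reports.values()])
        mask = frame["label"] == VTA
        if mask.sum() >= 2 and (~mask).sum() >= 2:
            stats.per_feature_p = feature_ttest(X_feat[mask.to_numpy()], X_feat[~mask.to_numpy()])
        return StudyResults(
            config=cfg, reports=reports, stats=stats, counts=counts, feature_frame=frame
        )


def run_pipeline(cfg: PipelineConfig, recordings=None, n_vta: int = 0, n_control: int = 0,
                 out_dir=None) -> StudyResults:
    """One-call orchestration: simulate (or take recordings), fit, and
    optionally persist the report, feature table and ROC points."""
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    if recordings is None:
        study = VTAStudy.from_synthetic(n_vta, n_control, config=cfg)
    else:
        study = VTAStudy(recordings, config=cfg)
    results = study.fit()
    if out_dir is not None:
        results.save(out_dir)
    return results
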