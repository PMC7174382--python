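"""Cross-validated evaluation, confusion metrics, ROC/AUC and statistics.

Classes are encoded 0 = control, 1 = VTA throughout; sensitivity is the
VTA detection rate, specificity the control rejection rate, both in
percent. AUC is computed from the threshold-sweep ROC (trapezoidal rule),
which for finite score sets equals the probability that a random
VTA/control score pair is correctly ordered, ties counting one half.

Cross-validation is stratified 10-fold by default. Augmentation interacts
with splitting in two modes: ``pre_split`` folds a pre-augmented dataset
(which leaks shifted near-duplicates across folds), while ``fold_safe``
augments the training portion of each fold only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .datatypes import FEATURE_NAMES


@dataclass
class EvaluationReport:
    """Per-fold and aggregate classification metrics for one algorithm."""

    algorithm_id: str
    per_fold: List[Tuple[float, float, float]]  # (sens %, spec %, acc %)
    roc_points: List[Tuple[float, float]]  # (FPR, TPR)
    auc: float
    flagged_folds: List[int] = field(default_factory=list)

    def _agg(self, idx: int) -> Tuple[float, float]:
        vals = np.array([f[idx] for f in self.per_fold], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return float("nan"), float("nan")
        return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    @property
    def sensitivity(self) -> Tuple[float, float]:
        return self._agg(0)

    @property
    def specificity(self) -> Tuple[float, float]:
        return self._agg(1)

    @property
    def accuracy(self) -> Tuple[float, float]:
        return self._agg(2)

    @property
    def fold_accuracies(self) -> List[float]:
        return [f[2] for f in self.per_fold]

    def as_dict(self) -> dict:
        return {
            "algorithm": self.algorithm_id,
            "sensitivity_mean": self.sensitivity[0],
            "sensitivity_sd": self.sensitivity[1],
            "specificity_mean": self.specificity[0],
            "specificity_sd": self.specificity[1],
            "accuracy_mean": self.accuracy[0],
            "accuracy_sd": self.accuracy[1],
            "auc": self.auc,
            "per_fold": self.per_fold,
        }


@dataclass
class StatsReport:
    """Per-feature group tests plus the cross-algorithm ANOVA."""

    per_feature_p: Optional[dict] = None
    anova: Optional[Tuple[float, int, int, float]] = None  # (F, df_between, df_within, p)
    posthoc: Optional[List[Tuple[int, int, float]]] = None  # (group_i, group_j, p)


def kfold_split(
    n: int,
    k: int = 10,
    seed: int = 0,
    labels: Optional[Sequence] = None,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Random k-fold partition of ``range(n)``: disjoint test sets covering
    every index, sizes differing by at most one; stratified by ``labels``
    when given. Deterministic given ``seed``."""
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    if labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        arg = np.asarray(labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        arg = np.zeros(n)
    return [(tr, te) for tr, te in splitter.split(np.zeros(n), arg)]


def confusion_metrics(labels, predictions) -> Tuple[float, float, float]:
    """(sensitivity %, specificity %, accuracy %) of hard 0/1 predictions.

    A rate whose class is absent from the truth is NaN; accuracy is always
    defined.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must align")
    tp = int(np.sum((y == 1) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    acc = 100.0 * (tp + tn) / y.size
    return sens, spec, acc


def roc_auc(labels, scores) -> Tuple[List[Tuple[float, float]], float]:
    """Threshold-sweep ROC points and trapezoidal AUC."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def cross_validate(
    model_builder: Callable[[int], object],
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    algorithm_id: str = "model",
    augment_fn: Optional[Callable] = None,
    augment_mode: str = "pre_split",
    stratified: bool = True,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Stratified k-fold evaluation of ``model_builder``.

    ``model_builder(seed)`` must return an unfitted model understood by
    :func:`vtapredict.models.train_model`. In ``fold_safe`` mode,
    ``augment_fn(X_train, y_train, seed)`` expands each training fold; in
    ``pre_split`` mode ``X``/``y`` are assumed already augmented and a leakage
    warning is emitted when an ``augment_fn`` was supplied upstream. The
    ROC/AUC pools the out-of-fold scores. Folds whose training data is
    single-class are flagged and excluded from rate aggregation.
    """
    from .models import predict_proba, train_model

    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    folds = kfold_split(len(y), k=k, seed=seed, labels=y if stratified else None)
    per_fold: List[Tuple[float, float, float]] = []
    flagged: List[int] = []
    pooled_scores = np.empty(len(y))
    pooled_mask = np.zeros(len(y), bool)
    for i, (tr, te) in enumerate(folds):
        X_tr, y_tr = X[tr], y[tr]
        if augment_fn is not None and augment_mode == "fold_safe":
            X_tr, y_tr = augment_fn(X_tr, y_tr, seed + i)
        if len(np.unique(y_tr)) < 2:
            warnings.warn(f"fold {i}: single-class training data; fold flagged")
            flagged.append(i)
            per_fold.append((float("nan"), float("nan"), float("nan")))
            continue
        model = model_builder(seed + i)
        model, _ = train_model(model, X_tr, y_tr)
        scores = predict_proba(model, X[te])
        pooled_scores[te] = scores
        pooled_mask[te] = True
        per_fold.append(confusion_metrics(y[te], (scores >= threshold).astype(int)))
    if pooled_mask.any() and len(np.unique(y[pooled_mask])) == 2:
        points, auc = roc_auc(y[pooled_mask], pooled_scores[pooled_mask])
    else:
        points, auc = [], float("nan")
    return EvaluationReport(
        algorithm_id=algorithm_id,
        per_fold=per_fold,
        roc_points=points,
        auc=auc,
        flagged_folds=flagged,
    )


def feature_ttest(
    features_vta: np.ndarray,
    features_control: np.ndarray,
    equal_var: bool = False,
) -> dict:
    """Two-tailed two-sample t-test per HRV feature (Welch by default).

    Inputs are (n, 11) arrays in canonical feature order; returns
    ``{feature_name: p_value}``. Degenerate (zero-variance) features yield
    NaN.
    """
    a = np.asarray(features_vta, float)
    b = np.asarray(features_control, float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != len(FEATURE_NAMES) or b.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected (n, {len(FEATURE_NAMES)}) feature matrices")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 recordings per group")
    out = {}
    for j, name in enumerate(FEATURE_NAMES):
        if np.std(a[:, j]) == 0 and np.std(b[:, j]) == 0 and np.mean(a[:, j]) == np.mean(b[:, j]):
            out[name] = 1.0
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(a[:, j], b[:, j], equal_var=equal_var)
        out[name] = float(res.pvalue)
    return out


def compare_algorithms(fold_accuracies: Sequence[Sequence[float]]) -> StatsReport:
    """One-way ANOVA across algorithms' fold accuracies plus Tukey HSD
    post-hoc pairwise comparisons.

    Four algorithms with 10 folds each give df (3, 36). Returns a
    :class:`StatsReport` with ``anova=(F, df_between, df_within, p)``.
    """
    groups = [np.asarray(g, float) for g in fold_accuracies]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs at least 2 values")
    df_between = len(groups) - 1
    df_within = sum(g.size for g in groups) - len(groups)
    if all(np.allclose(g, groups[0].mean()) for g in groups) and all(
        np.allclose(g.mean(), groups[0].mean()) for g in groups
    ):
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*groups)
    posthoc = []
    if not all(g.std() == 0 for g in groups):
        tukey = stats.tukey_hsd(*groups)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                posthoc.append((i, j, float(tukey.pvalue[i, j])))
    return StatsReport(
        anova=(float(f_stat), df_between, df_within, float(p)),
        posthoc=posthoc,
    )
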