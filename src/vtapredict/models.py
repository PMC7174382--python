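"""Classifier construction: the 1-D CNN and the ANN/SVM/KNN baselines.

All four models expose the same contract: ``fit(X, y)`` with ``y`` in
{0, 1} (1 = VTA) and a module-level :func:`predict_proba` returning one
positive-class score in [0, 1] per input row. The CNN consumes 1000-point
resampled RR vectors; the baselines consume the 11-feature HRV vectors.

The feature-based models are scikit-learn estimators behind a
standardization step (fitted on the training data only) because SVM and
KNN are scale-sensitive; the ANN is a 11 -> 22 -> 22 -> 1 multilayer
perceptron with ReLU hidden units and a logistic output.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path
from typing import List, Optional

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .nn import CNNSpec, DivergenceError, Sequential, TrainConfig, build_network

__all__ = [
    "CNNClassifier",
    "build_cnn",
    "build_ann",
    "build_baseline",
    "train_model",
    "predict_proba",
    "save_model",
    "load_model",
    "TrainConfig",
    "CNNSpec",
]


class CNNClassifier:
    """The numpy 1-D CNN with input standardization.

    Inputs are standardized with a single scalar mean and SD estimated from
    the training set (the input is a homogeneous RR tachogram, so a global
    affine rescale preserves its shape while conditioning the first
    convolution). Deterministic given ``seed``.
    """

    def __init__(
        self,
        spec: Optional[CNNSpec] = None,
        train_config: Optional[TrainConfig] = None,
        seed: int = 0,
    ):
        self.spec = spec or CNNSpec()
        self.train_config = train_config or TrainConfig(seed=seed)
        self.seed = seed
        self.network: Sequential = build_network(self.spec, seed=seed)
        self.history: List[float] = []
        self._mu = 0.0
        self._sigma = 1.0
        self.fitted = False

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != self.spec.input_length:
            raise ValueError(
                f"expected inputs of shape (n, {self.spec.input_length}), got {X.shape}"
            )
        return ((X - self._mu) / self._sigma)[:, None, :]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNNClassifier":
        X = np.asarray(X, float)
        self._mu = float(X.mean())
        self._sigma = float(X.std()) or 1.0
        # fresh weights on every fit so refitting is reproducible
        self.network = build_network(self.spec, seed=self.seed)
        self.history = self.network.fit(self._prepare(X), np.asarray(y), self.train_config)
        self.fitted = True
        return self

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("CNNClassifier is not fitted")
        X = np.asarray(X, float)
        if X.shape[0] == 0:
            return np.empty(0)
        return self.network.predict_proba1(self._prepare(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba1(X) >= 0.5).astype(int)


def build_cnn(
    spec: Optional[CNNSpec] = None,
    train_config: Optional[TrainConfig] = None,
    seed: int = 0,
) -> CNNClassifier:
    """The 1-D CNN classifier; raises
    :class:`~vtapredict.nn.SpecificationError` on an inconsistent spec."""
    return CNNClassifier(spec=spec, train_config=train_config, seed=seed)


def build_ann(hidden: tuple = (22, 22), seed: int = 0, max_iter: int = 500) -> Pipeline:
    """Two ReLU hidden layers of 22 units and a logistic output over the
    11 standardized HRV features."""
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "clf",
                MLPClassifier(
                    hidden_layer_sizes=hidden,
                    activation="relu",
                    solver="adam",
                    max_iter=max_iter,
                    random_state=seed,
                ),
            ),
        ]
    )


def build_baseline(kind: str, seed: int = 0, **hyperparams) -> Pipeline:
    """``kind`` is ``"svm"`` (RBF kernel) or ``"knn"`` (k=5); both behind a
    standardizer. Unknown kinds raise ValueError."""
    if kind == "svm":
        clf = SVC(
            kernel=hyperparams.pop("kernel", "rbf"),
            C=hyperparams.pop("C", 1.0),
            random_state=seed,
            **hyperparams,
        )
    elif kind == "knn":
        clf = KNeighborsClassifier(n_neighbors=hyperparams.pop("k", 5), **hyperparams)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}; use 'svm' or 'knn'")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_model(model, X: np.ndarray, y: np.ndarray, cfg: Optional[TrainConfig] = None):
    """Fit any of the four models; returns ``(model, history)`` where
    ``history`` is the per-epoch loss curve when the model exposes one."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} inputs vs {y.shape[0]} labels")
    if isinstance(model, CNNClassifier):
        if cfg is not None:
            model.train_config = cfg
        model.fit(X, y)
        return model, list(model.history)
    model.fit(X, y)
    final = model.named_steps.get("clf") if hasattr(model, "named_steps") else model
    history = list(getattr(final, "loss_curve_", []))
    return model, history


def predict_proba(model, X: np.ndarray) -> np.ndarray:
    """Positive-class (VTA) score in [0, 1] per input row; empty input gives
    an empty array. Raises if the model is unfitted."""
    X = np.asarray(X, float)
    if X.shape[0] == 0:
        return np.empty(0)
    if isinstance(model, (CNNClassifier, Sequential)):
        return model.predict_proba1(X)
    if hasattr(model, "predict_proba"):
        try:
            proba = model.predict_proba(X)
            classes = list(model.classes_)
            return proba[:, classes.index(1)]
        except AttributeError:
            pass  # e.g. SVC without probability estimates
    # margin classifiers: logistic squash of the signed decision function
    # (monotone, so ROC/AUC are unchanged; 0.5 maps to the decision boundary)
    margin = model.decision_function(X)
    return 1.0 / (1.0 + np.exp(-margin))


def save_model(model, out_dir) -> Path:
    """Serialize a fitted model to ``out_dir``: the CNN as a JSON spec plus
    an ``.npz`` of weights and normalization constants; scikit-learn models
    as a pickle. Returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(model, CNNClassifier):
        meta = {
            "kind": "cnn",
            "spec": {
                "input_length": model.spec.input_length,
                "conv_blocks": [vars(b) for b in model.spec.conv_blocks],
                "dense_head": list(model.spec.dense_head),
            },
            "seed": model.seed,
            "mu": model._mu,
            "sigma": model._sigma,
        }
        (out / "model.json").write_text(json.dumps(meta, indent=2))
        arrays = {}
        i = 0
        for layer in model.network.layers:
            for p, _ in layer.params():
                arrays[f"p{i}"] = p
                i += 1
        for j, layer in enumerate(model.network.layers):
            if hasattr(layer, "running_mean"):
                arrays[f"rm{j}"] = layer.running_mean
                arrays[f"rv{j}"] = layer.running_var
        np.savez(out / "weights.npz", **arrays)
    else:
        (out / "model.json").write_text(json.dumps({"kind": "sklearn"}))
        with open(out / "model.pkl", "wb") as fh:
            pickle.dump(model, fh)
    return out


def load_model(model_dir):
    """Inverse of :func:`save_model`."""
    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "model.json").read_text())
    if meta["kind"] == "cnn":
        from .nn import ConvBlockSpec

        spec = CNNSpec(
            input_length=meta["spec"]["input_length"],
            conv_blocks=tuple(ConvBlockSpec(**b) for b in meta["spec"]["conv_blocks"]),
            dense_head=tuple(meta["spec"]["dense_head"]),
        )
        model = CNNClassifier(spec=spec, seed=meta["seed"])
        model._mu, model._sigma = meta["mu"], meta["sigma"]
        data = np.load(model_dir / "weights.npz")
        i = 0
        for layer in model.network.layers:
            for p, _ in layer.params():
                p[...] = data[f"p{i}"]
                i += 1
        for j, layer in enumerate(model.network.layers):
            if hasattr(layer, "running_mean"):
                layer.running_mean = data[f"rm{j}"]
                layer.running_var = data[f"rv{j}"]
        model.fitted = True
        model.network.fitted = True
        return model
    with open(model_dir / "model.pkl", "rb") as fh:
        return pickle.load(fh)
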