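import numpy as np
import pytest

from vtapredict import features, preprocess, synthetic
from vtapredict.datatypes import VTA


def _dataset_arrays(n_vta, n_control, seed, **overrides):
    """Generate, window, featurize and resample a synthetic cohort."""
    vta_p = synthetic.vta_params(**overrides)
    ctl_p = synthetic.control_params(**overrides)
    recs = synthetic.generate_dataset(n_vta, n_control, vta_p, ctl_p, seed=seed)
    win = preprocess.WindowConfig()
    X_feat, X_cnn, y = [], [], []
    for rec in recs:
        series = preprocess.extract_required_window(rec.data, win)
        X_feat.append(features.extract_features(series).as_array())
        X_cnn.append(preprocess.resample_to_length(series, win.target_length))
        y.append(1 if rec.label == VTA else 0)
    return np.array(X_feat), np.array(X_cnn), np.array(y)


@pytest.fixture(scope="session")
def separated_dataset():
    """50 recordings at the class mean-NN gap with no between-recording
    mean spread and low jitter: nearly separable by design."""
    return _dataset_arrays(25, 25, seed=11, noise_sd=10.0, mean_sd=0.0)


@pytest.fixture(scope="session")
def study_scale_dataset():
    """200 recordings at the default class-conditional settings."""
    return _dataset_arrays(100, 100, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
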