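import numpy as np
import pytest

from vtapredict import models
from vtapredict.nn import (
    CNNSpec,
    ConvBlockSpec,
    SpecificationError,
    TrainConfig,
    build_network,
    shape_trace,
)

from .oracles import conv_pool_trace


class TestShapeTrace:
    def test_default_spec_layer_counts(self):
        spec = CNNSpec()
        assert [b.filters for b in spec.conv_blocks] == [3, 10, 10, 10]
        assert [b.kernel_size for b in spec.conv_blocks] == [102, 24, 11, 9]

    def test_default_spec_flattened_width_matches_hand_trace(self):
        trace = shape_trace(CNNSpec())
        assert trace["lengths"] == [899, 449, 426, 213, 203, 101, 93, 46]
        assert trace["flattened"] == 460
        blocks = [(3, 102), (10, 24), (10, 11), (10, 9)]
        assert conv_pool_trace(1000, blocks) == 460

    @pytest.mark.parametrize(
        "spec",
        [
            CNNSpec(input_length=1000, conv_blocks=(ConvBlockSpec(2, 2000),)),
            CNNSpec(input_length=50, conv_blocks=(ConvBlockSpec(3, 102),)),
        ],
    )
    def test_kernel_underflow_names_block(self, spec):
        with pytest.raises(SpecificationError, match="block 1"):
            shape_trace(spec)

    def test_forward_pass_shape_matches_analytic_trace(self, rng):
        # oracle equivalence between the shape calculator and the network
        for blocks in [
            ((ConvBlockSpec(2, 7), ConvBlockSpec(4, 5))),
            ((ConvBlockSpec(3, 11, pool_size=3),)),
            ((ConvBlockSpec(2, 6, stride=2),)),
        ]:
            spec = CNNSpec(input_length=120, conv_blocks=blocks, dense_head=(5, 1))
            net = build_network(spec, seed=0)
            x = rng.normal(size=(2, 1, 120))
            # run up to the flatten layer to observe the conv-stack shape
            h = x
            for layer in net.layers:
                h = layer.forward(h, train=False)
                if type(layer).__name__ == "Flatten":
                    break
            assert h.shape == (2, shape_trace(spec)["flattened"])


class TestNetworkTraining:
    def test_gradients_match_numeric_differentiation(self):
        spec = CNNSpec(
            input_length=30,
            conv_blocks=(ConvBlockSpec(2, 5), ConvBlockSpec(3, 4)),
            dense_head=(4, 1),
        )
        net = build_network(spec, seed=0)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 1, 30))
        y = np.array([0.0, 1.0, 1.0, 0.0])

        def loss():
            z = net.forward(x, train=True).ravel()
            return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))

        z = net.forward(x, train=True).ravel()
        p = 1 / (1 + np.exp(-z))
        net.backward(((p - y) / z.size)[:, None])
        eps, worst = 1e-6, 0.0
        for par, grad in net.params():
            for idx in [tuple(rng.integers(0, s) for s in par.shape) for _ in range(3)]:
                orig = par[idx]
                par[idx] = orig + eps
                lp = loss()
                par[idx] = orig - eps
                lm = loss()
                par[idx] = orig
                num = (lp - lm) / (2 * eps)
                worst = max(worst, abs(num - grad[idx]) / max(1e-8, abs(num) + abs(grad[idx])))
        assert worst < 1e-5

    def test_training_is_deterministic_given_seed(self, rng):
        X = rng.normal(700, 50, size=(24, 100))
        y = (rng.random(24) > 0.5).astype(int)
        spec = CNNSpec(input_length=100, conv_blocks=(ConvBlockSpec(2, 9),), dense_head=(4, 1))

        def run():
            m = models.build_cnn(spec, TrainConfig(epochs=3, seed=5), seed=5)
            m.fit(X, y)
            return models.predict_proba(m, X)

        assert np.array_equal(run(), run())

    def test_loss_history_decreases_on_separable_data(self, rng):
        X = np.vstack([rng.normal(600, 5, (16, 80)), rng.normal(900, 5, (16, 80))])
        y = np.array([1] * 16 + [0] * 16)
        spec = CNNSpec(input_length=80, conv_blocks=(ConvBlockSpec(2, 9),), dense_head=(4, 1))
        m = models.build_cnn(spec, TrainConfig(epochs=15, seed=0), seed=0)
        m.fit(X, y)
        assert m.history[-1] < m.history[0]
        assert np.mean(m.predict(X) == y) >= 0.95

    def test_mismatched_shapes_rejected(self, rng):
        m = models.build_cnn(CNNSpec(input_length=100, conv_blocks=(ConvBlockSpec(2, 9),)))
        with pytest.raises(ValueError):
            m.fit(rng.normal(size=(4, 50)), np.zeros(4))


class TestBaselines:
    def test_ann_architecture_and_parameter_count(self, rng):
        model = models.build_ann(seed=0)
        X = rng.normal(size=(30, 11))
        y = (rng.random(30) > 0.5).astype(int)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny random data need not converge
            model.fit(X, y)
        mlp = model.named_steps["clf"]
        assert [c.shape for c in mlp.coefs_] == [(11, 22), (22, 22), (22, 1)]
        n_params = sum(c.size for c in mlp.coefs_) + sum(i.size for i in mlp.intercepts_)
        assert n_params == 793
        scores = models.predict_proba(model, X)
        assert np.all((scores > 0) & (scores < 1))

    def test_knn_k1_memorizes_training_set(self, rng):
        model = models.build_baseline("knn", k=1)
        X = rng.normal(size=(20, 11))
        y = (rng.random(20) > 0.5).astype(int)
        model.fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_svm_separates_separable_points(self):
        model = models.build_baseline("svm")
        X = np.array([[0.0] * 11, [10.0] * 11])
        y = np.array([0, 1])
        model.fit(X, y)
        assert list(model.predict(X)) == [0, 1]
        scores = models.predict_proba(model, X)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_unknown_baseline_kind_rejected(self):
        with pytest.raises(ValueError, match="rf"):
            models.build_baseline("rf")

    def test_predict_proba_contracts(self, rng):
        m = models.build_cnn(CNNSpec(input_length=50, conv_blocks=(ConvBlockSpec(2, 5),)))
        with pytest.raises(RuntimeError):
            m.predict_proba1(rng.normal(size=(2, 50)))
        X = rng.normal(700, 30, size=(10, 50))
        y = np.array([0, 1] * 5)
        m.train_config = TrainConfig(epochs=2, seed=0)
        m.fit(X, y)
        assert models.predict_proba(m, np.empty((0, 50))).size == 0
        scores = models.predict_proba(m, X)
        assert np.all((scores >= 0) & (scores <= 1))
        assert set(np.unique((scores >= 0.5).astype(int))) <= {0, 1}


class TestSerialization:
    def test_cnn_roundtrip_preserves_predictions(self, tmp_path, rng):
        spec = CNNSpec(input_length=60, conv_blocks=(ConvBlockSpec(2, 7),), dense_head=(4, 1))
        m = models.build_cnn(spec, TrainConfig(epochs=3, seed=1), seed=1)
        X = rng.normal(700, 40, size=(12, 60))
        y = np.array([0, 1] * 6)
        m.fit(X, y)
        models.save_model(m, tmp_path / "cnn")
        back = models.load_model(tmp_path / "cnn")
        assert np.allclose(models.predict_proba(back, X), models.predict_proba(m, X))

    def test_sklearn_roundtrip(self, tmp_path, rng):
        model = models.build_baseline("knn")
        X = rng.normal(size=(15, 11))
        y = (rng.random(15) > 0.5).astype(int)
        model.fit(X, y)
        models.save_model(model, tmp_path / "knn")
        back = models.load_model(tmp_path / "knn")
        assert np.array_equal(back.predict(X), model.predict(X))
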