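"""Network construction, gradient correctness, training contract."""

import numpy as np
import pytest

from fallwalk.nets import ModelSpec, TaskHead, build_model, default_head, predict, train
from fallwalk.nets.model import _head_loss_grad, _total_loss


def _toy_data(n=16, T=40, seed=0, n_ids=3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 3, T))
    y = {"fall_status": rng.integers(0, 2, n), "identity": rng.integers(0, n_ids, n)}
    return X, y


def _small_spec(**kw):
    base = dict(family="ConvLSTM", n_filters=4, kernel_size=3, pool=2, pool_layers=5,
                dropout_rate=0.0, epochs=3, batch_size=8, seed=0)
    base.update(kw)
    return ModelSpec(**base)


class TestModelSpec:
    def test_convlstm_default_filter_taper(self):
        spec = ModelSpec(family="ConvLSTM", n_filters=128)
        assert spec.conv_layer_filters == [128, 128, 128, 96, 96]
        assert spec.lstm_layers == 1

    def test_family_invariants_enforced(self):
        with pytest.raises(ValueError):
            ModelSpec(family="LSTM", lstm_layers=0)
        with pytest.raises(ValueError):
            ModelSpec(family="ConvLSTM", lstm_layers=2)
        with pytest.raises(ValueError):
            ModelSpec(family="CNN", lstm_layers=1)

    def test_exactly_one_main_head(self):
        with pytest.raises(ValueError):
            ModelSpec(heads=[default_head("gender")])
        with pytest.raises(ValueError):
            TaskHead("fall_status", 2, "categorical_cross_entropy", loss_weight=0.0)


class TestBuildModel:
    def test_identical_seeds_identical_parameters(self):
        a = build_model(_small_spec(), input_shape=(3, 40))
        b = build_model(_small_spec(), input_shape=(3, 40))
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_parameter_count_reported(self):
        net = build_model(_small_spec(), input_shape=(3, 40))
        assert net.n_parameters == sum(p.value.size for p in net.params()) > 0

    @pytest.mark.parametrize("family,n_lstm", [("CNN", 0), ("LSTM", 2), ("ConvLSTM", 1)])
    def test_all_families_forward(self, family, n_lstm):
        spec = _small_spec(family=family, lstm_layers=n_lstm or None)
        net = build_model(spec, input_shape=(3, 40))
        X, _ = _toy_data()
        out = net.forward(X)
        assert out["fall_status"].shape == (16, 2)

    def test_gradient_check_multitask_convlstm(self):
        """Backprop gradients match central finite differences."""
        spec = _small_spec(heads=[default_head("fall_status"),
                                  default_head("identity", n_subjects=3, loss_weight=2.0)])
        net = build_model(spec, input_shape=(3, 40))
        X, y = _toy_data(n=10)
        logits = net.forward(X)
        grads = {}
        for task, h in net.head_specs.items():
            _, g = _head_loss_grad(h.loss_kind, logits[task], y[task])
            grads[task] = h.loss_weight * g
        for p in net.params():
            p.grad[...] = 0.0
        net.backward(grads)
        rng = np.random.default_rng(1)
        eps = 1e-6
        for p in net.params():
            for _ in range(2):
                idx = tuple(rng.integers(0, s) for s in p.value.shape)
                old = p.value[idx]
                p.value[idx] = old + eps
                lp, _ = _total_loss(net, X, y)
                p.value[idx] = old - eps
                lm, _ = _total_loss(net, X, y)
                p.value[idx] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - p.grad[idx]) <= 1e-4 * max(1.0, abs(num))

    def test_gradient_check_regression_and_sigmoid_heads(self):
        spec = _small_spec(family="CNN", lstm_layers=None, pool_layers=2,
                           heads=[default_head("fall_status"), default_head("gender", loss_weight=0.5),
                                  default_head("age", loss_weight=3.0)])
        net = build_model(spec, input_shape=(3, 30))
        rng = np.random.default_rng(2)
        X = rng.standard_normal((8, 3, 30))
        y = {"fall_status": rng.integers(0, 2, 8), "gender": rng.integers(0, 2, 8).astype(float),
             "age": rng.standard_normal(8)}
        logits = net.forward(X)
        grads = {t: h.loss_weight * _head_loss_grad(h.loss_kind, logits[t], y[t])[1]
                 for t, h in net.head_specs.items()}
        for p in net.params():
            p.grad[...] = 0.0
        net.backward(grads)
        eps = 1e-6
        for p in net.params():
            idx = tuple(0 for _ in p.value.shape)
            old = p.value[idx]
            p.value[idx] = old + eps
            lp, _ = _total_loss(net, X, y)
            p.value[idx] = old - eps
            lm, _ = _total_loss(net, X, y)
            p.value[idx] = old
            num = (lp - lm) / (2 * eps)
            assert abs(num - p.grad[idx]) <= 1e-4 * max(1.0, abs(num))


class TestTrainPredict:
    def test_training_reduces_loss_on_separable_data(self):
        rng = np.random.default_rng(3)
        n = 60
        y = rng.integers(0, 2, n)
        X = rng.normal(0, 0.1, (n, 3, 40)) + y[:, None, None] * 0.8
        spec = _small_spec(epochs=15, learning_rate=1e-2)
        net = build_model(spec, input_shape=(3, 40))
        m = train(net, X, {"fall_status": y}, X[:10], {"fall_status": y[:10]})
        assert m.history["loss"][-1] < m.history["loss"][0]
        scores = predict(m, X)["fall_status"]
        # capacity sanity: separable data is fit well within the epoch budget
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, scores) >= 0.95

    def test_loss_decomposition_every_epoch(self):
        X, y = _toy_data(n=24)
        spec = _small_spec(epochs=4, heads=[default_head("fall_status", loss_weight=10.0),
                                            default_head("identity", n_subjects=3, loss_weight=1.0)])
        net = build_model(spec, input_shape=(3, 40))
        m = train(net, X, y, X[:8], {t: v[:8] for t, v in y.items()})
        for e in range(len(m.history["loss"])):
            recombined = sum(
                net.head_specs[t].loss_weight * m.history[f"loss_{t}"][e] for t in net.head_specs
            )
            assert m.history["loss"][e] == pytest.approx(recombined, rel=1e-6)

    def test_missing_head_labels_rejected_before_training(self):
        X, y = _toy_data()
        spec = _small_spec(heads=[default_head("fall_status"), default_head("gender")])
        net = build_model(spec, input_shape=(3, 40))
        with pytest.raises(ValueError, match="gender"):
            train(net, X, {"fall_status": y["fall_status"]}, X, {"fall_status": y["fall_status"]})

    def test_single_class_labels_warn_but_train(self):
        X, _ = _toy_data()
        y = {"fall_status": np.zeros(16, int)}
        net = build_model(_small_spec(epochs=2), input_shape=(3, 40))
        with pytest.warns(UserWarning, match="one fall-status class"):
            train(net, X, y, X[:4], {"fall_status": y["fall_status"][:4]})

    def test_predict_contract(self):
        X, y = _toy_data(n=12)
        spec = _small_spec(epochs=2, heads=[default_head("fall_status"),
                                            default_head("identity", n_subjects=3)])
        net = build_model(spec, input_shape=(3, 40))
        m = train(net, X, y, X[:4], {t: v[:4] for t, v in y.items()})
        out = predict(m, X)
        assert out["fall_status"].shape == (12,)
        assert np.all((out["fall_status"] >= 0) & (out["fall_status"] <= 1))
        assert out["identity"].shape == (12, 3)
        assert np.allclose(out["identity"].sum(axis=1), 1.0)
        # inference is deterministic: a duplicated window scores identically
        dup = np.stack([X[0], X[0]])
        sd = predict(m, dup)["fall_status"]
        assert sd[0] == sd[1]
        with pytest.raises(ValueError):
            predict(m, X[:, :2, :])

    def test_untrained_model_rejected(self):
        net = build_model(_small_spec(), input_shape=(3, 40))
        with pytest.raises(ValueError, match="not trained"):
            predict(net, np.zeros((1, 3, 40)))
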