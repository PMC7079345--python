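import numpy as np
import pytest

from dtilearn._nn import (
    DenseLayer,
    Dropout,
    LastStep,
    LSTMLayer,
    Network,
    mse_loss_and_grad,
    softmax,
)
from dtilearn.models import (
    DeepLSTMClassifier,
    GridSearchSVM,
    LSTMConfig,
    MLPBaselineClassifier,
    TrainingError,
    build_deep_lstm,
    build_mlp_baseline,
    load_network_model,
    lstm_layer_parameter_count,
    predict,
    save_network_model,
    train_svm_baseline,
)


def separable_data(rng, n=200, d=40, margin=2.0):
    """Linearly separable binary data along a random direction."""
    w = rng.normal(size=d)
    w /= np.linalg.norm(w)
    X = rng.normal(size=(n, d))
    y = (X @ w > 0).astype(int)
    X += margin * np.outer(2 * y - 1, w)
    return X, y


class TestEngine:
    def test_lstm_parameter_count(self):
        rng = np.random.default_rng(0)
        layer = LSTMLayer(5, 3, rng)
        assert layer.n_parameters == 4 * (5 * 3 + 9 + 3) == 108
        assert lstm_layer_parameter_count(5, 3) == 108
        assert sum(p.size for p in layer.params()) == 108

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        net = Network([LSTMLayer(5, 4, rng), LastStep(), DenseLayer(4, 2, rng)])
        X = rng.normal(size=(6, 2, 5))  # two timesteps exercises BPTT
        Y = np.eye(2)[rng.integers(0, 2, size=6)]

        def loss():
            return mse_loss_and_grad(softmax(net.forward(X)), Y)[0]

        _, dl = mse_loss_and_grad(softmax(net.forward(X)), Y)
        net.backward(dl)
        grads = [g.copy() for g in net.grads()]
        eps = 1e-6
        for p, g in zip(net.params(), grads):
            flat_idx = np.unravel_index(
                np.argmax(np.abs(g)), g.shape
            )  # check the largest-gradient entry of every tensor
            orig = p[flat_idx]
            p[flat_idx] = orig + eps
            lp = loss()
            p[flat_idx] = orig - eps
            lm = loss()
            p[flat_idx] = orig
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(g[flat_idx], rel=1e-4, abs=1e-8)

    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        p = softmax(rng.normal(size=(10, 2)) * 30)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p >= 0).all()

    def test_dropout_identity_at_inference(self):
        rng = np.random.default_rng(0)
        layer = Dropout(0.5, rng)
        x = rng.normal(size=(4, 6))
        np.testing.assert_array_equal(layer.forward(x, train=False), x)


class TestArchitectures:
    def test_default_lstm_topology(self):
        model = build_deep_lstm()
        rng = np.random.default_rng(0)
        net = model._build(400, rng)
        lstm_layers = [l for l in net.layers if isinstance(l, LSTMLayer)]
        assert len(lstm_layers) == 4
        assert all(l.units == 36 for l in lstm_layers)
        assert net.layers[-1].W.shape == (36, 2)  # 2-way softmax head

    def test_default_mlp_topology(self):
        model = build_mlp_baseline()
        rng = np.random.default_rng(0)
        net = model._build(400, rng)
        dense_hidden = [l for l in net.layers[:-1] if isinstance(l, DenseLayer)]
        assert len(dense_hidden) == 4
        assert all(l.W.shape[1] == 36 for l in dense_hidden)

    def test_zero_layers_rejected(self):
        with pytest.raises(ValueError):
            LSTMConfig(n_hidden_layers=0)
        with pytest.raises(ValueError):
            DeepLSTMClassifier(n_hidden_layers=0).fit(
                np.zeros((20, 4)), np.array([0, 1] * 10)
            )


class TestTraining:
    def test_learns_separable_data(self, rng):
        X, y = separable_data(rng)
        model = DeepLSTMClassifier(max_epochs=120, random_state=0)
        model.fit(X, y)
        assert model.history_[-1]["train_loss"] < model.history_[0]["train_loss"]
        assert model.best_epoch_ <= model.max_epochs

    def test_determinism_same_seed(self, rng):
        X, y = separable_data(rng, n=80, d=10)
        runs = []
        for _ in range(2):
            m = DeepLSTMClassifier(max_epochs=15, random_state=11).fit(X, y)
            runs.append((m.history_, m.predict_score(X)))
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_single_class_labels_rejected(self, rng):
        X = rng.normal(size=(30, 5))
        with pytest.raises(TrainingError):
            DeepLSTMClassifier().fit(X, np.zeros(30, dtype=int))

    def test_empty_training_set_rejected(self):
        with pytest.raises(TrainingError):
            DeepLSTMClassifier().fit(np.empty((0, 4)), np.empty(0, dtype=int))

    def test_early_stop_restores_best_epoch(self, rng):
        X, y = separable_data(rng, n=120, d=12)
        m = DeepLSTMClassifier(max_epochs=60, random_state=2).fit(X, y)
        val_losses = [h["val_loss"] for h in m.history_]
        assert min(val_losses) == val_losses[m.best_epoch_ - 1]

    def test_scores_are_probabilities(self, rng):
        X, y = separable_data(rng, n=100, d=8)
        m = DeepLSTMClassifier(max_epochs=20, random_state=0).fit(X, y)
        p = m.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        s = predict(m, X)
        assert ((s >= 0) & (s <= 1)).all()

    def test_inference_is_deterministic(self, rng):
        X, y = separable_data(rng, n=80, d=6)
        m = MLPBaselineClassifier(max_epochs=15, random_state=0).fit(X, y)
        s1, s2 = m.predict_score(X), m.predict_score(X)
        np.testing.assert_array_equal(s1, s2)

    @pytest.mark.parametrize("cls", [DeepLSTMClassifier, MLPBaselineClassifier])
    def test_separable_heldout_auc(self, cls, rng):
        from dtilearn.evaluation import compute_auc

        X, y = separable_data(rng, n=300, d=40)
        m = cls(max_epochs=150, random_state=0).fit(X[:200], y[:200], X_val=X[200:250], y_val=y[200:250])
        assert compute_auc(y[250:], m.predict_score(X[250:])) >= 0.95

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        X, y = separable_data(rng, n=80, d=6)
        m = DeepLSTMClassifier(max_epochs=10, random_state=0).fit(X, y)
        save_network_model(m, tmp_path / "m.npz")
        loaded = load_network_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(loaded.predict_score(X), m.predict_score(X))
        assert loaded.best_epoch_ == m.best_epoch_


class TestSVM:
    def test_degenerate_grid_selected(self, rng):
        X, y = separable_data(rng, n=60, d=5)
        m = GridSearchSVM(c_grid=(2.0,), gamma_grid=(0.05,), k_folds=3).fit(X, y)
        assert m.best_params_ == {"C": 2.0, "gamma": 0.05}

    def test_xor_pattern_rbf(self, rng):
        X = rng.uniform(-1, 1, size=(200, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        m = train_svm_baseline(X, y, c_grid=(1.0, 10.0), gamma_grid=(1.0, "scale"), seed=0)
        assert (m.predict(X) == y).mean() > 0.9

    def test_determinism(self, rng):
        X, y = separable_data(rng, n=60, d=4)
        s1 = train_svm_baseline(X, y, seed=5).predict_score(X)
        s2 = train_svm_baseline(X, y, seed=5).predict_score(X)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(TrainingError):
            train_svm_baseline(X, np.ones(20, dtype=int))

    def test_scores_in_unit_interval(self, rng):
        X, y = separable_data(rng, n=60, d=4)
        s = train_svm_baseline(X, y).predict_score(X)
        assert ((s >= 0) & (s <= 1)).all()
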