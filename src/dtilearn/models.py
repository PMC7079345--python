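"""DTI classifiers: stacked-LSTM network and MLP / SVM baselines.

The primary model is a deep LSTM: four stacked LSTM layers of 36 memory
cells (sigmoid gates, tanh cell activations), dropout 0.5 between layers,
and a 2-way softmax head, trained with mean squared error and the Nadam
optimizer (initial learning rate 0.002, decay 0.004, momentum 0.5, batch
size 64, at most 500 epochs) with early stopping on validation loss and
restoration of the best epoch.  The MLP baseline matches depth, width,
dropout, loss and optimizer; the SVM baseline is an RBF support-vector
machine with grid-searched (C, gamma).

Input vectors are presented to the recurrent layers as a single time step
(time_steps=1); weights are initialized from N(0, 0.1^2), seed-controlled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.svm import SVC

from ._nn import DenseLayer, Dropout, LastStep, LSTMLayer, Nadam, Network, mse_loss_and_grad, softmax

__all__ = [
    "LSTMConfig",
    "DeepLSTMClassifier",
    "MLPBaselineClassifier",
    "GridSearchSVM",
    "build_deep_lstm",
    "build_mlp_baseline",
    "train_model",
    "train_svm_baseline",
    "predict",
    "lstm_layer_parameter_count",
]


class TrainingError(ValueError):
    """Raised for degenerate training inputs (empty or single-class)."""


@dataclass
class LSTMConfig:
    """Hyperparameters of the deep LSTM (defaults follow the method)."""

    n_hidden_layers: int = 4
    units_per_layer: int = 36
    dropout_rate: float = 0.5
    input_dim: int = 400
    time_steps: int = 1
    batch_size: int = 64
    max_epochs: int = 500
    learning_rate: float = 0.002
    lr_decay: float = 0.004
    momentum: float = 0.5
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden_layers < 1 or self.units_per_layer < 1:
            raise ValueError("layer and unit counts must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 1 or self.time_steps < 1:
            raise ValueError("batch size, epochs and time steps must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def lstm_layer_parameter_count(d_in: int, units: int) -> int:
    """4(d*u + u^2 + u): input/forget/cell/output weights plus biases."""
    return 4 * (d_in * units + units**2 + units)


def _check_labels(y: np.ndarray, what: str = "training") -> np.ndarray:
    y = np.asarray(y).astype(int).ravel()
    if y.size == 0:
        raise TrainingError(f"empty {what} set")
    classes = np.unique(y)
    if not np.isin(classes, (0, 1)).all():
        raise TrainingError("labels must be binary 0/1")
    if classes.size < 2:
        raise TrainingError(f"{what} labels contain a single class")
    return y


class _BaseNetClassifier:
    """Shared training loop for the NumPy network classifiers."""

    arch: str = "net"

    def __init__(
        self,
        n_hidden_layers: int = 4,
        units_per_layer: int = 36,
        dropout_rate: float = 0.5,
        time_steps: int = 1,
        batch_size: int = 64,
        max_epochs: int = 500,
        learning_rate: float = 0.002,
        lr_decay: float = 0.004,
        momentum: float = 0.5,
        early_stop_patience: int = 50,
        input_scaling: str | None = "rms",
        random_state: int = 0,
    ):
        self.n_hidden_layers = n_hidden_layers
        self.units_per_layer = units_per_layer
        self.dropout_rate = dropout_rate
        self.time_steps = time_steps
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.momentum = momentum
        self.early_stop_patience = early_stop_patience
        self.input_scaling = input_scaling
        self.random_state = random_state

    # -- sklearn plumbing --------------------------------------------------
    _param_names = (
        "n_hidden_layers", "units_per_layer", "dropout_rate", "time_steps",
        "batch_size", "max_epochs", "learning_rate", "lr_decay", "momentum",
        "early_stop_patience", "input_scaling", "random_state",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- architecture (overridden) ----------------------------------------
    def _build(self, input_dim: int, rng: np.random.Generator) -> Network:
        raise NotImplementedError

    def _shape_input(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        if self.n_hidden_layers < 1 or self.units_per_layer < 1:
            raise ValueError("layer and unit counts must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        y = _check_labels(y)
        if X.shape[0] != y.size:
            raise ValueError("X and y length mismatch")

        if X_val is None or y_val is None:
            # carve an internal stratified validation split when none is given
            X, X_val, y, y_val = train_test_split(
                X, y, test_size=0.2, stratify=y, random_state=self.random_state
            )
        else:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val).astype(int).ravel()
            if X_val.shape[0] == 0:
                raise TrainingError("validation set is empty")

        if self.input_scaling not in (None, "none", "rms"):
            raise ValueError("input_scaling must be 'rms' or None")
        if self.input_scaling == "rms":
            # one global scale keeps gate/unit pre-activations in the linear
            # regime under the N(0, 0.1^2) weight init without reweighting
            # individual components
            sd = float(X.std())
            self.input_scale_ = sd if sd > 0 else 1.0
        else:
            self.input_scale_ = 1.0
        X = X / self.input_scale_
        X_val = X_val / self.input_scale_

        rng = np.random.default_rng(self.random_state)
        self.n_features_in_ = X.shape[1]
        self.network_ = self._build(X.shape[1], rng)
        optimizer = Nadam(
            self.network_.params(),
            learning_rate=self.learning_rate,
            lr_decay=self.lr_decay,
            momentum=self.momentum,
        )

        Xt = self._shape_input(X)
        Xv = self._shape_input(X_val)
        Y = np.eye(2)[y]
        Yv = np.eye(2)[y_val]

        n = X.shape[0]
        best_val = np.inf
        best_weights = self.network_.get_weights()
        best_epoch = 0
        history: list[dict] = []

        for epoch in range(1, self.max_epochs + 1):
            optimizer.epoch = epoch - 1
            order = rng.permutation(n)
            batch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self.network_.forward(Xt[idx], train=True)
                p = softmax(logits)
                loss, dlogits = mse_loss_and_grad(p, Y[idx])
                self.network_.backward(dlogits)
                optimizer.step(self.network_.grads())
                batch_losses.append(loss)
            val_p = softmax(self.network_.forward(Xv, train=False))
            val_loss = float(np.mean((val_p - Yv) ** 2))
            history.append(
                {"epoch": epoch, "train_loss": float(np.mean(batch_losses)), "val_loss": val_loss}
            )
            if val_loss < best_val:
                best_val = val_loss
                best_weights = self.network_.get_weights()
                best_epoch = epoch
            elif (
                epoch - best_epoch >= self.early_stop_patience
                and val_loss > best_val + max(1e-4, 0.01 * best_val)
            ):
                # stop only on a genuine increasing trend: a flat plateau
                # (common early under MSE + softmax) does not terminate
                break

        self.network_.set_weights(best_weights)
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.classes_ = np.array([0, 1])
        return self

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects {self.n_features_in_}"
            )
        X = X / self.input_scale_
        return softmax(self.network_.forward(self._shape_input(X), train=False))

    def predict_score(self, X) -> np.ndarray:
        """Positive-class probability per row (in [0, 1])."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_score(X) >= threshold).astype(int)


class DeepLSTMClassifier(_BaseNetClassifier):
    """Stacked-LSTM binary classifier (the method's primary model)."""

    arch = "lstm"

    def _shape_input(self, X: np.ndarray) -> np.ndarray:
        n, d = X.shape
        T = self.time_steps
        if d % T != 0:
            raise ValueError(f"input_dim {d} not divisible by time_steps {T}")
        return X.reshape(n, T, d // T)

    def _build(self, input_dim: int, rng: np.random.Generator) -> Network:
        layers: list = []
        d = input_dim // self.time_steps
        for _ in range(self.n_hidden_layers):
            layers.append(LSTMLayer(d, self.units_per_layer, rng))
            layers.append(Dropout(self.dropout_rate, rng))
            d = self.units_per_layer
        layers.append(LastStep())
        layers.append(DenseLayer(d, 2, rng))
        return Network(layers)


class MLPBaselineClassifier(_BaseNetClassifier):
    """Feed-forward baseline matching the LSTM's depth, width and training."""

    arch = "mlp"

    def _shape_input(self, X: np.ndarray) -> np.ndarray:
        return X

    def _build(self, input_dim: int, rng: np.random.Generator) -> Network:
        # Glorot init (init_sd=None): the fixed-sd Gaussian init of the LSTM
        # collapses activations over four 36-unit tanh layers (per-layer
        # forward gain 0.1 * sqrt(36) = 0.6)
        layers: list = []
        d = input_dim
        for _ in range(self.n_hidden_layers):
            layers.append(DenseLayer(d, self.units_per_layer, rng,
                                     activation="tanh", init_sd=None))
            layers.append(Dropout(self.dropout_rate, rng))
            d = self.units_per_layer
        layers.append(DenseLayer(d, 2, rng, init_sd=None))
        return Network(layers)


class GridSearchSVM:
    """RBF support-vector baseline with cross-validated grid search.

    (C, gamma) are chosen by k-fold cross-validated accuracy on the training
    data; scores are the decision function mapped through a logistic link.
    """

    def __init__(self, c_grid=(0.1, 1.0, 10.0), gamma_grid=("scale", 0.01, 0.1),
                 k_folds: int = 5, random_state: int = 0):
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.k_folds = k_folds
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "c_grid": self.c_grid,
            "gamma_grid": self.gamma_grid,
            "k_folds": self.k_folds,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = _check_labels(y)
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        cv = StratifiedKFold(n_splits=self.k_folds, shuffle=True, random_state=self.random_state)
        search = GridSearchCV(
            SVC(kernel="rbf"),
            {"C": list(self.c_grid), "gamma": list(self.gamma_grid)},
            scoring="accuracy",
            cv=cv,
        )
        search.fit(X, y)
        self.best_params_ = search.best_params_
        self.estimator_ = search.best_estimator_
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def predict_score(self, X) -> np.ndarray:
        d = self.estimator_.decision_function(np.asarray(X, dtype=float))
        return 1.0 / (1.0 + np.exp(-d))

    def predict_proba(self, X) -> np.ndarray:
        s = self.predict_score(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_score(X) >= threshold).astype(int)


# -- functional wrappers mirroring the operation surface -------------------

def _estimator_from_config(cls, config: LSTMConfig):
    return cls(
        n_hidden_layers=config.n_hidden_layers,
        units_per_layer=config.units_per_layer,
        dropout_rate=config.dropout_rate,
        time_steps=config.time_steps,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        learning_rate=config.learning_rate,
        lr_decay=config.lr_decay,
        momentum=config.momentum,
        early_stop_patience=config.early_stop_patience,
        random_state=config.seed,
    )


def build_deep_lstm(config: LSTMConfig = LSTMConfig()) -> DeepLSTMClassifier:
    return _estimator_from_config(DeepLSTMClassifier, config)


def build_mlp_baseline(config: LSTMConfig = LSTMConfig()) -> MLPBaselineClassifier:
    return _estimator_from_config(MLPBaselineClassifier, config)


def train_model(model, X_train, y_train, X_val, y_val, config: LSTMConfig | None = None):
    """Fit a built model on an explicit train/validation split."""
    if config is not None:
        model.set_params(**_estimator_from_config(type(model), config).get_params())
    return model.fit(X_train, y_train, X_val=X_val, y_val=y_val)


def train_svm_baseline(X, y, c_grid=(0.1, 1.0, 10.0), gamma_grid=("scale", 0.01, 0.1),
                       k_folds: int = 5, seed: int = 0) -> GridSearchSVM:
    return GridSearchSVM(c_grid, gamma_grid, k_folds, seed).fit(X, y)


def predict(model, X) -> np.ndarray:
    """Positive-class interaction probability per row."""
    return model.predict_score(X)


# -- checkpointing ---------------------------------------------------------

def save_network_model(model: _BaseNetClassifier, path) -> None:
    """Persist a fitted network classifier to a single NPZ archive."""
    arrays = {f"w{i}": w for i, w in enumerate(model.network_.get_weights())}
    params = {
        k: ("none" if v is None else v)
        for k, v in model.get_params().items()
        if not isinstance(v, (tuple, list))
    }
    np.savez(
        Path(path),
        arch=model.arch,
        n_features_in=model.n_features_in_,
        input_scale=model.input_scale_,
        best_epoch=model.best_epoch_,
        history_epochs=np.array([h["epoch"] for h in model.history_]),
        history_train=np.array([h["train_loss"] for h in model.history_]),
        history_val=np.array([h["val_loss"] for h in model.history_]),
        **params,
        **arrays,
    )


def load_network_model(path) -> _BaseNetClassifier:
    with np.load(Path(path)) as data:
        arch = str(data["arch"])
        cls = DeepLSTMClassifier if arch == "lstm" else MLPBaselineClassifier
        params = {k: data[k].item() for k in cls._param_names if k in data}
        model = cls(**params)
        model.n_features_in_ = int(data["n_features_in"])
        model.input_scale_ = float(data["input_scale"])
        rng = np.random.default_rng(model.random_state)
        model.network_ = model._build(model.n_features_in_, rng)
        weights = [data[f"w{i}"] for i in range(len(model.network_.params()))]
        model.network_.set_weights(weights)
        model.best_epoch_ = int(data["best_epoch"])
        model.history_ = [
            {"epoch": int(e), "train_loss": float(t), "val_loss": float(v)}
            for e, t, v in zip(data["history_epochs"], data["history_train"], data["history_val"])
        ]
        model.classes_ = np.array([0, 1])
    return model


def history_to_tsv(model: _BaseNetClassifier, path=None) -> str:
    lines = ["epoch\ttrain_loss\tval_loss"]
    for h in model.history_:
        lines.append(f"{h['epoch']}\t{h['train_loss']:.8g}\t{h['val_loss']:.8g}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
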