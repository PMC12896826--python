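"""Training, fine-tuning and the scikit-learn estimator for S-ResNet."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .model import ModelSpec, SResNet, build_sresnet, count_macs
from .nn import Adam, softmax, softmax_cross_entropy


@dataclass(frozen=True)
class TrainConfig:
    """Classifier training hyperparameters (Adam + cross-entropy)."""

    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 128
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    seed: int | None = None

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "cross_entropy":
            raise ValueError("only cross-entropy loss is supported")
        if self.learning_rate < 0 or self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


def run_training(
    net: SResNet,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Run the Adam/cross-entropy loop in place; returns the epoch log."""
    X = np.asarray(X, dtype=net.dtype)
    y = np.asarray(y, dtype=int)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    log: list[dict] = []
    net.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        losses, correct = [], 0
        for i in range(0, len(X), cfg.batch_size):
            idx = order[i: i + cfg.batch_size]
            logits = net(X[idx])
            loss = softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss {float(loss.data)} at epoch {epoch}, "
                    f"batch {i // cfg.batch_size}; lower the learning rate"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
        log.append(
            {"epoch": epoch, "loss": float(np.mean(losses)),
             "accuracy": correct / len(X)}
        )
    net.eval()
    return log


class SResNetClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn estimator around the S-ResNet network.

    Parameters mirror the reference training setup: Adam, cross-entropy,
    learning rate 0.001, 100 epochs, batch size 128.  ``widths`` overrides
    individual channel widths of the default 32/(64,64)/(128,128)/64
    architecture (keys: conv1, block1_mid, block1_out, block2_mid,
    block2_out, fc1).
    """

    def __init__(
        self,
        learning_rate: float = 0.001,
        epochs: int = 100,
        batch_size: int = 128,
        widths: dict | None = None,
        input_length: int = 10,
        head_relu: bool = False,
        dtype: str = "float32",
        random_state: int | None = None,
    ):
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.widths = widths
        self.input_length = input_length
        self.head_relu = head_relu
        self.dtype = dtype
        self.random_state = random_state

    # -- estimator API -------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != self.input_length:
            raise ValueError(f"X must have shape (n, {self.input_length})")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        spec = build_sresnet(
            **(self.widths or {}),
            input_length=self.input_length,
            num_classes=len(self.classes_),
        )
        rng = np.random.default_rng(self.random_state)
        self.network_ = SResNet(spec, rng, head_relu=self.head_relu,
                                dtype=np.dtype(self.dtype))
        self.spec_ = spec
        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.random_state,
        )
        self.history_ = run_training(self.network_, X, y_idx, cfg, rng)
        self.n_features_in_ = X.shape[1]
        return self

    def finetune(
        self,
        X,
        y,
        epochs: int | None = None,
        learning_rate: float | None = None,
        seed: int | None = None,
    ):
        """Continue training from the current weights (same loop as fit)."""
        check_is_fitted(self, "network_")
        y_idx = np.searchsorted(self.classes_, np.asarray(y))
        cfg = TrainConfig(
            learning_rate=self.learning_rate if learning_rate is None else learning_rate,
            epochs=self.epochs if epochs is None else epochs,
            batch_size=self.batch_size,
        )
        rng = np.random.default_rng(self.random_state if seed is None else seed)
        self.history_ = self.history_ + run_training(
            self.network_, np.asarray(X, float), y_idx, cfg, rng
        )
        return self

    def decision_function(self, X):
        check_is_fitted(self, "network_")
        return self.network_.predict_logits(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return softmax(self.decision_function(X))

    def predict(self, X):
        return self.classes_[self.decision_function(X).argmax(axis=1)]

    # -- convenience ---------------------------------------------------
    def mac_report(self):
        check_is_fitted(self, "spec_")
        return count_macs(self.spec_)

    def copy_with_network(self, network: SResNet) -> "SResNetClassifier":
        """Clone the estimator shell around a (possibly pruned) network."""
        clone = SResNetClassifier(**self.get_params())
        clone.classes_ = self.classes_.copy()
        clone.network_ = network
        clone.spec_ = network.spec
        clone.history_ = list(getattr(self, "history_", []))
        clone.n_features_in_ = self.n_features_in_
        return clone

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "spec.json").write_text(self.spec_.to_json())
        np.savez(d / "weights.npz", classes=self.classes_,
                 **self.network_.state_dict())

    @classmethod
    def load(cls, directory, **params) -> "SResNetClassifier":
        from pathlib import Path

        d = Path(directory)
        spec = ModelSpec.from_json((d / "spec.json").read_text())
        state = dict(np.load(d / "weights.npz"))
        classes = state.pop("classes")
        clf = cls(**params)
        clf.classes_ = classes
        clf.spec_ = spec
        clf.network_ = SResNet(spec, np.random.default_rng(0),
                               head_relu=clf.head_relu, dtype=np.dtype(clf.dtype))
        clf.network_.load_state_dict(state)
        clf.network_.eval()
        clf.history_ = []
        clf.n_features_in_ = spec.input_length
        return clf


def train_classifier(
    train_X, train_y, cfg: TrainConfig = TrainConfig(),
    widths: dict | None = None, input_length: int = 10,
) -> SResNetClassifier:
    """Functional wrapper over :class:`SResNetClassifier`."""
    clf = SResNetClassifier(
        learning_rate=cfg.learning_rate, epochs=cfg.epochs,
        batch_size=cfg.batch_size, widths=widths,
        input_length=input_length, random_state=cfg.seed,
    )
    return clf.fit(train_X, train_y)
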