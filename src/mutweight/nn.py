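"""A small feed-forward neural network for multiclass classification.

Architecture: ``n_layers`` fully connected hidden layers whose widths halve
layer to layer (first layer ``U``, then ``U/2``, ``U/4``, ...), each
followed by dropout, and a softmax output head with one unit per class.
Trained by minimising categorical cross-entropy with mini-batch Adam or
SGD.  Dropout is inverted (activations rescaled at train time) and is a
no-op at inference, so prediction is deterministic given the fitted
weights.

The estimator follows the familiar ``fit`` / ``predict`` /
``predict_proba`` surface so it can drop into the evaluation harness next
to the scikit-learn models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["NNSpec", "FeedForwardNN", "build_nn"]


@dataclass(frozen=True)
class NNSpec:
    """Hyperparameters of the feed-forward network.

    ``n_layers`` counts hidden layers; the softmax head is implied.
    Widths follow the halving rule from ``first_layer_units``.  Epochs and
    batch size default to 50, matching the fixed training schedule used
    throughout the classification experiments (no early stopping).
    """

    n_layers: int = 2
    first_layer_units: int = 128
    dropout: float = 0.25
    activation: str = "relu"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 50
    n_classes: int | None = None

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("need at least one hidden layer")
        if not 0 <= self.dropout < 1:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unsupported activation {self.activation!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")

    def hidden_widths(self) -> list[int]:
        """[U, U/2, U/4, ...] — halving, rounding down (with a warning)."""
        widths = []
        u = self.first_layer_units
        for i in range(self.n_layers):
            if u < 1:
                raise ValueError(
                    f"first_layer_units={self.first_layer_units} cannot be halved "
                    f"{self.n_layers - 1} times"
                )
            widths.append(int(u))
            if i < self.n_layers - 1 and u % 2:
                warnings.warn(
                    f"layer width {u} is odd; rounding the next layer down to {u // 2}",
                    stacklevel=2,
                )
            u //= 2
        return widths


def build_nn(spec: NNSpec, seed: int = 0) -> "FeedForwardNN":
    """Instantiate an untrained network from a spec."""
    return FeedForwardNN(
        n_layers=spec.n_layers,
        first_layer_units=spec.first_layer_units,
        dropout=spec.dropout,
        activation=spec.activation,
        optimizer=spec.optimizer,
        learning_rate=spec.learning_rate,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        random_state=seed,
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class FeedForwardNN:
    """Halving-width MLP with dropout and a softmax head.

    Parameters mirror :class:`NNSpec`; ``random_state`` seeds weight
    initialisation, batch shuffling and dropout masks, making training a
    deterministic function of (data, hyperparameters, seed).
    """

    def __init__(
        self,
        n_layers: int = 2,
        first_layer_units: int = 128,
        dropout: float = 0.25,
        activation: str = "relu",
        optimizer: str = "adam",
        learning_rate: float = 1e-3,
        epochs: int = 50,
        batch_size: int = 50,
        random_state: int = 0,
    ):
        self.spec = NNSpec(
            n_layers=n_layers,
            first_layer_units=first_layer_units,
            dropout=dropout,
            activation=activation,
            optimizer=optimizer,
            learning_rate=learning_rate,
            epochs=epochs,
            batch_size=batch_size,
        )
        self.random_state = random_state
        self.classes_: np.ndarray | None = None
        self._W: list[np.ndarray] = []
        self._b: list[np.ndarray] = []

    # -- forward/backward ------------------------------------------------

    def _act(self, z: np.ndarray) -> np.ndarray:
        return np.maximum(z, 0.0) if self.spec.activation == "relu" else np.tanh(z)

    def _act_grad(self, a: np.ndarray) -> np.ndarray:
        return (a > 0).astype(a.dtype) if self.spec.activation == "relu" else 1.0 - a * a

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None):
        """Returns (softmax probabilities, cached activations, dropout masks)."""
        acts = [X]
        masks = []
        a = X
        p_drop = self.spec.dropout
        for W, b in zip(self._W[:-1], self._b[:-1]):
            a = self._act(a @ W + b)
            if rng is not None and p_drop > 0:
                mask = (rng.random(a.shape) >= p_drop) / (1.0 - p_drop)
                a = a * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(a)
        probs = _softmax(a @ self._W[-1] + self._b[-1])
        return probs, acts, masks

    # -- API -------------------------------------------------------------

    def fit(self, X: np.ndarray, y) -> "FeedForwardNN":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        n_classes = self.classes_.size
        Y = np.zeros((n, n_classes))
        Y[np.arange(n), y_idx] = 1.0

        rng = np.random.default_rng(self.random_state)
        widths = [d] + self.spec.hidden_widths() + [n_classes]
        gain = np.sqrt(2.0) if self.spec.activation == "relu" else 1.0
        self._W = [
            rng.normal(0.0, gain / np.sqrt(widths[i]), size=(widths[i], widths[i + 1]))
            for i in range(len(widths) - 1)
        ]
        self._b = [np.zeros(w) for w in widths[1:]]

        lr = self.spec.learning_rate
        adam = self.spec.optimizer == "adam"
        if adam:
            mW = [np.zeros_like(W) for W in self._W]
            vW = [np.zeros_like(W) for W in self._W]
            mB = [np.zeros_like(b) for b in self._b]
            vB = [np.zeros_like(b) for b in self._b]
            beta1, beta2, eps = 0.9, 0.999, 1e-8
            t = 0

        batch = max(1, min(self.spec.batch_size, n))
        for _ in range(self.spec.epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                Xb, Yb = X[idx], Y[idx]
                probs, acts, masks = self._forward(Xb, rng)
                delta = (probs - Yb) / len(idx)  # dCE/dlogits
                grads_W, grads_b = [], []
                for li in range(len(self._W) - 1, -1, -1):
                    grads_W.append(acts[li].T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if li > 0:
                        delta = delta @ self._W[li].T
                        if masks[li - 1] is not None:
                            delta = delta * masks[li - 1]
                        delta = delta * self._act_grad(acts[li])
                grads_W.reverse()
                grads_b.reverse()
                if adam:
                    t += 1
                    corr1 = 1.0 - beta1**t
                    corr2 = 1.0 - beta2**t
                    for li in range(len(self._W)):
                        mW[li] = beta1 * mW[li] + (1 - beta1) * grads_W[li]
                        vW[li] = beta2 * vW[li] + (1 - beta2) * grads_W[li] ** 2
                        self._W[li] -= lr * (mW[li] / corr1) / (np.sqrt(vW[li] / corr2) + eps)
                        mB[li] = beta1 * mB[li] + (1 - beta1) * grads_b[li]
                        vB[li] = beta2 * vB[li] + (1 - beta2) * grads_b[li] ** 2
                        self._b[li] -= lr * (mB[li] / corr1) / (np.sqrt(vB[li] / corr2) + eps)
                else:
                    for li in range(len(self._W)):
                        self._W[li] -= lr * grads_W[li]
                        self._b[li] -= lr * grads_b[li]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.classes_ is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=np.float64)
        probs, _, _ = self._forward(X, rng=None)  # dropout off at inference
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def get_params(self, deep: bool = True) -> dict:
        p = {k: getattr(self.spec, k) for k in (
            "n_layers", "first_layer_units", "dropout", "activation",
            "optimizer", "learning_rate", "epochs", "batch_size",
        )}
        p["random_state"] = self.random_state
        return p
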