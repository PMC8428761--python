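"""Two-layer dropout MLP for binary spectrum classification.

Architecture (fixed):

    input -> dropout(p) -> dense(n_in -> n_hidden) -> relu
          -> dropout(p) -> dense(n_hidden -> 2) -> softmax

The hidden width follows the sizing rule n_hidden = nint(n_in / 10) —
nearest integer, ties away from zero — intended for input lengths between
201 and 806 features. Dense weights are Glorot-uniform initialized, biases
start at zero; an L2 penalty applies to weights only, never biases.
Training minimizes softmax cross-entropy plus the weight penalty for a
fixed number of epochs with full-batch Adam (cohorts here are at most a
few hundred rows, so full batch is both robust and exactly reproducible).
Dropout uses inverted scaling (activations divided by 1-p during training)
so inference is a plain forward pass. A single seeded RNG stream drives
initialization and every dropout mask, making training bit-reproducible.

Class order is fixed as (group1_osteo, group2_healthy); a softmax tie
(p = 0.5) resolves to group 1, the screening-conservative choice.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .cohort import GROUP1, GROUP2

__all__ = ["ClassifierConfig", "MLPClassifier", "hidden_width", "CLASS_ORDER"]

CLASS_ORDER = (GROUP1, GROUP2)

_SIZING_DOMAIN = (201, 806)


def hidden_width(n_in: int) -> int:
    """Hidden-layer width: nearest integer to n_in / 10, ties away from zero.

    The rule is stated for 201 <= n_in <= 806; outside that domain it still
    evaluates but emits a warning.
    """
    if n_in < 1:
        raise ValueError(f"n_in must be >= 1, got {n_in}")
    if not (_SIZING_DOMAIN[0] <= n_in <= _SIZING_DOMAIN[1]):
        warnings.warn(
            f"hidden_width called with n_in={n_in}, outside the stated domain "
            f"{_SIZING_DOMAIN[0]}..{_SIZING_DOMAIN[1]}",
            stacklevel=2,
        )
    return int(np.floor(n_in / 10 + 0.5))


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the dropout MLP.

    ``n_hidden=None`` derives the width from the sizing rule. The optimizer
    settings (Adam, learning rate 1e-3, full batch) and the L2 coefficient
    are package defaults, all overridable.
    """

    n_in: int
    n_hidden: int | None = None
    dropout_rate: float = 0.5
    epochs: int = 1000
    l2_weights: float = 1e-4
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_in < 1:
            raise ValueError("n_in must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.l2_weights < 0:
            raise ValueError("l2_weights must be >= 0")

    def resolved_hidden(self) -> int:
        width = self.n_hidden if self.n_hidden is not None else hidden_width(self.n_in)
        if width < 1:
            raise ValueError(
                f"sizing rule gives hidden width {width} for n_in={self.n_in}; "
                "the network needs at least one hidden unit"
            )
        return width


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _loss_and_grads(params: dict[str, np.ndarray], X: np.ndarray, Y: np.ndarray,
                    mask_in: np.ndarray, mask_h: np.ndarray, l2: float):
    """Softmax cross-entropy + L2(weights) and its analytic gradients.

    ``mask_in``/``mask_h`` are the (already 1/(1-p)-scaled) dropout masks;
    pass all-ones arrays for inference-style evaluation. Exposed at module
    level so a finite-difference check can probe it directly.
    """
    W1, b1, W2, b2 = params["W1"], params["b1"], params["W2"], params["b2"]
    n = X.shape[0]
    Xd = X * mask_in
    A1 = Xd @ W1 + b1
    R = np.maximum(A1, 0.0)
    Rd = R * mask_h
    Z = Rd @ W2 + b2
    P = _softmax(Z)
    ce = -np.sum(Y * np.log(np.clip(P, 1e-300, None))) / n
    loss = ce + l2 * (np.sum(W1 * W1) + np.sum(W2 * W2))

    dZ = (P - Y) / n
    gW2 = Rd.T @ dZ + 2.0 * l2 * W2
    gb2 = dZ.sum(axis=0)
    dRd = dZ @ W2.T
    dA1 = dRd * mask_h * (A1 > 0)
    gW1 = Xd.T @ dA1 + 2.0 * l2 * W1
    gb1 = dA1.sum(axis=0)
    return loss, {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}


class MLPClassifier:
    """The trained/untrained two-layer dropout network."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        self.n_hidden = config.resolved_hidden()
        self._rng = np.random.default_rng(config.seed)
        self.params = self._glorot_init()
        self.fitted = False

    def _glorot_init(self) -> dict[str, np.ndarray]:
        n_in, n_h = self.config.n_in, self.n_hidden
        lim1 = np.sqrt(6.0 / (n_in + n_h))
        lim2 = np.sqrt(6.0 / (n_h + 2))
        return {
            "W1": self._rng.uniform(-lim1, lim1, size=(n_in, n_h)),
            "b1": np.zeros(n_h),
            "W2": self._rng.uniform(-lim2, lim2, size=(n_h, 2)),
            "b2": np.zeros(2),
        }

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y) -> "MLPClassifier":
        """Train for ``config.epochs`` full-batch Adam steps.

        ``y`` holds class labels (group strings from :mod:`wristrf.cohort`).
        Both classes must be present; non-finite features are rejected.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.n_in:
            raise ValueError(f"X must be (n, {self.config.n_in}), got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("training features contain NaN/Inf")
        y = np.asarray(y)
        Y = np.zeros((X.shape[0], 2))
        for j, cls in enumerate(CLASS_ORDER):
            Y[y == cls, j] = 1.0
        if not np.all(Y.sum(axis=1) == 1.0):
            bad = sorted(set(y) - set(CLASS_ORDER))
            raise ValueError(f"labels outside {CLASS_ORDER}: {bad}")
        if np.any(Y.sum(axis=0) == 0):
            raise ValueError("both classes must be present in the training labels")

        p = self.config.dropout_rate
        keep = 1.0 - p
        lr = self.config.learning_rate
        l2 = self.config.l2_weights
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in self.params.items()}
        n = X.shape[0]

        for t in range(1, self.config.epochs + 1):
            if p > 0:
                mask_in = (self._rng.random((n, self.config.n_in)) >= p) / keep
                mask_h = (self._rng.random((n, self.n_hidden)) >= p) / keep
            else:
                mask_in = np.ones((n, self.config.n_in))
                mask_h = np.ones((n, self.n_hidden))
            _, grads = _loss_and_grads(self.params, X, Y, mask_in, mask_h, l2)
            for k in self.params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                m_hat = m[k] / (1 - beta1**t)
                v_hat = v[k] / (1 - beta2**t)
                self.params[k] = self.params[k] - lr * m_hat / (np.sqrt(v_hat) + eps)
        self.fitted = True
        return self

    # -- inference ----------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities, dropout disabled; rows sum to 1."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.config.n_in:
            raise ValueError(
                f"feature length {X.shape[1]} does not match n_in={self.config.n_in}"
            )
        H = np.maximum(X @ self.params["W1"] + self.params["b1"], 0.0)
        return _softmax(H @ self.params["W2"] + self.params["b2"])

    def predict(self, x: np.ndarray) -> tuple[str, np.ndarray]:
        """Predicted label and the (p_group1, p_group2) pair for one vector.

        An exact tie goes to group 1 (flagging the possibly diseased
        subject is the conservative screening outcome).
        """
        probs = self.predict_proba(np.atleast_2d(x))[0]
        label = CLASS_ORDER[0] if probs[0] >= probs[1] else CLASS_ORDER[1]
        return label, probs

    def predict_labels(self, X: np.ndarray) -> list[str]:
        probs = self.predict_proba(X)
        return [CLASS_ORDER[0] if p[0] >= p[1] else CLASS_ORDER[1] for p in probs]

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Save config and learned parameters as a JSON bundle."""
        bundle = {
            "config": {
                "n_in": self.config.n_in,
                "n_hidden": self.config.n_hidden,
                "dropout_rate": self.config.dropout_rate,
                "epochs": self.config.epochs,
                "l2_weights": self.config.l2_weights,
                "learning_rate": self.config.learning_rate,
                "seed": self.config.seed,
            },
            "fitted": self.fitted,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(bundle))

    @classmethod
    def load(cls, path) -> "MLPClassifier":
        bundle = json.loads(Path(path).read_text())
        model = cls(ClassifierConfig(**bundle["config"]))
        model.params = {k: np.asarray(v, dtype=float) for k, v in bundle["params"].items()}
        model.fitted = bool(bundle["fitted"])
        return model
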