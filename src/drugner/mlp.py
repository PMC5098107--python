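"""Window classifier: a feed-forward net trained on the printed objective.

The cost is mean sum-of-squares on one-hot targets with an optional
weight-decay term,

    J(W, b) = (1/m) sum_i 1/2 ||h(x_i) - y_i||^2  +  (lambda/2) sum W^2,

with sigmoid hidden layers and a softmax output — the monitored loss is
kept as sum-of-squares despite the softmax, because that is the objective
the regularization study is defined on.  Bias terms are excluded from the
decay sum.  Three decay settings are used in the experiments: L0
(lambda = 0), L1 (lambda = 1) and L2 (lambda = the distance-derived
coefficient from :func:`drugner.embed.lambda_avg_distance` over the word
vectors).

Training is plain minibatch gradient descent with momentum, seeded and
single-threaded, so runs are bit-reproducible.  Two numerical choices
matter on imbalanced window data and are deliberate: the output-layer
error signal is the conventional softmax backprop ``h - y`` (pushing the
exact sum-of-squares error through the softmax Jacobian multiplies the
signal by output probabilities twice and provably stalls at the majority
-class prior here — the classic squared-error-on-softmax plateau), and
hidden sigmoid layers use the 4x Glorot uniform init recommended for
logistic activations (the plain factor leaves mid-layer activations
nearly constant and gradients vanishing).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .embed import WordVectorTable, lambda_avg_distance


def regularization_lambda(
    kind: str, table: WordVectorTable | None = None, seed: int = 0
) -> float:
    """Map a decay setting name (l0/l1/l2) to its coefficient."""
    kind = kind.lower()
    if kind == "l0":
        return 0.0
    if kind == "l1":
        return 1.0
    if kind == "l2":
        if table is None:
            raise ValueError("l2 needs a word-vector table")
        X = np.vstack([table.vectors[t] for t in sorted(table.vectors)])
        return lambda_avg_distance(X, seed=seed)
    raise ValueError(f"unknown regularization {kind!r}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


class WindowMLPClassifier(ClassifierMixin, BaseEstimator):
    """Multilayer perceptron over encoded 5-token windows.

    Parameters (defaults are the experiment settings: two hidden layers of
    100 sigmoid units, softmax output, learning rate 1, momentum 0.5, 100
    epochs, minibatches of 100):

    alpha : weight-decay coefficient lambda (see module docstring)
    seed : controls init and minibatch shuffling; fit is deterministic

    Fitted attributes: ``classes_``, ``coefs_``, ``intercepts_``,
    ``loss_curve_`` (full-batch mean error per epoch, length = epochs).
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (100, 100),
        learning_rate: float = 1.0,
        momentum: float = 0.5,
        epochs: int = 100,
        batch_size: int = 100,
        alpha: float = 0.0,
        shuffle: bool = True,
        seed: int = 0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = epochs
        self.batch_size = batch_size
        self.alpha = alpha
        self.shuffle = shuffle
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [X]
        a = X
        for l, (W, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            z = a @ W + b
            a = _softmax(z) if l == len(self.coefs_) - 1 else _sigmoid(z)
            acts.append(a)
        return acts

    def fit(self, X: np.ndarray, y: np.ndarray) -> "WindowMLPClassifier":
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        self.classes_ = np.unique(y)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        Y = np.zeros((X.shape[0], len(self.classes_)))
        Y[np.arange(X.shape[0]), [class_index[c] for c in y]] = 1.0

        rng = np.random.default_rng(self.seed)
        sizes = [X.shape[1], *self.hidden_layer_sizes, len(self.classes_)]
        self.coefs_ = []
        self.intercepts_ = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # 4x Glorot: the sigmoid-activation variant
            r = 4.0 * np.sqrt(6.0 / (fan_in + fan_out))
            self.coefs_.append(rng.uniform(-r, r, size=(fan_in, fan_out)))
            self.intercepts_.append(np.zeros(fan_out))
        vel_W = [np.zeros_like(W) for W in self.coefs_]
        vel_b = [np.zeros_like(b) for b in self.intercepts_]

        n = X.shape[0]
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            batch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                acts = self._forward(X[idx])
                h = acts[-1]
                e = h - Y[idx]
                batch_losses.append(0.5 * float((e**2).sum()) / len(idx))
                # conventional softmax backprop (see module docstring)
                delta = e
                for l in range(len(self.coefs_) - 1, -1, -1):
                    gW = acts[l].T @ delta / len(idx) + self.alpha * self.coefs_[l]
                    gb = delta.mean(axis=0)
                    if l > 0:
                        a = acts[l]
                        delta = (delta @ self.coefs_[l].T) * a * (1.0 - a)
                    vel_W[l] = self.momentum * vel_W[l] - self.learning_rate * gW
                    vel_b[l] = self.momentum * vel_b[l] - self.learning_rate * gb
                    self.coefs_[l] += vel_W[l]
                    self.intercepts_[l] += vel_b[l]
            self.loss_curve_.append(float(np.mean(batch_losses)))
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self._forward(X)[-1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def confidence(self, X: np.ndarray) -> np.ndarray:
        """Max softmax probability per window (entity-conflict resolution)."""
        return self.predict_proba(X).max(axis=1)

    def weight_norm(self) -> float:
        """sqrt(sum W^2) over all non-bias weights (decay diagnostics)."""
        check_is_fitted(self, "coefs_")
        return float(np.sqrt(sum(float((W**2).sum()) for W in self.coefs_)))

    def total_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        """The full objective J(W, b) including the decay term."""
        check_is_fitted(self, "coefs_")
        class_index = {c: i for i, c in enumerate(self.classes_)}
        Y = np.zeros((X.shape[0], len(self.classes_)))
        Y[np.arange(X.shape[0]), [class_index[c] for c in y]] = 1.0
        h = self.predict_proba(X)
        data = 0.5 * float(((h - Y) ** 2).sum()) / X.shape[0]
        decay = 0.5 * self.alpha * sum(float((W**2).sum()) for W in self.coefs_)
        return data + decay
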