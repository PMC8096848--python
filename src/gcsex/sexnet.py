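"""Densely connected feed-forward sex classifier.

The network predicts P(male) from a standardized expression profile. It is
DenseNet-style in the feed-forward sense: every hidden layer receives the
concatenation of the raw input and all earlier hidden-layer outputs, and
the sigmoid output unit sees the full concatenation. The implementation is
pure numpy with hand-written backpropagation: besides parameter gradients
it exposes the analytic gradient of the output with respect to the input,
which is the primitive integrated-gradient attribution needs.

Training runs a fixed number of epochs of minibatch Adam on binary
cross-entropy, records a per-epoch validation metric, and restores the
parameters of the best epoch (ties broken toward the earliest), so the
returned model is the best of the per-epoch snapshots rather than the last.

Sex encoding everywhere: female = 0, male = 1. Attribution signs inherit
this convention (positive attribution pushes the prediction toward male).
"""
from __future__ import annotations

import copy

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
}


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class DenseSexClassifier(ClassifierMixin, BaseEstimator):
    """11-layer densely connected sex classifier (sklearn estimator).

    Parameters
    ----------
    total_layers : number of weight layers including the output unit;
        the default 11 gives 10 hidden layers.
    hidden_width : units per hidden layer.
    activation : "relu" (default) or "tanh".
    epochs : training epochs; one validation-metric entry is recorded per
        epoch and the best epoch's parameters are restored after training.
    metric : "accuracy" (default) or "auc", the best-model criterion.
    random_state : seeds initialization and minibatch shuffling.

    Attributes (after fit)
    ----------------------
    validation_trace_ : list of per-epoch validation metrics, length epochs.
    best_epoch_ : index of the restored epoch (argmax, earliest tie).
    n_features_in_ : input dimension.
    """

    def __init__(
        self,
        total_layers: int = 11,
        hidden_width: int = 64,
        activation: str = "relu",
        epochs: int = 200,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        metric: str = "accuracy",
        random_state: int | None = 0,
    ):
        self.total_layers = total_layers
        self.hidden_width = hidden_width
        self.activation = activation
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.metric = metric
        self.random_state = random_state

    # ---- construction ----

    def _validate_config(self) -> None:
        if self.total_layers < 2:
            raise ValueError("total_layers must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.metric not in ("accuracy", "auc"):
            raise ValueError(f"unknown metric {self.metric!r}")

    def initialize(self, n_features: int) -> "DenseSexClassifier":
        """Allocate parameters for ``n_features`` inputs (deterministic per
        random_state); called by fit, or directly for an untrained model."""
        self._validate_config()
        if n_features < 1:
            raise ValueError("n_features must be >= 1")
        rng = np.random.default_rng(self.random_state)
        H = self.total_layers - 1
        w = self.hidden_width
        gain = np.sqrt(2.0) if self.activation == "relu" else 1.0
        self.W_, self.b_ = [], []
        fan_in = n_features
        for _ in range(H):
            self.W_.append(rng.normal(0.0, gain / np.sqrt(fan_in), size=(fan_in, w)))
            self.b_.append(np.zeros(w))
            fan_in += w
        self.W_out_ = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, 1))
        self.b_out_ = np.zeros(1)
        self.n_features_in_ = n_features
        self.classes_ = np.array([0, 1])
        return self

    @property
    def n_parameters_(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.W_, self.b_)) + self.W_out_.size + 1

    # ---- forward / backward ----

    def _forward(self, X: np.ndarray):
        act, _ = _ACTIVATIONS[self.activation]
        segs = [X]          # input + each hidden output
        zs = []
        for W, b in zip(self.W_, self.b_):
            c = np.concatenate(segs, axis=1)
            z = c @ W + b
            zs.append(z)
            segs.append(act(z))
        c_out = np.concatenate(segs, axis=1)
        logit = (c_out @ self.W_out_ + self.b_out_).ravel()
        return logit, segs, zs

    def _backward(self, segs, zs, delta_logit):
        """Backprop a per-sample gradient at the logit; returns
        (param grads, input gradient)."""
        _, dact = _ACTIVATIONS[self.activation]
        H = len(self.W_)
        w = self.hidden_width
        d = segs[0].shape[1]
        delta_logit = delta_logit.reshape(-1, 1)
        c_out = np.concatenate(segs, axis=1)
        gW_out = c_out.T @ delta_logit
        gb_out = delta_logit.sum(axis=0)
        back = delta_logit @ self.W_out_.T        # grad wrt c_out
        g_x = back[:, :d].copy()
        g_h = [back[:, d + k * w: d + (k + 1) * w].copy() for k in range(H)]
        gW = [None] * H
        gb = [None] * H
        for k in range(H - 1, -1, -1):
            delta = g_h[k] * dact(zs[k])
            c_k = np.concatenate(segs[: k + 1], axis=1)
            gW[k] = c_k.T @ delta
            gb[k] = delta.sum(axis=0)
            back = delta @ self.W_[k].T
            g_x += back[:, :d]
            for j in range(k):
                g_h[j] += back[:, d + j * w: d + (j + 1) * w]
        return gW, gb, gW_out, gb_out, g_x

    # ---- public surface ----

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = self._check_X(X)
        logit, _, _ = self._forward(X)
        return logit

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict_proba_male(self, X: np.ndarray) -> np.ndarray:
        """P(male) per sample, in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba_male(X) >= 0.5).astype(int)

    def output_and_input_grad(self, X: np.ndarray):
        """P(male) and its analytic gradient with respect to each input.

        Returns (p, G) with p of shape (n,) and G of shape (n, n_genes);
        G[i] = dP(male | x_i) / dx_i. This is the contract integrated
        gradients relies on.
        """
        X = self._check_X(X)
        logit, segs, zs = self._forward(X)
        p = _sigmoid(logit)
        *_, g_x = self._backward(segs, zs, p * (1.0 - p))
        return p, g_x

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "W_"):
            raise RuntimeError("model is not initialized; call fit or initialize")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"input has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return X

    def _score(self, X: np.ndarray, y: np.ndarray) -> float:
        p = self.predict_proba_male(X)
        if self.metric == "auc":
            return float(roc_auc_score(y, p))
        return float(np.mean((p >= 0.5).astype(int) == y))

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "DenseSexClassifier":
        """Train with minibatch Adam; keep the best validation epoch.

        X is (n_samples, n_genes) standardized expression; y is 0/1
        (female/male). Without an explicit validation set the per-epoch
        metric is computed on the training data (the trace is still
        recorded and the best epoch restored).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        self.initialize(X.shape[1])
        rng = np.random.default_rng(
            None if self.random_state is None else self.random_state + 1
        )
        if X_val is None:
            X_val, y_val = X, y
        else:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=float).ravel()

        params = self.W_ + self.b_ + [self.W_out_, self.b_out_]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = X.shape[0]
        trace: list[float] = []
        best = (-np.inf, -1, None)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start: start + self.batch_size]
                Xb, yb = X[idx], y[idx]
                logit, segs, zs = self._forward(Xb)
                p = _sigmoid(logit)
                delta = (p - yb) / len(idx)        # d mean-BCE / d logit
                gW, gb, gWo, gbo, _ = self._backward(segs, zs, delta)
                grads = gW + gb + [gWo, gbo]
                t += 1
                lr_t = self.learning_rate * np.sqrt(1 - b2 ** t) / (1 - b1 ** t)
                for p_, g_, m_, v_ in zip(params, grads, m, v):
                    m_ *= b1
                    m_ += (1 - b1) * g_
                    v_ *= b2
                    v_ += (1 - b2) * g_ ** 2
                    p_ -= lr_t * m_ / (np.sqrt(v_) + eps)
            score = self._score(X_val, y_val)
            trace.append(score)
            if score > best[0]:
                best = (score, epoch,
                        (copy.deepcopy(self.W_), copy.deepcopy(self.b_),
                         self.W_out_.copy(), self.b_out_.copy()))
        self.validation_trace_ = trace
        self.best_epoch_ = best[1]
        self.W_, self.b_, self.W_out_, self.b_out_ = best[2]
        return self
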