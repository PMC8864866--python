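"""Minimal dense neural network used by every learnable stage.

A deliberately small, fully deterministic multilayer perceptron: dense
layers with ReLU activations, inverted dropout, a sigmoid output unit and
binary cross-entropy trained with Adam.  Seeding the constructor makes
training bit-reproducible on a single thread, which the pipeline's
determinism contracts rely on.  With ``hidden=()`` the network degenerates
to a single affine map + sigmoid (logistic regression) — exactly the
"fully connected layer without dropout" used for the smear-level ensemble
classifier.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError

__all__ = ["DenseNet"]

_EPS = 1e-12


class DenseNet:
    """Binary classifier: dense layers -> sigmoid probability.

    Parameters
    ----------
    n_features : int
        Input dimensionality.
    hidden : tuple of int
        Widths of the hidden layers (may be empty).
    dropout : float
        Dropout rate applied to hidden activations during training.
    lr : float
        Adam learning rate.
    epochs : int
        Training epochs over the full set.
    batch_size : int
        Minibatch size (capped at the sample count).
    seed : int
        Seed for weight init, shuffling and dropout masks.
    standardize : bool
        Learn per-feature mean/std on fit and apply at predict time.
    """

    def __init__(self, n_features, hidden=(), *, dropout=0.0, lr=0.01,
                 epochs=200, batch_size=64, seed=0, standardize=True):
        self.n_features = int(n_features)
        self.hidden = tuple(int(h) for h in hidden)
        self.dropout = float(dropout)
        self.lr = float(lr)
        self.epochs = int(epochs)
        self.batch_size = int(batch_size)
        self.seed = int(seed)
        self.standardize = bool(standardize)
        self.loss_history: list[float] = []
        self.is_trained = False
        self._mu = np.zeros(self.n_features)
        self._sigma = np.ones(self.n_features)
        rng = np.random.default_rng(self.seed)
        sizes = (self.n_features, *self.hidden, 1)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._rng = rng

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights) + sum(b.size for b in self.biases))

    # ---------------------------------------------------------------- forward
    def _forward(self, X, train_rng=None):
        """Return (activations per layer, dropout masks). X already standardized."""
        acts = [X]
        masks = []
        a = X
        n_hidden = len(self.weights) - 1
        for i in range(n_hidden):
            z = a @ self.weights[i] + self.biases[i]
            a = np.maximum(z, 0.0)
            if train_rng is not None and self.dropout > 0.0:
                mask = (train_rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                a = a * mask
            else:
                mask = None
            masks.append(mask)
            acts.append(a)
        z = a @ self.weights[-1] + self.biases[-1]
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -35.0, 35.0)))
        acts.append(p)
        return acts, masks

    # -------------------------------------------------------------------- fit
    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).reshape(-1)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise DataError(f"expected (n, {self.n_features}) features, got {X.shape}")
        if X.shape[0] != y.shape[0] or X.shape[0] == 0:
            raise DataError("features and targets must be non-empty and aligned")
        if np.unique(y).size < 2:
            raise DataError("both classes must be present in the training targets")
        if self.standardize:
            self._mu = X.mean(axis=0)
            sd = X.std(axis=0)
            self._sigma = np.where(sd > _EPS, sd, 1.0)
        Xs = (X - self._mu) / self._sigma
        n = Xs.shape[0]
        bs = max(1, min(self.batch_size, n))
        rng = self._rng
        # Adam state
        m_w = [np.zeros_like(w) for w in self.weights]
        v_w = [np.zeros_like(w) for w in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        v_b = [np.zeros_like(b) for b in self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        self.loss_history = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                xb, yb = Xs[idx], y[idx]
                acts, masks = self._forward(xb, train_rng=rng)
                p = acts[-1][:, 0]
                loss = -np.mean(yb * np.log(p + _EPS) + (1 - yb) * np.log(1 - p + _EPS))
                epoch_loss += loss * len(idx)
                # backprop: d(BCE)/dz_out = p - y
                delta = (p - yb)[:, None] / len(idx)
                grads_w, grads_b = [], []
                for i in range(len(self.weights) - 1, -1, -1):
                    a_prev = acts[i]
                    grads_w.append(a_prev.T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if i > 0:
                        delta = delta @ self.weights[i].T
                        if masks[i - 1] is not None:
                            delta = delta * masks[i - 1]
                        delta = delta * (acts[i] > 0)
                grads_w.reverse()
                grads_b.reverse()
                t += 1
                for i in range(len(self.weights)):
                    m_w[i] = beta1 * m_w[i] + (1 - beta1) * grads_w[i]
                    v_w[i] = beta2 * v_w[i] + (1 - beta2) * grads_w[i] ** 2
                    m_b[i] = beta1 * m_b[i] + (1 - beta1) * grads_b[i]
                    v_b[i] = beta2 * v_b[i] + (1 - beta2) * grads_b[i] ** 2
                    mhw = m_w[i] / (1 - beta1 ** t)
                    vhw = v_w[i] / (1 - beta2 ** t)
                    mhb = m_b[i] / (1 - beta1 ** t)
                    vhb = v_b[i] / (1 - beta2 ** t)
                    self.weights[i] -= self.lr * mhw / (np.sqrt(vhw) + eps)
                    self.biases[i] -= self.lr * mhb / (np.sqrt(vhb) + eps)
            self.loss_history.append(epoch_loss / n)
        self.is_trained = True
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise DataError(f"expected {self.n_features} features, got {X.shape[1]}")
        Xs = (X - self._mu) / self._sigma
        acts, _ = self._forward(Xs)
        return acts[-1][:, 0]
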