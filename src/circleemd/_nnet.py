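"""A compact feed-forward classifier in plain numpy.

Architecture: input -> [Linear -> BatchNorm -> ReLU -> Dropout] per hidden
layer -> Linear -> softmax, trained with Adam on categorical cross-entropy in
mini-batches.  Batch statistics are tracked with running averages for
deterministic evaluation; prediction disables dropout.  Fully seeded and
single-threaded, so runs are reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DenseNet"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    """Mean categorical cross-entropy -(1/n) sum_x sum_c y_c ln z_c."""
    return float(-np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1)))


class DenseNet:
    """Multi-layer perceptron with batch normalisation and dropout."""

    def __init__(
        self,
        n_features: int,
        n_classes: int,
        hidden: tuple[int, ...] = (300, 200, 100),
        dropout: float = 0.5,
        lr: float = 1e-3,
        batch_size: int = 32,
        epochs: int = 200,
        seed: int = 0,
    ) -> None:
        self.hidden = tuple(hidden)
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.rng = np.random.default_rng(seed)
        sizes = [n_features, *hidden, n_classes]
        self.W = [
            self.rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.gamma = [np.ones(h) for h in hidden]
        self.beta = [np.zeros(h) for h in hidden]
        self.run_mean = [np.zeros(h) for h in hidden]
        self.run_var = [np.ones(h) for h in hidden]
        params = self.W + self.b + self.gamma + self.beta
        self._adam_m = [np.zeros_like(p) for p in params]
        self._adam_v = [np.zeros_like(p) for p in params]
        self._adam_t = 0
        self.loss_history: list[float] = []

    # --- forward/backward -------------------------------------------------

    def _forward_train(self, x: np.ndarray):
        cache = []
        a = x
        for l, _ in enumerate(self.hidden):
            z = a @ self.W[l] + self.b[l]
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            self.run_mean[l] = (1 - _BN_MOMENTUM) * self.run_mean[l] + _BN_MOMENTUM * mu
            self.run_var[l] = (1 - _BN_MOMENTUM) * self.run_var[l] + _BN_MOMENTUM * var
            inv = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mu) * inv
            bn = self.gamma[l] * zhat + self.beta[l]
            relu_mask = bn > 0
            h = bn * relu_mask
            if self.dropout > 0:
                drop_mask = self.rng.random(h.shape) >= self.dropout
                h = h * drop_mask / (1.0 - self.dropout)
            else:
                drop_mask = None
            cache.append((a, zhat, inv, relu_mask, drop_mask))
            a = h
        logits = a @ self.W[-1] + self.b[-1]
        return logits, a, cache

    def _backward(self, x, onehot, logits, last_a, cache):
        n = x.shape[0]
        probs = _softmax(logits)
        dlogits = (probs - onehot) / n
        gW = [np.zeros_like(w) for w in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        gG = [np.zeros_like(g) for g in self.gamma]
        gB = [np.zeros_like(b) for b in self.beta]
        gW[-1] = last_a.T @ dlogits
        gb[-1] = dlogits.sum(axis=0)
        da = dlogits @ self.W[-1].T
        for l in range(len(self.hidden) - 1, -1, -1):
            a_in, zhat, inv, relu_mask, drop_mask = cache[l]
            if drop_mask is not None:
                da = da * drop_mask / (1.0 - self.dropout)
            dbn = da * relu_mask
            gG[l] = np.sum(dbn * zhat, axis=0)
            gB[l] = np.sum(dbn, axis=0)
            dzhat = dbn * self.gamma[l]
            m = dzhat.shape[0]
            dz = (inv / m) * (
                m * dzhat - dzhat.sum(axis=0) - zhat * np.sum(dzhat * zhat, axis=0)
            )
            gW[l] = a_in.T @ dz
            gb[l] = dz.sum(axis=0)
            da = dz @ self.W[l].T
        return gW + gb + gG + gB, cross_entropy(probs, onehot)

    def _adam_step(self, grads) -> None:
        params = self.W + self.b + self.gamma + self.beta
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self._adam_t)
            vhat = v / (1 - b2**self._adam_t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)

    # --- public API -------------------------------------------------------

    def fit(self, x: np.ndarray, y: np.ndarray) -> "DenseNet":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        n, n_classes = x.shape[0], self.b[-1].size
        onehot = np.eye(n_classes)[y]
        for _ in range(self.epochs):
            order = self.rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                if idx.size < 2:  # batch statistics need >= 2 samples
                    continue
                logits, last_a, cache = self._forward_train(x[idx])
                grads, loss = self._backward(x[idx], onehot[idx], logits, last_a, cache)
                self._adam_step(grads)
                epoch_losses.append(loss)
            self.loss_history.append(float(np.mean(epoch_losses)))
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        a = np.asarray(x, dtype=float)
        for l, _ in enumerate(self.hidden):
            z = a @ self.W[l] + self.b[l]
            zhat = (z - self.run_mean[l]) / np.sqrt(self.run_var[l] + _BN_EPS)
            a = np.maximum(self.gamma[l] * zhat + self.beta[l], 0.0)
        return _softmax(a @ self.W[-1] + self.b[-1])

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)
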