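"""A minimal LSTM sequence classifier (numpy forward pass + BPTT + Adam).

Architecture: input layer -> one LSTM hidden layer with U units -> dense
softmax output, trained with categorical cross-entropy.  Only the final
hidden state feeds the output layer, which is the standard setup for
whole-sequence classification.  Gradients are backpropagated through time
over the full sequence and clipped by global norm for stability on
large-amplitude raw signals.

Shapes: inputs are (batch, timesteps, features); gate weights are packed
column-wise as [input, forget, cell, output].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class FitHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


class LSTMClassifier:
    """Single-hidden-layer LSTM classifier trained with Adam.

    Parameters
    ----------
    n_hidden : int
        Number of LSTM units U.
    n_classes : int
        Output classes (softmax width).
    n_features : int
        Input features per timestep (1 for scalar signals).
    learning_rate : float
        Adam step size (default 0.001, the standard setting).
    seed : int
        Seeds weight initialization and minibatch shuffling; fits are
        bitwise reproducible for a fixed seed.
    """

    def __init__(self, n_hidden: int = 16, n_classes: int = 2, n_features: int = 1,
                 learning_rate: float = 0.001, clip_norm: float = 5.0, seed: int = 0):
        if n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        self.n_hidden = n_hidden
        self.n_classes = n_classes
        self.n_features = n_features
        self.learning_rate = learning_rate
        self.clip_norm = clip_norm
        self.seed = seed

        rng = np.random.default_rng(seed)
        H, F, C = n_hidden, n_features, n_classes
        sx = 1.0 / np.sqrt(F)
        sh = 1.0 / np.sqrt(H)
        self.Wx = rng.uniform(-sx, sx, (F, 4 * H))
        self.Wh = rng.uniform(-sh, sh, (H, 4 * H))
        self.b = np.zeros(4 * H)
        self.b[H:2 * H] = 1.0  # forget-gate bias: remember by default
        self.Wout = rng.uniform(-sh, sh, (H, C))
        self.bout = np.zeros(C)
        self._rng = rng
        self._adam_state = None

    # -- forward ------------------------------------------------------------

    def _forward(self, X: np.ndarray, want_cache: bool = False):
        B, Tn, F = X.shape
        H = self.n_hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = [] if want_cache else None
        for t in range(Tn):
            z = X[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = 1.0 / (1.0 + np.exp(-z[:, :H]))
            f = 1.0 / (1.0 + np.exp(-z[:, H:2 * H]))
            g = np.tanh(z[:, 2 * H:3 * H])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * H:]))
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            if want_cache:
                cache.append((i, f, g, o, c_prev, tc, h_prev))
        logits = h @ self.Wout + self.bout
        return (logits, h, cache) if want_cache else (logits, h)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(np.asarray(X, dtype=float))
        return _softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def evaluate(self, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """Mean cross-entropy loss and accuracy on (X, y)."""
        p = self.predict_proba(X)
        y = np.asarray(y, dtype=int)
        loss = float(-np.log(np.clip(p[np.arange(len(y)), y], 1e-12, None)).mean())
        acc = float((np.argmax(p, axis=1) == y).mean())
        return loss, acc

    # -- backward -----------------------------------------------------------

    def _backward(self, X, y, logits, h_final, cache):
        B, Tn, _ = X.shape
        H = self.n_hidden
        p = _softmax(logits)
        dlogits = p.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B

        grads = {
            "Wout": h_final.T @ dlogits,
            "bout": dlogits.sum(axis=0),
            "Wx": np.zeros_like(self.Wx),
            "Wh": np.zeros_like(self.Wh),
            "b": np.zeros_like(self.b),
        }
        dh = dlogits @ self.Wout.T
        dc = np.zeros((B, H))
        for t in range(Tn - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ], axis=1)
            grads["Wx"] += X[:, t, :].T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dz @ self.Wh.T
            dc = dc * f

        loss = float(-np.log(np.clip(p[np.arange(B), y], 1e-12, None)).mean())
        acc = float((np.argmax(p, axis=1) == y).mean())
        return grads, loss, acc

    def _adam_step(self, grads):
        if self._adam_state is None:
            self._adam_state = {k: (np.zeros_like(v), np.zeros_like(v))
                                for k, v in grads.items()}
            self._adam_t = 0
        norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
        if self.clip_norm and norm > self.clip_norm:
            grads = {k: g * (self.clip_norm / norm) for k, g in grads.items()}
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr = self.learning_rate * np.sqrt(1 - b2 ** self._adam_t) / (1 - b1 ** self._adam_t)
        for k, g in grads.items():
            m, v = self._adam_state[k]
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g ** 2
            getattr(self, k)[...] = getattr(self, k) - lr * m / (np.sqrt(v) + eps)

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 200,
            batch_size: int = 64, X_val: np.ndarray | None = None,
            y_val: np.ndarray | None = None) -> FitHistory:
        """Minibatch training; per-epoch train metrics are averaged over the
        epoch's minibatches, validation metrics are a full forward pass.

        Raises ``FloatingPointError`` if the loss becomes non-finite.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n = X.shape[0]
        history = FitHistory()
        for epoch in range(epochs):
            order = self._rng.permutation(n)
            losses, accs, weights = [], [], []
            for start in range(0, n, batch_size):
                sel = order[start:start + batch_size]
                logits, h, cache = self._forward(X[sel], want_cache=True)
                grads, loss, acc = self._backward(X[sel], y[sel], logits, h, cache)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch + 1}; "
                        f"grad norms: "
                        + ", ".join(f"{k}={float(np.abs(g).max()):.3g}"
                                    for k, g in grads.items()))
                self._adam_step(grads)
                losses.append(loss)
                accs.append(acc)
                weights.append(len(sel))
            w = np.asarray(weights, dtype=float)
            history.train_loss.append(float(np.average(losses, weights=w)))
            history.train_accuracy.append(float(np.average(accs, weights=w)))
            if X_val is not None:
                vl, va = self.evaluate(X_val, y_val)
                history.val_loss.append(vl)
                history.val_accuracy.append(va)
        return history
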