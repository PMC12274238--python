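"""The trained classification head: an LSTM over per-frame feature sequences.

This is the only trained component of the pipeline.  A single-layer LSTM
with 128 hidden units reads a 25-frame feature sequence and a fully
connected layer maps each hidden state to a softmax over the six states
(background + five gestures).  Training minimizes frame-averaged
cross-entropy with Adam and early stopping on validation loss.

The network is implemented directly in NumPy (forward pass,
backpropagation through time, Adam) and wrapped as a scikit-learn
estimator, so it composes with sklearn model selection and is exactly
reproducible from a seed on any CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .annotation import N_CLASSES


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class LSTMGestureClassifier(BaseEstimator, ClassifierMixin):
    """Per-frame gesture classifier over fixed-length feature sequences.

    Parameters
    ----------
    hidden_units : LSTM state size (128 matches the original head).
    n_classes : number of output states (background + 5 gestures).
    epochs, batch_size, learning_rate : Adam training schedule.
    patience : early-stopping patience on validation loss (epochs).
    validation_fraction : share of training sequences held out for early
        stopping when no explicit validation set is passed to :meth:`fit`.
    class_weight : ``None`` or ``"balanced"`` (inverse-frequency weights in
        the loss; off by default).
    random_state : seed for weight init, shuffling and the validation split.

    ``fit`` consumes ``X`` of shape ``(n_sequences, seq_len, dim)`` and ``y``
    of shape ``(n_sequences, seq_len)`` with integer frame labels; frames at
    gesture boundaries may carry mixed labels within one sequence, and the
    loss is averaged over frames.
    """

    def __init__(self, hidden_units: int = 128, n_classes: int = N_CLASSES,
                 epochs: int = 30, batch_size: int = 128,
                 learning_rate: float = 3e-3, patience: int = 5,
                 validation_fraction: float = 0.1,
                 class_weight: str | None = None,
                 grad_clip: float = 5.0, random_state: int = 0):
        self.hidden_units = hidden_units
        self.n_classes = n_classes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.class_weight = class_weight
        self.grad_clip = grad_clip
        self.random_state = random_state

    # -- numerics --------------------------------------------------------------

    def _init_weights(self, dim: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        H, K = self.hidden_units, self.n_classes

        def glorot(fan_in, fan_out, shape):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias starts open
        return {
            "Wx": glorot(dim, H, (dim, 4 * H)),
            "Wh": glorot(H, H, (H, 4 * H)),
            "b": b,
            "Wy": glorot(H, K, (H, K)),
            "by": np.zeros(K),
        }

    def _forward(self, X: np.ndarray, W: dict[str, np.ndarray],
                 keep_cache: bool = False):
        """X: (B, T, D) -> probabilities (B, T, K) [+ BPTT cache]."""
        B, T, _ = X.shape
        H = self.hidden_units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = [] if keep_cache else None
        for t in range(T):
            a = X[:, t] @ W["Wx"] + h @ W["Wh"] + W["b"]
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = _sigmoid(a[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            if keep_cache:
                cache.append((i, f, g, o, c_prev, tc))
        logits = hs @ W["Wy"] + W["by"]
        probs = _softmax(logits)
        if keep_cache:
            return probs, hs, cache
        return probs

    def _backward(self, X, y, probs, hs, cache, W, sample_weight):
        """Frame-averaged cross-entropy gradients via BPTT."""
        B, T, D = X.shape
        H = self.hidden_units
        K = self.n_classes
        onehot = np.eye(K)[y]                      # (B, T, K)
        dlogits = (probs - onehot) * sample_weight[..., None]
        grads = {k: np.zeros_like(v) for k, v in W.items()}
        grads["Wy"] = np.einsum("bth,btk->hk", hs, dlogits)
        grads["by"] = dlogits.sum(axis=(0, 1))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc = cache[t]
            dh = dlogits[:, t] @ W["Wy"].T + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H))
            grads["Wx"] += X[:, t].T @ da
            grads["Wh"] += h_prev.T @ da
            grads["b"] += da.sum(axis=0)
            dh_next = da @ W["Wh"].T
            dc_next = dc * f
        return grads

    def _loss(self, probs, y, sample_weight):
        p = np.take_along_axis(probs, y[..., None], axis=-1)[..., 0]
        return float(np.mean(-np.log(np.maximum(p, 1e-12)) * sample_weight)
                     / max(np.mean(sample_weight), 1e-12))

    # -- estimator API ---------------------------------------------------------

    def fit(self, X, y, validation_data=None):
        """Train on sequences ``X (n, T, D)`` with frame labels ``y (n, T)``."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 3 or y.shape != X.shape[:2]:
            raise ValueError("X must be (n, seq_len, dim) and y (n, seq_len)")
        rng = np.random.default_rng(self.random_state)
        n, T, D = X.shape

        present = np.unique(y)
        missing = sorted(set(range(self.n_classes)) - set(present.tolist()))
        if missing:
            import warnings
            warnings.warn(f"classes absent from training labels: {missing}; "
                          "the head can still emit them with low probability",
                          stacklevel=2)

        if validation_data is not None:
            Xv, yv = (np.asarray(validation_data[0], dtype=np.float64),
                      np.asarray(validation_data[1], dtype=np.int64))
            Xt, yt = X, y
        else:
            n_val = max(1, int(round(n * self.validation_fraction))) if n > 1 else 0
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            if len(tr_idx) == 0:
                tr_idx = val_idx
            Xt, yt = X[tr_idx], y[tr_idx]
            Xv, yv = X[val_idx], y[val_idx]
            if len(val_idx) == 0:
                Xv, yv = Xt, yt

        cw = np.ones(self.n_classes)
        if self.class_weight == "balanced":
            counts = np.bincount(yt.ravel(), minlength=self.n_classes).astype(float)
            nz = counts > 0
            cw[nz] = counts[nz].sum() / (nz.sum() * counts[nz])
        wt = cw[yt]
        wv = cw[yv]

        W = self._init_weights(D, rng)
        m = {k: np.zeros_like(v) for k, v in W.items()}
        v = {k: np.zeros_like(v_) for k, v_ in W.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss = np.inf
        best_W = {k: w.copy() for k, w in W.items()}
        history = {"epoch": [], "train_loss": [], "val_loss": [], "val_accuracy": []}
        stale = 0
        for epoch in range(self.epochs):
            order = rng.permutation(len(Xt))
            ep_loss = 0.0
            n_batches = 0
            for s in range(0, len(order), self.batch_size):
                idx = order[s:s + self.batch_size]
                xb, yb, wb = Xt[idx], yt[idx], wt[idx]
                probs, hs, cache = self._forward(xb, W, keep_cache=True)
                ep_loss += self._loss(probs, yb, wb)
                n_batches += 1
                grads = self._backward(xb, yb, probs, hs, cache, W, wb)
                scale = 1.0 / (len(idx) * xb.shape[1] * max(np.mean(wb), 1e-12))
                step += 1
                for k in W:
                    gk = grads[k] * scale
                    gn = np.linalg.norm(gk)
                    if gn > self.grad_clip:
                        gk = gk * (self.grad_clip / gn)
                    m[k] = beta1 * m[k] + (1 - beta1) * gk
                    v[k] = beta2 * v[k] + (1 - beta2) * gk ** 2
                    mh = m[k] / (1 - beta1 ** step)
                    vh = v[k] / (1 - beta2 ** step)
                    W[k] -= self.learning_rate * mh / (np.sqrt(vh) + eps)
            val_probs = self._predict_in_batches(Xv, W)
            val_loss = self._loss(val_probs, yv, wv)
            val_acc = float(np.mean(val_probs.argmax(axis=-1) == yv))
            history["epoch"].append(epoch)
            history["train_loss"].append(ep_loss / max(n_batches, 1))
            history["val_loss"].append(val_loss)
            history["val_accuracy"].append(val_acc)
            if val_loss < best_loss - 1e-5:
                best_loss = val_loss
                best_W = {k: w.copy() for k, w in W.items()}
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        self.weights_ = best_W
        self.history_ = history
        self.n_features_in_ = D
        self.sequence_len_ = T
        self.classes_ = np.arange(self.n_classes)
        self.best_val_loss_ = best_loss
        return self

    def _predict_in_batches(self, X, W, batch: int = 512) -> np.ndarray:
        outs = [self._forward(X[s:s + batch], W) for s in range(0, len(X), batch)]
        return np.concatenate(outs) if outs else np.empty((0, 0, self.n_classes))

    def predict_proba(self, X) -> np.ndarray:
        """Per-frame class probabilities, shape ``(n, seq_len, n_classes)``."""
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        if X.shape[2] != self.n_features_in_:
            raise ValueError(f"feature dim {X.shape[2]} != fitted "
                             f"{self.n_features_in_}")
        return self._predict_in_batches(X, self.weights_)

    def predict(self, X) -> np.ndarray:
        """Per-frame argmax labels (ties resolved toward the lower index)."""
        return self.predict_proba(X).argmax(axis=-1)

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    # -- persistence -----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "weights_")
        path = Path(path)
        np.savez(path, __config__=json.dumps(self.get_params()), **self.weights_)

    @classmethod
    def load(cls, path: str | Path) -> "LSTMGestureClassifier":
        with np.load(path, allow_pickle=False) as z:
            params = json.loads(str(z["__config__"]))
            est = cls(**params)
            est.weights_ = {k: z[k] for k in ("Wx", "Wh", "b", "Wy", "by")}
        est.n_features_in_ = est.weights_["Wx"].shape[0]
        est.sequence_len_ = None
        est.classes_ = np.arange(est.n_classes)
        est.history_ = {}
        return est
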