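"""A compact 1-D convolutional network implemented on numpy.

Architecture: a stack of strided 1-D convolutions with ReLU, global average
pooling over time, a dense ReLU layer, and a softmax classification layer.
Training is mini-batch Adam on cross-entropy with best-validation-accuracy
checkpointing. Everything is seeded and single-threaded-deterministic.

The implementation favours clarity and the matmul-heavy im2col formulation,
which is fast enough at the reduced widths used for synthetic-data training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvNet", "ConvNetSpec"]


@dataclass
class ConvNetSpec:
    """Shape hyperparameters of the network."""

    in_channels: int
    n_classes: int
    n_conv_layers: int = 4
    filters: int = 32
    kernel_size: int = 7
    stride: int = 2
    dense_units: int = 64
    #: inputs are divided by this before the first layer, so that signals in
    #: physiological μV ranges reach the network at unit scale
    input_scale: float = 50.0


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B, C, L) -> (B, L_out, C*k) patches with 'same'-style zero padding."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(xp, k, axis=2)[:, :, ::stride, :]  # B,C,L_out,k
    B, C, L_out, _ = win.shape
    return win.transpose(0, 2, 1, 3).reshape(B, L_out, C * k)


class _Conv1d:
    def __init__(self, c_in, c_out, k, stride, rng):
        scale = np.sqrt(2.0 / (c_in * k))
        self.w = rng.normal(0.0, scale, (c_in * k, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.stride, self.c_in = k, stride, c_in

    def forward(self, x):
        self._cols = _im2col(x, self.k, self.stride)        # B,L_out,C*k
        y = self._cols @ self.w + self.b                     # B,L_out,c_out
        self._x_shape = x.shape
        return y.transpose(0, 2, 1)                          # B,c_out,L_out

    def backward(self, dy):
        dy = dy.transpose(0, 2, 1)                           # B,L_out,c_out
        B, L_out, _ = dy.shape
        self.dw = np.tensordot(self._cols, dy, axes=([0, 1], [0, 1]))
        self.db = dy.sum(axis=(0, 1))
        dcols = dy @ self.w.T                                # B,L_out,C*k
        dcols = dcols.reshape(B, L_out, self.c_in, self.k).transpose(0, 2, 1, 3)
        _, C, L = self._x_shape
        pad = self.k // 2
        dxp = np.zeros((B, C, L + 2 * pad), dtype=np.float32)
        idx = np.arange(L_out) * self.stride
        for j in range(self.k):
            np.add.at(dxp, (slice(None), slice(None), idx + j), dcols[:, :, :, j])
        return dxp[:, :, pad:pad + L]

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class _Dense:
    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class ConvNet:
    """Strided conv stack + global average pooling + dense + softmax."""

    def __init__(self, spec: ConvNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.convs = []
        c = spec.in_channels
        for _ in range(spec.n_conv_layers):
            self.convs.append(_Conv1d(c, spec.filters, spec.kernel_size,
                                      spec.stride, rng))
            c = spec.filters
        self.dense = _Dense(c, spec.dense_units, rng)
        self.head = _Dense(spec.dense_units, spec.n_classes, rng)
        self._adam_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for a (B, C, L) float batch."""
        a = np.ascontiguousarray(x, dtype=np.float32) / np.float32(self.spec.input_scale)
        self._relu_masks = []
        for conv in self.convs:
            a = conv.forward(a)
            mask = a > 0
            a *= mask
            self._relu_masks.append(mask)
        self._pool_len = a.shape[2]
        a = a.mean(axis=2)                                   # global avg pool
        h = self.dense.forward(a)
        hmask = h > 0
        h *= hmask
        self._dense_mask = hmask
        logits = self.head.forward(h)
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        self._probs = e / e.sum(axis=1, keepdims=True)
        return self._probs

    def _backward(self, y_true: np.ndarray) -> None:
        B = y_true.size
        dlogits = self._probs.copy()
        dlogits[np.arange(B), y_true] -= 1.0
        dlogits /= B
        dh = self.head.backward(dlogits.astype(np.float32))
        dh *= self._dense_mask
        da = self.dense.backward(dh)
        da = np.repeat(da[:, :, None] / self._pool_len, self._pool_len, axis=2)
        for conv, mask in zip(reversed(self.convs), reversed(self._relu_masks)):
            da *= mask
            da = conv.backward(da)

    def _layers(self):
        return [*self.convs, self.dense, self.head]

    def _adam_step(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for layer in self._layers():
            for name, p, g in layer.params():
                key = (id(layer), name)
                m, v = self._adam_state.get(key, (np.zeros_like(p), np.zeros_like(p)))
                m = beta1 * m + (1 - beta1) * g
                v = beta2 * v + (1 - beta2) * g * g
                self._adam_state[key] = (m, v)
                mhat = m / (1 - beta1 ** t)
                vhat = v / (1 - beta2 ** t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- training / inference ------------------------------------------------

    def get_weights(self):
        out = []
        for layer in self._layers():
            out.append(layer.w.copy())
            out.append(layer.b.copy())
        return out

    def set_weights(self, weights):
        i = 0
        for layer in self._layers():
            layer.w[...] = weights[i]; i += 1
            layer.b[...] = weights[i]; i += 1

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(self.forward(x[i:i + batch_size]).copy())
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)

    def fit(self, x, y, x_val, y_val, *, lr=1e-3, batch_size=64, max_epochs=20,
            seed=0, verbose=False):
        """Adam training with best-validation-accuracy checkpointing.

        Returns a history dict with per-epoch train loss and validation
        accuracy; the network is left at the best-validation checkpoint.
        """
        if x.shape[0] == 0 or x_val.shape[0] == 0:
            raise ValueError("training and validation sets must be non-empty")
        y = np.asarray(y, dtype=np.int64)
        y_val = np.asarray(y_val, dtype=np.int64)
        for arr in (y, y_val):
            if arr.min() < 0 or arr.max() >= self.spec.n_classes:
                raise ValueError("label outside the configured class range")
        rng = np.random.default_rng(seed)
        history = {"train_loss": [], "val_accuracy": []}
        best_acc, best_weights = -1.0, None
        for epoch in range(max_epochs):
            order = rng.permutation(x.shape[0])
            losses = []
            for i in range(0, len(order), batch_size):
                idx = order[i:i + batch_size]
                probs = self.forward(x[idx])
                losses.append(float(-np.log(
                    np.clip(probs[np.arange(idx.size), y[idx]], 1e-12, None)).mean()))
                self._backward(y[idx])
                self._adam_step(lr)
            val_acc = float((self.predict(x_val) == y_val).mean())
            history["train_loss"].append(float(np.mean(losses)))
            history["val_accuracy"].append(val_acc)
            if val_acc > best_acc:
                best_acc = val_acc
                best_weights = self.get_weights()
            if verbose:
                print(f"epoch {epoch + 1}: loss {history['train_loss'][-1]:.4f} "
                      f"val acc {val_acc:.3f}")
        self.set_weights(best_weights)
        history["best_val_accuracy"] = best_acc
        return history

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for i, layer in enumerate(self._layers()):
            arrays[f"w{i}"] = layer.w
            arrays[f"b{i}"] = layer.b
        np.savez(path, n_conv_layers=self.spec.n_conv_layers,
                 filters=self.spec.filters, kernel_size=self.spec.kernel_size,
                 stride=self.spec.stride, dense_units=self.spec.dense_units,
                 in_channels=self.spec.in_channels, n_classes=self.spec.n_classes,
                 input_scale=self.spec.input_scale, **arrays)

    @classmethod
    def load(cls, path) -> "ConvNet":
        z = np.load(path)
        spec = ConvNetSpec(
            in_channels=int(z["in_channels"]), n_classes=int(z["n_classes"]),
            n_conv_layers=int(z["n_conv_layers"]), filters=int(z["filters"]),
            kernel_size=int(z["kernel_size"]), stride=int(z["stride"]),
            dense_units=int(z["dense_units"]), input_scale=float(z["input_scale"]),
        )
        net = cls(spec)
        for i, layer in enumerate(net._layers()):
            layer.w[...] = z[f"w{i}"]
            layer.b[...] = z[f"b{i}"]
        return net
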