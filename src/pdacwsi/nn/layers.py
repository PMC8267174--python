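"""Layer primitives. Every layer implements forward(x) and backward(dout);
parameters live in ``layer.params`` with matching gradients in
``layer.grads`` after a backward pass."""

from __future__ import annotations

import copy

import numpy as np


class Layer:
    """Base class; stateless layers keep empty param dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or kxk, odd k) convolution, stride 1, zero 'same' padding.

    He-normal initialisation from the supplied generator. The forward and
    backward passes are written as k*k shifted matmuls, which keeps peak
    memory at one padded copy of the input instead of a full im2col buffer.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, dtype=np.float32) -> None:
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        std = np.sqrt(2.0 / (k * k * c_in))
        self.params = {
            "W": (rng.standard_normal((k, k, c_in, c_out)) * std).astype(dtype),
            "b": np.zeros(c_out, dtype=dtype),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.broadcast_to(self.params["b"], (n, h, w, self.c_out)).copy()
        W = self.params["W"]
        for i in range(k):
            for j in range(k):
                out += xp[:, i:i + h, j:j + w, :] @ W[i, j]
        self._cache = xp
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = self._cache
        n, h, w, _ = dout.shape
        W = self.params["W"]
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                patch = xp[:, i:i + h, j:j + w, :]
                dW[i, j] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i:i + h, j:j + w, :] += dout @ W[i, j].T
        self.grads = {"W": dW, "b": dout.sum(axis=(0, 1, 2))}
        return dxp[:, p:p + h, p:p + w, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        # clip to keep exp() finite; sigmoid saturates long before +/-60
        self._s = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._s

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._s * (1.0 - self._s)


class MaxPool(Layer):
    """Non-overlapping max pool; spatial dims must be divisible by k."""

    def __init__(self, k: int) -> None:
        super().__init__()
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        n, h, w, c = x.shape
        if h % k or w % k:
            raise ValueError(f"spatial dims {h}x{w} not divisible by pool {k}")
        xr = (x.reshape(n, h // k, k, w // k, k, c)
               .transpose(0, 1, 3, 5, 2, 4)
               .reshape(n, h // k, w // k, c, k * k))
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        n, h, w, c = self._shape
        dxr = np.zeros((n, h // k, w // k, c, k * k), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        return (dxr.reshape(n, h // k, w // k, c, k, k)
                   .transpose(0, 1, 4, 2, 5, 3)
                   .reshape(n, h, w, c))


class GlobalAvgPool(Layer):
    """(N,H,W,C) -> (N,C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w),
                               self._shape).astype(dout.dtype)


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Dense(Layer):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        std = np.sqrt(2.0 / f_in)
        self.params = {
            "W": (rng.standard_normal((f_in, f_out)) * std).astype(dtype),
            "b": np.zeros(f_out, dtype=dtype),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


class Sequential:
    """A linear stack of layers with optional intermediate capture, which
    Grad-CAM uses to read conv activations and the gradients flowing into
    them."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, record: set[int] | None = None):
        outputs: dict[int, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            x = layer.forward(x)
            if record and i in record:
                outputs[i] = x
        if record is None:
            return x
        return x, outputs

    def backward(self, dout: np.ndarray, record: set[int] | None = None):
        grads_at: dict[int, np.ndarray] = {}
        for i in range(len(self.layers) - 1, -1, -1):
            if record and i in record:
                grads_at[i] = dout  # gradient w.r.t. layers[i]'s output
            dout = self.layers[i].backward(dout)
        if record is None:
            return dout
        return dout, grads_at

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        """Yield (layer, name) pairs in a stable order."""
        for layer in self.layers:
            for name in sorted(layer.params):
                yield layer, name

    def state_dict(self) -> list[dict[str, np.ndarray]]:
        return [copy.deepcopy(layer.params) for layer in self.layers]

    def load_state_dict(self, state: list[dict[str, np.ndarray]]) -> None:
        for layer, params in zip(self.layers, state, strict=True):
            layer.params = copy.deepcopy(params)

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params.values())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean categorical cross-entropy over the batch.

    Returns (loss, dlogits, probabilities); labels are integer class ids.
    """
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, dlogits, p
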