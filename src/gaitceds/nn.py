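"""Minimal NHWC neural-network engine: forward, analytic backward, Adam.

Layers operate on arrays of shape (N, H, W, C).  Each layer exposes
``forward(x, training)`` and ``backward(grad)``; trainable arrays live in
``layer.p`` with matching gradients in ``layer.g``, non-trainable state
(batch-norm moving statistics) in ``layer.s``.  Composite layers list
sub-layers in ``layer.children`` so parameter traversal is recursive.

The engine implements exactly what the gait models need — small 2-D
convolutions (kernels 1x9, 1x3, 6x1), non-overlapping pooling, batch
normalization, depthwise convolution, dense layers — with no attempt at
generality beyond that.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np


class Layer:
    """Base layer: parameter dicts plus recursive traversal."""

    def __init__(self) -> None:
        self.p: dict[str, np.ndarray] = {}  # trainable
        self.g: dict[str, np.ndarray] = {}  # gradients of self.p
        self.s: dict[str, np.ndarray] = {}  # non-trainable state
        self.children: list[Layer] = []
        self.name = type(self).__name__

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def walk(self, prefix: str = "") -> Iterator[tuple[str, "Layer"]]:
        label = f"{prefix}{self.name}"
        yield label, self
        for i, child in enumerate(self.children):
            yield from child.walk(prefix=f"{label}.{i}:")

    def n_parameters(self, include_state: bool = True) -> int:
        """Array-size parameter count (trainable, plus state by default)."""
        total = 0
        for _, layer in self.walk():
            total += sum(a.size for a in layer.p.values())
            if include_state:
                total += sum(a.size for a in layer.s.values())
        return total

    def astype(self, dtype) -> "Layer":
        for _, layer in self.walk():
            for d in (layer.p, layer.g, layer.s):
                for k in d:
                    d[k] = d[k].astype(dtype)
        return self


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def same_pad(in_len: int, kernel: int, stride: int) -> tuple[int, int]:
    """'same' padding amounts (before, after): output = ceil(in/stride)."""
    out_len = -(-in_len // stride)
    total = max((out_len - 1) * stride + kernel - in_len, 0)
    return total // 2, total - total // 2


class Conv2D(Layer):
    """2-D convolution with bias, NHWC, 'same' or 'valid' padding."""

    def __init__(self, in_ch, out_ch, kernel, stride=(1, 1), padding="same",
                 rng=None, dtype=np.float32, name=None):
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        rng = rng or np.random.default_rng(0)
        kh, kw = kernel
        self.kh, self.kw = kh, kw
        self.stride = stride
        self.padding = padding
        fan_in, fan_out = kh * kw * in_ch, kh * kw * out_ch
        self.p["W"] = glorot_uniform(rng, (kh, kw, in_ch, out_ch), fan_in, fan_out, dtype)
        self.p["b"] = np.zeros(out_ch, dtype=dtype)
        if name:
            self.name = name

    def forward(self, x, training=False):
        n, h, w, _ = x.shape
        sh, sw = self.stride
        if self.padding == "same":
            pt, pb = same_pad(h, self.kh, sh)
            pl, pr = same_pad(w, self.kw, sw)
        else:
            pt = pb = pl = pr = 0
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0))) if (pt | pb | pl | pr) else x
        hp, wp = xp.shape[1], xp.shape[2]
        ho = (hp - self.kh) // sh + 1
        wo = (wp - self.kw) // sw + 1
        out = np.tile(self.p["b"], (n, ho, wo, 1)).astype(xp.dtype)
        weight = self.p["W"]
        for u in range(self.kh):
            for v in range(self.kw):
                sl = xp[:, u : u + sh * (ho - 1) + 1 : sh, v : v + sw * (wo - 1) + 1 : sw, :]
                out += sl @ weight[u, v]
        self._cache = (xp, (pt, pb, pl, pr), (ho, wo), x.shape)
        return out

    def backward(self, grad):
        xp, (pt, pb, pl, pr), (ho, wo), x_shape = self._cache
        sh, sw = self.stride
        weight = self.p["W"]
        dW = np.zeros_like(weight)
        dxp = np.zeros_like(xp)
        for u in range(self.kh):
            for v in range(self.kw):
                sl = xp[:, u : u + sh * (ho - 1) + 1 : sh, v : v + sw * (wo - 1) + 1 : sw, :]
                dW[u, v] = np.tensordot(sl, grad, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, u : u + sh * (ho - 1) + 1 : sh, v : v + sw * (wo - 1) + 1 : sw, :] += (
                    grad @ weight[u, v].T
                )
        self.g["W"] = dW
        self.g["b"] = grad.sum(axis=(0, 1, 2))
        n, h, w, c = x_shape
        return dxp[:, pt : pt + h, pl : pl + w, :]


class DepthwiseConv1xK(Layer):
    """Depthwise convolution along the width axis: one 1xK filter per channel.

    The channel count is unchanged; with 'valid' padding the width
    shrinks by K-1.  Includes a per-channel bias.
    """

    def __init__(self, channels, k=3, padding="valid", rng=None, dtype=np.float32,
                 name=None):
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        rng = rng or np.random.default_rng(0)
        self.k = k
        self.padding = padding
        self.p["W"] = glorot_uniform(rng, (k, channels), k, k, dtype)
        self.p["b"] = np.zeros(channels, dtype=dtype)
        if name:
            self.name = name

    def forward(self, x, training=False):
        if self.padding == "same":
            pl, pr = same_pad(x.shape[2], self.k, 1)
            xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (0, 0)))
        else:
            pl = pr = 0
            xp = x
        wo = xp.shape[2] - self.k + 1
        out = np.tile(self.p["b"], (x.shape[0], x.shape[1], wo, 1)).astype(x.dtype)
        for u in range(self.k):
            out += xp[:, :, u : u + wo, :] * self.p["W"][u]
        self._cache = (xp, pl, x.shape[2], wo)
        return out

    def backward(self, grad):
        xp, pl, w_in, wo = self._cache
        dW = np.empty_like(self.p["W"])
        dxp = np.zeros_like(xp)
        for u in range(self.k):
            dW[u] = (xp[:, :, u : u + wo, :] * grad).sum(axis=(0, 1, 2))
            dxp[:, :, u : u + wo, :] += grad * self.p["W"][u]
        self.g["W"] = dW
        self.g["b"] = grad.sum(axis=(0, 1, 2))
        return dxp[:, :, pl : pl + w_in, :]


class MaxPool1x2(Layer):
    """Non-overlapping 1x2 max pooling along the width axis."""

    def __init__(self, name=None):
        super().__init__()
        if name:
            self.name = name

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        if w % 2:
            raise ValueError(f"width {w} not divisible by pool size 2")
        xr = x.reshape(n, h, w // 2, 2, c)
        self._idx = xr.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None, :], axis=3)[:, :, :, 0, :]

    def backward(self, grad):
        n, h, w, c = self._shape
        dxr = np.zeros((n, h, w // 2, 2, c), dtype=grad.dtype)
        np.put_along_axis(dxr, self._idx[..., None, :], grad[..., None, :], axis=3)
        return dxr.reshape(n, h, w, c)


class AvgPool1x2(Layer):
    """Non-overlapping 1x2 average pooling along the width axis."""

    def __init__(self, name=None):
        super().__init__()
        if name:
            self.name = name

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        if w % 2:
            raise ValueError(f"width {w} not divisible by pool size 2")
        self._shape = x.shape
        return x.reshape(n, h, w // 2, 2, c).mean(axis=3)

    def backward(self, grad):
        n, h, w, c = self._shape
        return np.repeat(grad[:, :, :, None, :] / 2.0, 2, axis=3).reshape(n, h, w, c)


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W).

    Carries four arrays per channel: learnable gamma/beta and moving
    mean/variance used at inference.
    """

    def __init__(self, channels, momentum=0.9, eps=1e-5, dtype=np.float32, name=None):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.p["gamma"] = np.ones(channels, dtype=dtype)
        self.p["beta"] = np.zeros(channels, dtype=dtype)
        self.s["moving_mean"] = np.zeros(channels, dtype=dtype)
        self.s["moving_var"] = np.ones(channels, dtype=dtype)
        if name:
            self.name = name

    def forward(self, x, training=False):
        axes = (0, 1, 2)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.s["moving_mean"] = (m * self.s["moving_mean"] + (1 - m) * mean).astype(
                self.s["moving_mean"].dtype
            )
            self.s["moving_var"] = (m * self.s["moving_var"] + (1 - m) * var).astype(
                self.s["moving_var"].dtype
            )
        else:
            mean = self.s["moving_mean"]
            var = self.s["moving_var"]
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        self._cache = (xhat, std, training)
        return self.p["gamma"] * xhat + self.p["beta"]

    def backward(self, grad):
        xhat, std, training = self._cache
        self.g["gamma"] = (grad * xhat).sum(axis=(0, 1, 2))
        self.g["beta"] = grad.sum(axis=(0, 1, 2))
        gghat = grad * self.p["gamma"]
        if not training:
            return gghat / std
        axes = (0, 1, 2)
        m = np.prod([xhat.shape[a] for a in axes])
        return (gghat - gghat.mean(axis=axes) - xhat * (gghat * xhat).mean(axis=axes)) / std


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim, out_dim, rng=None, dtype=np.float32, name=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.p["W"] = glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim, dtype)
        self.p["b"] = np.zeros(out_dim, dtype=dtype)
        if name:
            self.name = name

    def forward(self, x, training=False):
        self._x = x
        return x @ self.p["W"] + self.p["b"]

    def backward(self, grad):
        self.g["W"] = self._x.T @ grad
        self.g["b"] = grad.sum(axis=0)
        return grad @ self.p["W"].T


class Network(Layer):
    """A plain sequential stack with weight snapshot/restore and I/O."""

    def __init__(self, layers, name="Network"):
        super().__init__()
        self.children = list(layers)
        self.name = name

    def forward(self, x, training=False):
        for layer in self.children:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.children):
            grad = layer.backward(grad)
        return grad

    def features(self, x, batch_size=1024):
        """Activations after the flatten stage (penultimate, pre-softmax)."""
        flat_idx = max(i for i, l in enumerate(self.children) if isinstance(l, Flatten))
        outs = []
        for lo in range(0, x.shape[0], batch_size):
            xb = x[lo : lo + batch_size]
            for layer in self.children[: flat_idx + 1]:
                xb = layer.forward(xb, training=False)
            outs.append(xb)
        return np.concatenate(outs, axis=0)

    def logits(self, x, batch_size=1024):
        outs = []
        for lo in range(0, x.shape[0], batch_size):
            outs.append(self.forward(x[lo : lo + batch_size], training=False))
        return np.concatenate(outs, axis=0)

    def predict_proba(self, x, batch_size=1024):
        return softmax(self.logits(x, batch_size=batch_size))

    def predict(self, x, batch_size=1024):
        return self.logits(x, batch_size=batch_size).argmax(axis=1)

    def get_weights(self):
        return [
            (lbl, {k: v.copy() for k, v in layer.p.items()},
             {k: v.copy() for k, v in layer.s.items()})
            for lbl, layer in self.walk()
        ]

    def set_weights(self, snapshot):
        for (lbl, p, s), (lbl2, layer) in zip(snapshot, self.walk(), strict=True):
            if lbl != lbl2:
                raise ValueError(f"weight snapshot mismatch: {lbl} vs {lbl2}")
            for k, v in p.items():
                layer.p[k] = v.copy()
            for k, v in s.items():
                layer.s[k] = v.copy()

    def save_arrays(self, path):
        arrays = {}
        for i, (lbl, layer) in enumerate(self.walk()):
            for k, v in layer.p.items():
                arrays[f"{i:03d}|{lbl}|p|{k}"] = v
            for k, v in layer.s.items():
                arrays[f"{i:03d}|{lbl}|s|{k}"] = v
        np.savez(path, **arrays)

    def load_arrays(self, path):
        with np.load(path) as npz:
            layers = list(self.walk())
            for key in npz.files:
                idx, lbl, kind, k = key.split("|")
                lbl2, layer = layers[int(idx)]
                if lbl != lbl2:
                    raise ValueError(f"layer mismatch at {key}: model has {lbl2}")
                target = layer.p if kind == "p" else layer.s
                if target[k].shape != npz[key].shape:
                    raise ValueError(f"shape mismatch at {key}")
                target[k] = npz[key].copy()


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-300)).mean()
    grad = p
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype)


class Adam:
    """Adaptive-moment optimizer over a network's trainable arrays."""

    def __init__(self, net: Network, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for lbl, layer in net.walk():
            for k, arr in layer.p.items():
                self.m[(lbl, k)] = np.zeros_like(arr, dtype=np.float64)
                self.v[(lbl, k)] = np.zeros_like(arr, dtype=np.float64)

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for lbl, layer in self.net.walk():
            for k, arr in layer.p.items():
                grad = layer.g.get(k)
                if grad is None:
                    continue
                m = self.m[(lbl, k)]
                v = self.v[(lbl, k)]
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad * grad
                update = self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                layer.p[k] = (arr - update).astype(arr.dtype)


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of scalar f at x (test utility)."""
    grad = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return grad
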