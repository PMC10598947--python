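"""Neural-network building blocks on top of the autograd engine.

Layout convention: channels-first, ``(N, C, *spatial)`` with 2-D spatial axes
``(H, W)`` for slice networks and 3-D ``(H, W, D)`` for volumetric ones.
All convolutions are stride 1 with odd kernels and "same" zero padding;
spatial resolution changes only through pooling and upsampling.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, unfold

__all__ = [
    "Module",
    "Conv",
    "Dense",
    "BatchNorm",
    "max_pool",
    "max_unpool",
    "upsample_nearest",
    "global_avg_pool",
    "softmax",
]


class Module:
    """Minimal parameter container with recursive traversal."""

    def __init__(self):
        self.training = True

    def parameters(self):
        seen = set()
        for obj in self.__dict__.values():
            yield from _collect_params(obj, seen)

    def set_training(self, flag: bool):
        self.training = flag
        for obj in self.__dict__.values():
            for m in _collect_modules(obj):
                m.training = flag
        return self

    def state_arrays(self) -> dict:
        """Flat name -> ndarray mapping of all parameters and buffers."""
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"param_{i}"] = p.data
        for j, b in enumerate(self._buffers()):
            out[f"buffer_{j}"] = b[1]
        return out

    def load_state_arrays(self, arrays: dict):
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(arrays[f"param_{i}"], dtype=np.float64)
        for j, (setter, _) in enumerate(self._buffers()):
            setter(np.asarray(arrays[f"buffer_{j}"], dtype=np.float64))

    def _buffers(self):
        """(setter, array) pairs for non-trainable state (batch-norm stats)."""
        pairs = []
        for obj in self.__dict__.values():
            for m in _collect_modules(obj):
                if isinstance(m, BatchNorm):
                    pairs.append((lambda a, m=m: setattr(m, "running_mean", a), m.running_mean))
                    pairs.append((lambda a, m=m: setattr(m, "running_var", a), m.running_var))
        if isinstance(self, BatchNorm):
            pairs.append((lambda a: setattr(self, "running_mean", a), self.running_mean))
            pairs.append((lambda a: setattr(self, "running_var", a), self.running_var))
        return pairs


def _collect_params(obj, seen):
    if isinstance(obj, Tensor) and obj.requires_grad and id(obj) not in seen:
        seen.add(id(obj))
        yield obj
    elif isinstance(obj, Module):
        for sub in obj.__dict__.values():
            yield from _collect_params(sub, seen)
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            yield from _collect_params(item, seen)


def _collect_modules(obj):
    if isinstance(obj, Module):
        yield obj
        for sub in obj.__dict__.values():
            yield from _collect_modules(sub)
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            yield from _collect_modules(item)


class Conv(Module):
    """N-dimensional convolution (stride 1, same padding, odd kernel)."""

    def __init__(self, in_channels: int, out_channels: int, kernel=3, ndim: int = 2, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if np.isscalar(kernel):
            kernel = (int(kernel),) * ndim
        self.kernel = tuple(kernel)
        if any(k % 2 == 0 for k in self.kernel):
            raise ValueError("kernel sizes must be odd for same padding")
        self.ndim = ndim
        fan_in = in_channels * int(np.prod(self.kernel))
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_channels, in_channels) + self.kernel),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        pad = [(0, 0), (0, 0)] + [((k - 1) // 2, (k - 1) // 2) for k in self.kernel]
        xp = x.pad(pad)
        cols = unfold(xp, self.kernel)  # (N, *out, C, *k)
        out_spatial = cols.shape[1 : 1 + self.ndim]
        flat = cols.reshape((n * int(np.prod(out_spatial)), c * int(np.prod(self.kernel))))
        w2 = self.weight.reshape((self.weight.shape[0], -1))
        y = flat @ w2.transpose((1, 0)) + self.bias
        y = y.reshape((n,) + tuple(out_spatial) + (self.weight.shape[0],))
        perm = (0, 1 + self.ndim) + tuple(range(1, 1 + self.ndim))
        return y.transpose(perm)


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, scale, size=(in_features, out_features)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm(Module):
    """Batch normalization over the batch + spatial axes.

    At evaluation time (and always when the effective batch statistics are
    degenerate, e.g. batch size 1 with a single voxel) running estimates are
    used, so batch-size-1 training remains usable.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0,) + tuple(range(2, x.ndim))
        cshape = (1, x.shape[1]) + (1,) * (x.ndim - 2)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.reshape(-1)
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.reshape(-1)
            )
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            mu = Tensor(self.running_mean.reshape(cshape))
            var = Tensor(self.running_var.reshape(cshape))
            xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma.reshape(cshape) + self.beta.reshape(cshape)


def max_pool(x: Tensor, factors):
    """Max pooling with per-axis window=stride ``factors`` (1 or 2).

    Returns ``(pooled, state)`` where ``state`` carries the argmax indices
    needed by :func:`max_unpool` (SegNet-style decoders).
    """
    factors = tuple(int(f) for f in factors)
    nd = len(factors)
    shp = x.shape
    for s, f in zip(shp[2:], factors):
        if s % f:
            raise ValueError(f"spatial extent {s} not divisible by pool factor {f}")
    grouped = [shp[0], shp[1]]
    for s, f in zip(shp[2:], factors):
        grouped += [s // f, f]
    perm = [0, 1] + [2 + 2 * i for i in range(nd)] + [3 + 2 * i for i in range(nd)]
    windows = x.data.reshape(grouped).transpose(perm)
    out_spatial = windows.shape[2 : 2 + nd]
    flat = windows.reshape(windows.shape[: 2 + nd] + (-1,))
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    inv_perm = np.argsort(perm)

    def _scatter(g):
        gf = np.zeros(flat.shape, dtype=np.float64)
        np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
        return gf.reshape(windows.shape).transpose(inv_perm).reshape(shp)

    out = Tensor(out_data, parents=(x,), backward=lambda g: (_scatter(g),))
    state = {"idx": idx, "factors": factors, "input_shape": shp, "scatter": _scatter}
    return out, state


def max_unpool(y: Tensor, state) -> Tensor:
    """Place pooled values back at their argmax locations, zeros elsewhere."""
    factors, shp, idx = state["factors"], state["input_shape"], state["idx"]
    nd = len(factors)
    out_data = state["scatter"](y.data)

    def _bw(g):
        grouped = [shp[0], shp[1]]
        for s, f in zip(shp[2:], factors):
            grouped += [s // f, f]
        perm = [0, 1] + [2 + 2 * i for i in range(nd)] + [3 + 2 * i for i in range(nd)]
        windows = g.reshape(grouped).transpose(perm)
        flat = windows.reshape(windows.shape[: 2 + nd] + (-1,))
        return (np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0],)

    return Tensor(out_data, parents=(y,), backward=_bw)


def upsample_nearest(x: Tensor, factors) -> Tensor:
    """Nearest-neighbour upsampling by integer per-axis ``factors``."""
    factors = tuple(int(f) for f in factors)
    out_data = x.data
    for ax, f in enumerate(factors):
        if f > 1:
            out_data = np.repeat(out_data, f, axis=2 + ax)

    def _bw(g):
        for ax, f in enumerate(factors):
            if f > 1:
                s = g.shape
                newshape = s[: 2 + ax] + (s[2 + ax] // f, f) + s[3 + ax :]
                g = g.reshape(newshape).sum(axis=3 + ax)
        return (g,)

    return Tensor(out_data, parents=(x,), backward=_bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, *spatial) -> (N, C)."""
    return x.mean(axis=tuple(range(2, x.ndim)))


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, no grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)
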