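"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small define-by-run engine: every operation returns a new
:class:`Tensor` holding the result and a closure that propagates gradients to
its parents. It supports exactly the primitives the segmentation and
classification networks need (dense/convolutional layers via ``unfold`` +
``matmul``, pooling with stored indices, nearest-neighbour upsampling,
elementwise math with numpy broadcasting, reductions, concatenation and
slicing). Gradients are checked against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "unfold"]


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == tuple(shape):
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the graph reachable from self
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            # retain gradients everywhere: intermediate activations are
            # inspected by Grad-CAM, leaves by the optimizer
            node.grad = g if node.grad is None else node.grad + g
            if node._backward is None or not node._parents:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic -------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(
            self.data + other.data,
            parents=(self, other),
            backward=lambda g: (
                _sum_to_shape(g, self.shape),
                _sum_to_shape(g, other.shape),
            ),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            backward=lambda g: (
                _sum_to_shape(g * other.data, self.shape),
                _sum_to_shape(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return Tensor(
            self.data / other.data,
            parents=(self, other),
            backward=lambda g: (
                _sum_to_shape(g / other.data, self.shape),
                _sum_to_shape(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor(
            self.data**e,
            parents=(self,),
            backward=lambda g: (g * e * self.data ** (e - 1),),
        )

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor(out_data, parents=(self,), backward=lambda g: (g * out_data,))

    def log(self):
        return Tensor(np.log(self.data), parents=(self,), backward=lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor(out_data, parents=(self,), backward=lambda g: (g / (2.0 * out_data),))

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=(self,), backward=lambda g: (g * mask,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(
            out_data, parents=(self,), backward=lambda g: (g * out_data * (1 - out_data),)
        )

    # -- reductions & reshaping ------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            parents=(self,),
        )

        def _bw(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor(
            self.data.reshape(shape),
            parents=(self,),
            backward=lambda g: (g.reshape(self.shape),),
        )

    def transpose(self, axes):
        inverse = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            parents=(self,),
            backward=lambda g: (g.transpose(inverse),),
        )

    def __getitem__(self, index):
        def _bw(g):
            full = np.zeros(self.shape, dtype=np.float64)
            np.add.at(full, index, g)
            return (full,)

        return Tensor(self.data[index], parents=(self,), backward=_bw)

    def pad(self, pad_width):
        """Zero padding; ``pad_width`` as for :func:`numpy.pad`."""
        pw = tuple(tuple(p) for p in pad_width)
        slices = tuple(slice(b, b + s) for (b, _), s in zip(pw, self.shape))
        return Tensor(
            np.pad(self.data, pw),
            parents=(self,),
            backward=lambda g: (g[slices],),
        )

    def matmul(self, other: "Tensor"):
        other = self._coerce(other)
        if self.ndim != 2 or other.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        return Tensor(
            self.data @ other.data,
            parents=(self, other),
            backward=lambda g: (g @ other.data.T, self.data.T @ g),
        )

    __matmul__ = matmul


def concat(tensors, axis: int) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        outs = []
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(start, stop)
            outs.append(g[tuple(idx)])
        return tuple(outs)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=_bw,
    )


def unfold(x: Tensor, kernel: tuple) -> Tensor:
    """Extract sliding windows over the trailing spatial axes.

    ``x`` has shape ``(N, C, *spatial)``; returns shape
    ``(N, *out_spatial, C, *kernel)`` with ``out = spatial - kernel + 1``
    (stride 1). Backward scatter-adds window gradients back onto the input.
    """
    k = tuple(kernel)
    nd = len(k)
    view = np.lib.stride_tricks.sliding_window_view(x.data, k, axis=tuple(range(2, 2 + nd)))
    # view: (N, C, *out_spatial, *kernel) -> (N, *out_spatial, C, *kernel)
    perm = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
    out_data = view.transpose(perm).copy()

    def _bw(g):
        # g: (N, *out_spatial, C, *kernel)
        full = np.zeros(x.shape, dtype=np.float64)
        n, c = x.shape[0], x.shape[1]
        out_spatial = out_data.shape[1 : 1 + nd]
        g = g.reshape((n,) + tuple(out_spatial) + (c,) + k)
        if nd == 2:
            kh, kw = k
            for i in range(kh):
                for j in range(kw):
                    full[:, :, i : i + out_spatial[0], j : j + out_spatial[1]] += g[
                        :, :, :, :, i, j
                    ].transpose(0, 3, 1, 2)
        elif nd == 3:
            kh, kw, kd = k
            for i in range(kh):
                for j in range(kw):
                    for l in range(kd):
                        full[
                            :,
                            :,
                            i : i + out_spatial[0],
                            j : j + out_spatial[1],
                            l : l + out_spatial[2],
                        ] += g[:, :, :, :, :, i, j, l].transpose(0, 4, 1, 2, 3)
        else:  # pragma: no cover - only 2-D/3-D used
            raise ValueError("unfold supports 2-D or 3-D kernels")
        return (full,)

    return Tensor(out_data, parents=(x,), backward=_bw)
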