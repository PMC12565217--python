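"""Minimal reverse-mode automatic differentiation on numpy arrays.

Everything trainable in this package (the filter-parameter generator, the
skip-convolution U-Net used for kernel pretraining, the toy segmenter) is a
small CNN, so a compact tensor autograd with the dozen ops those networks
need is sufficient: broadcasting arithmetic, matmul, reductions, activations,
2-D convolution (via im2col, with stride and groups), reflect/zero padding,
pooling, nearest upsampling and a separable bilinear resize expressed as two
constant linear maps.

All data is float64. Graphs are built eagerly; ``Tensor.backward`` runs a
topological sweep. Operations are deterministic: the same inputs produce
bit-identical outputs and gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "conv2d", "no_grad"]


class _NoGrad:
    """Context manager disabling graph construction (inference mode)."""

    enabled = False

    def __enter__(self):
        self._prev = _NoGrad.enabled
        _NoGrad.enabled = True
        return self

    def __exit__(self, *exc):
        _NoGrad.enabled = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "op")
    __array_priority__ = 100.0

    def __init__(self, data, requires_grad: bool = False, parents=(), op: str = "leaf"):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and not _NoGrad.enabled
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents = parents if self.requires_grad else ()
        self.op = op

    # ----- construction helpers -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, op={self.op}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # ----- graph machinery -------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        # iterative DFS post-order (graphs can be deep after many layers)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # graphs are single-use: drop closures and edges immediately so the
        # step's intermediate buffers are freed without waiting for the
        # cycle collector
        for node in topo:
            if node is not self and node._parents:
                node._backward = None
                node._parents = ()
                node.grad = None

    # ----- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other), "add")
        if out.requires_grad:
            def _bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))
            out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,), "neg")
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other), "mul")
        if out.requires_grad:
            def _bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other), "div")
        if out.requires_grad:
            def _bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(
                        -g * self.data / (other.data ** 2), other.shape))
            out._backward = _bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,), "pow")
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(
                g * exponent * self.data ** (exponent - 1))
        return out

    # ----- elementwise functions ------------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,), "exp")
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,), "log")
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        s = np.sqrt(self.data)
        out = Tensor(s, self.requires_grad, (self,), "sqrt")
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * 0.5 / s)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,), "abs")
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,), "relu")
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,), "sigmoid")
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, self.requires_grad, (self,), "tanh")
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * (1.0 - t * t))
        return out

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad, (self,), "clip")
        if out.requires_grad:
            mask = (self.data >= lo) & (self.data <= hi)
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, self.requires_grad, (self,), "softmax")
        if out.requires_grad:
            def _bwd(g):
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accumulate(s * (g - dot))
            out._backward = _bwd
        return out

    # ----- reductions / reshaping -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,), "sum")
        if out.requires_grad:
            def _bwd(g):
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.shape))
                else:
                    ax = axis if isinstance(axis, tuple) else (axis,)
                    if not keepdims:
                        g = np.expand_dims(g, ax)
                    self._accumulate(np.broadcast_to(g, self.shape))
            out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,), "reshape")
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,), "transpose")
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,), "slice")
        if out.requires_grad:
            def _bwd(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
            out._backward = _bwd
        return out

    def matmul(self, other: "Tensor"):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other), "matmul")
        if out.requires_grad:
            def _bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(
                        g @ np.swapaxes(other.data, -1, -2), self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(
                        np.swapaxes(self.data, -1, -2) @ g, other.shape))
            out._backward = _bwd
        return out

    __matmul__ = matmul

    # ----- spatial ops (NCHW) ---------------------------------------------
    def pad2d(self, pad: int, mode: str = "reflect"):
        """Pad the two trailing axes by ``pad`` on each side."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        if mode == "zero":
            padded = np.pad(self.data, width)
        else:
            padded = np.pad(self.data, width, mode=mode)
        out = Tensor(padded, self.requires_grad, (self,), f"pad-{mode}")
        if out.requires_grad:
            h, w = self.shape[-2:]
            if mode == "zero":
                sl = (Ellipsis, slice(pad, pad + h), slice(pad, pad + w))
                out._backward = lambda g: self._accumulate(g[sl])
            else:
                idx = np.pad(np.arange(h * w).reshape(h, w),
                             [(pad, pad), (pad, pad)], mode=mode).ravel()

                def _bwd(g):
                    lead = g.shape[:-2]
                    flat = g.reshape(*lead, -1)
                    acc = np.zeros(lead + (h * w,))
                    np.add.at(acc, (Ellipsis, idx), flat)
                    self._accumulate(acc.reshape(self.shape))
                out._backward = _bwd
        return out

    def avg_pool2d(self, k: int = 2):
        n, c, h, w = self.shape
        hh, ww = h // k, w // k
        view = self.data[:, :, : hh * k, : ww * k].reshape(n, c, hh, k, ww, k)
        out = Tensor(view.mean(axis=(3, 5)), self.requires_grad, (self,), "avgpool")
        if out.requires_grad:
            def _bwd(g):
                full = np.zeros_like(self.data)
                full[:, :, : hh * k, : ww * k] = np.repeat(
                    np.repeat(g, k, axis=2), k, axis=3) / (k * k)
                self._accumulate(full)
            out._backward = _bwd
        return out

    def global_avg_pool2d(self):
        return self.mean(axis=(2, 3))

    def upsample_nearest2d(self, scale: int = 2):
        out = Tensor(np.repeat(np.repeat(self.data, scale, axis=-2), scale, axis=-1),
                     self.requires_grad, (self,), "upsample")
        if out.requires_grad:
            n, c, h, w = self.shape

            def _bwd(g):
                self._accumulate(
                    g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5)))
            out._backward = _bwd
        return out

    def resize_bilinear(self, out_h: int, out_w: int):
        """Half-pixel-centered bilinear resize of the two trailing axes.

        Expressed as two constant interpolation matrices so the op is linear
        (and exactly differentiable) in the input.
        """
        h, w = self.shape[-2:]
        A = _bilinear_matrix(h, out_h)
        B = _bilinear_matrix(w, out_w)
        y = np.einsum("ij,...jk,lk->...il", A, self.data, B, optimize=True)
        out = Tensor(y, self.requires_grad, (self,), "resize")
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(
                np.einsum("ji,...jk,kl->...il", A, g, B, optimize=True))
        return out


def _bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic matrix mapping a length-n_in axis to n_out samples."""
    A = np.zeros((n_out, n_in))
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    scale = n_in / n_out
    # half-pixel centers, clamped to the valid range (align_corners=False)
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    A[np.arange(n_out), lo] += 1.0 - frac
    A[np.arange(n_out), hi] += frac
    return A


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 req, tuple(tensors), "concat")
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = _bwd
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 req, tuple(tensors), "stack")
    if out.requires_grad:
        def _bwd(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accumulate(np.take(g, i, axis=axis))
        out._backward = _bwd
    return out


# --------------------------------------------------------------------------
# convolution
# --------------------------------------------------------------------------

def depthwise_conv2d(x: Tensor, weight: Tensor, *, pad_mode: str = "reflect") -> Tensor:
    """Per-channel 2-D convolution of an (N, C, H, W) batch.

    ``weight`` is (kh, kw) shared by every channel, (C, kh, kw) per channel,
    or (N, C, kh, kw) per sample and channel. Same-size output via the given
    padding mode; stride 1. One vectorized einsum instead of per-group calls.
    """
    x = as_tensor(x)
    weight = as_tensor(weight)
    if x.ndim != 4:
        raise ValueError("depthwise_conv2d expects (N, C, H, W)")
    kh, kw = weight.shape[-2:]
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel sizes must be odd")
    if kh != kw:
        raise ValueError("only square kernels supported")
    n, c, h, w = x.shape
    xp = x.pad2d(kh // 2, mode=pad_mode)
    win = np.lib.stride_tricks.sliding_window_view(xp.data, (kh, kw), axis=(2, 3))
    wk = _dw_broadcast(weight.data, n, c, kh, kw)     # (n, c, kh, kw) view
    y = np.einsum("nchwij,ncij->nchw", win, wk, optimize=True)
    req = x.requires_grad or weight.requires_grad
    out = Tensor(y, req, (x, weight), "dwconv")
    if out.requires_grad:
        def _bwd(g):
            if weight.requires_grad:
                gw = np.einsum("nchwij,nchw->ncij",
                               np.lib.stride_tricks.sliding_window_view(
                                   xp.data, (kh, kw), axis=(2, 3)),
                               g, optimize=True)
                weight._accumulate(_unbroadcast(gw, weight.shape))
            if xp.requires_grad:
                # d/dx_pad is the full correlation of g with the flipped kernel
                gpad = np.pad(g, [(0, 0), (0, 0), (kh - 1, kh - 1),
                                  (kw - 1, kw - 1)])
                gwin = np.lib.stride_tricks.sliding_window_view(
                    gpad, (kh, kw), axis=(2, 3))
                gxp = np.einsum("nchwij,ncij->nchw", gwin,
                                wk[:, :, ::-1, ::-1], optimize=True)
                xp._accumulate(gxp)
        out._backward = _bwd
        # the pad node (not the raw input) must join the topo sweep
        out._parents = (xp, weight)
    return out


def _dw_broadcast(wdata: np.ndarray, n: int, c: int, kh: int, kw: int) -> np.ndarray:
    if wdata.ndim == 2:
        return np.broadcast_to(wdata, (n, c, kh, kw))
    if wdata.ndim == 3:
        return np.broadcast_to(wdata[None], (n, c, kh, kw))
    if wdata.ndim == 4:
        return wdata
    raise ValueError(f"unsupported depthwise weight shape {wdata.shape}")

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    """(N, C, H, W) -> (N, out_h, out_w, C*kh*kw) patch matrix."""
    n, c, h, w = x.shape
    out_h = (h - kh) // stride + 1
    out_w = (w - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]      # N,C,oh,ow,kh,kw
    col = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, out_h, out_w, c * kh * kw)
    return np.ascontiguousarray(col), out_h, out_w


def _col2im(col: np.ndarray, x_shape, kh: int, kw: int, stride: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patches back onto the input grid."""
    n, c, h, w = x_shape
    _, out_h, out_w, _ = col.shape
    col = col.reshape(n, out_h, out_w, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    x = np.zeros(x_shape)
    for i in range(kh):
        hi = i + stride * out_h
        for j in range(kw):
            wj = j + stride * out_w
            x[:, :, i:hi:stride, j:wj:stride] += col[:, :, :, :, i, j]
    return x


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, pad_mode: str = "zero",
           groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW input, OIHW weight."""
    x = as_tensor(x)
    weight = as_tensor(weight)
    if padding:
        x = x.pad2d(padding, mode=pad_mode)
    if groups == 1:
        return _conv2d_g1(x, weight, bias, stride)
    cin = x.shape[1] // groups
    cout = weight.shape[0] // groups
    pieces = []
    for g in range(groups):
        xg = x[:, g * cin:(g + 1) * cin]
        wg = weight[g * cout:(g + 1) * cout]
        bg = bias[g * cout:(g + 1) * cout] if bias is not None else None
        pieces.append(_conv2d_g1(xg, wg, bg, stride))
    return concat(pieces, axis=1)


def _conv2d_g1(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int) -> Tensor:
    n, c, h, w = x.shape
    o, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight expects {ci}")
    col, out_h, out_w = _im2col(x.data, kh, kw, stride)
    wmat = weight.data.reshape(o, -1)
    y = col.reshape(-1, c * kh * kw) @ wmat.T
    y = y.reshape(n, out_h, out_w, o).transpose(0, 3, 1, 2)
    if bias is not None:
        y = y + bias.data.reshape(1, -1, 1, 1)
    req = x.requires_grad or weight.requires_grad or (
        bias is not None and bias.requires_grad)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, req, parents, "conv2d")
    if out.requires_grad:
        col_for_w = col if weight.requires_grad else None

        def _bwd(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(-1, o)
            if weight.requires_grad:
                gw = gmat.T @ col_for_w.reshape(-1, c * kh * kw)
                weight._accumulate(gw.reshape(weight.shape))
            if x.requires_grad:
                gcol = (gmat @ wmat).reshape(n, out_h, out_w, c * kh * kw)
                x._accumulate(_col2im(gcol, x.shape, kh, kw, stride))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
        out._backward = _bwd
    return out
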