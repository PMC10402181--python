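"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine powering the trainable unrolled reconstructor:
tensors wrap real or complex ndarrays, operations record closures computing
vector-Jacobian products, and :func:`backward` accumulates gradients of a real
scalar loss by reverse topological traversal.

Complex convention: every complex tensor is treated as a pair of real arrays.
For a real loss L, the stored gradient of a complex tensor z is

    z.grad = dL/dRe(z) + 1j * dL/dIm(z),

i.e. the adjoint with respect to the real inner product Re<a, b>.  Under this
convention the unitary FFT back-propagates through its inverse, and
multiplication by a constant c back-propagates through conj(c).

Only the operations the reconstruction graph needs are provided; each op's
vjp is unit-tested against central finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "backward"]


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "parents", "vjps", "requires_grad", "_id")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.parents: tuple = ()
        self.vjps: tuple = ()
        self.requires_grad = bool(requires_grad)

    @property
    def shape(self):
        return self.data.shape

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, vjps) -> Tensor:
    out = Tensor(data)
    tracked = [(p, v) for p, v in zip(parents, vjps) if p.requires_grad or p.parents]
    if tracked:
        out.parents = tuple(p for p, _ in tracked)
        out.vjps = tuple(v for _, v in tracked)
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient down to the shape of a broadcast operand."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _to_dtype_of(g: np.ndarray, t: Tensor) -> np.ndarray:
    """Project a gradient onto the tangent space of t (real tensors take the
    real part; complex tensors keep both components)."""
    if not t.is_complex and np.iscomplexobj(g):
        return g.real
    return g


def backward(loss: Tensor) -> None:
    """Accumulate gradients of a real scalar ``loss`` into .grad fields."""
    if loss.data.size != 1 or np.iscomplexobj(loss.data):
        raise ValueError("backward() needs a real scalar loss")
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(loss, False)]
    while stack:  # iterative DFS: graphs can exceed the recursion limit
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node.grad is None or not node.parents:
            continue
        g = node.grad
        for parent, vjp in zip(node.parents, node.vjps):
            _accum(parent, _to_dtype_of(vjp(g), parent))


# ---------------------------------------------------------------------------
# arithmetic


def add(a, b) -> Tensor:
    a, b = _lift(a), _lift(b)
    return _node(
        a.data + b.data,
        (a, b),
        (
            lambda g: _unbroadcast(g, a.shape),
            lambda g: _unbroadcast(g, b.shape),
        ),
    )


def sub(a, b) -> Tensor:
    a, b = _lift(a), _lift(b)
    return _node(
        a.data - b.data,
        (a, b),
        (
            lambda g: _unbroadcast(g, a.shape),
            lambda g: _unbroadcast(-g, b.shape),
        ),
    )


def neg(a) -> Tensor:
    a = _lift(a)
    return _node(-a.data, (a,), (lambda g: -g,))


def mul(a, b) -> Tensor:
    """Elementwise product with broadcasting; complex factors back-propagate
    through the conjugate (real-inner-product adjoint)."""
    a, b = _lift(a), _lift(b)
    return _node(
        a.data * b.data,
        (a, b),
        (
            lambda g: _unbroadcast(g * np.conj(b.data), a.shape),
            lambda g: _unbroadcast(g * np.conj(a.data), b.shape),
        ),
    )


def div(a, b) -> Tensor:
    a, b = _lift(a), _lift(b)
    out = a.data / b.data
    return _node(
        out,
        (a, b),
        (
            lambda g: _unbroadcast(g * np.conj(1.0 / b.data), a.shape),
            lambda g: _unbroadcast(g * np.conj(-out / b.data), b.shape),
        ),
    )


def exp(a) -> Tensor:
    a = _lift(a)
    out = np.exp(a.data)
    return _node(out, (a,), (lambda g: g * np.conj(out),))


def sigmoid(a) -> Tensor:
    a = _lift(a)
    out = 1.0 / (1.0 + np.exp(-a.data))
    return _node(out, (a,), (lambda g: g * out * (1.0 - out),))


def relu(a) -> Tensor:
    a = _lift(a)
    m = a.data > 0
    return _node(a.data * m, (a,), (lambda g: g * m,))


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp; gradient passes only where the input is inside [lo, hi]."""
    a = _lift(a)
    inside = (a.data >= lo) & (a.data <= hi)
    return _node(np.clip(a.data, lo, hi), (a,), (lambda g: g * inside,))


def soft_shrink(y, beta) -> Tensor:
    """Elementwise soft threshold sign(y) * max(|y| - beta, 0).

    ``beta`` may be a learnable non-negative scalar tensor; its gradient is
    -sum(sign(y)) over the surviving entries.
    """
    y, beta = _lift(y), _lift(beta)
    b = float(beta.data)
    if b < 0:
        raise ValueError("soft threshold requires beta >= 0")
    s = np.sign(y.data)
    mag = np.abs(y.data) - b
    keep = mag > 0
    out = s * mag * keep
    return _node(
        out,
        (y, beta),
        (
            lambda g: g * keep,
            lambda g: np.asarray(-(g * s * keep).sum()).reshape(beta.shape),
        ),
    )


# ---------------------------------------------------------------------------
# complex structure


def conj(a) -> Tensor:
    a = _lift(a)
    return _node(np.conj(a.data), (a,), (lambda g: np.conj(g),))


def real(a) -> Tensor:
    a = _lift(a)
    return _node(a.data.real.copy(), (a,), (lambda g: g.astype(np.complex128),))


def imag(a) -> Tensor:
    a = _lift(a)
    return _node(a.data.imag.copy(), (a,), (lambda g: 1j * g,))


def to_complex(re, im) -> Tensor:
    re, im = _lift(re), _lift(im)
    return _node(
        re.data + 1j * im.data,
        (re, im),
        (lambda g: g.real, lambda g: g.imag),
    )


# ---------------------------------------------------------------------------
# Fourier transforms (unitary, centered, over the first two axes)

_AXES = (0, 1)


def fft2c(a) -> Tensor:
    a = _lift(a)
    out = np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(a.data, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )
    return _node(out, (a,), (lambda g: _ifft2c_arr(g),))


def ifft2c(a) -> Tensor:
    a = _lift(a)
    return _node(_ifft2c_arr(a.data), (a,), (lambda g: _fft2c_arr(g),))


def _fft2c_arr(x):
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


def _ifft2c_arr(x):
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


# ---------------------------------------------------------------------------
# shape manipulation and reductions


def reshape(a, shape) -> Tensor:
    a = _lift(a)
    old = a.shape
    return _node(a.data.reshape(shape), (a,), (lambda g: g.reshape(old),))


def transpose(a, axes) -> Tensor:
    a = _lift(a)
    inv = tuple(np.argsort(axes))
    return _node(np.transpose(a.data, axes), (a,), (lambda g: np.transpose(g, inv),))


def sum_axis(a, axis, keepdims: bool = False) -> Tensor:
    a = _lift(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, a.shape)

    return _node(out, (a,), (vjp,))


def concat(parts, axis: int) -> Tensor:
    parts = [_lift(p) for p in parts]
    sizes = [p.shape[axis] for p in parts]
    offs = np.cumsum([0] + sizes)
    out = np.concatenate([p.data for p in parts], axis=axis)

    def make_vjp(i):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offs[i]), int(offs[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return _node(out, tuple(parts), tuple(make_vjp(i) for i in range(len(parts))))


def take(a, index, axis: int) -> Tensor:
    """Slice one index along an axis (keeping the axis collapsed)."""
    a = _lift(a)
    sl = [slice(None)] * a.data.ndim
    sl[axis] = index
    sl = tuple(sl)

    def vjp(g):
        out = np.zeros(a.shape, dtype=g.dtype if a.is_complex else np.float64)
        out[sl] = g
        return out

    return _node(a.data[sl].copy(), (a,), (vjp,))


def sqnorm(a) -> Tensor:
    """Sum of squared magnitudes -> real scalar tensor."""
    a = _lift(a)
    out = np.asarray(np.sum(np.abs(a.data) ** 2))
    return _node(out, (a,), (lambda g: 2.0 * g * a.data,))


def scale(a, s: float) -> Tensor:
    a = _lift(a)
    return _node(a.data * s, (a,), (lambda g: g * s,))


# ---------------------------------------------------------------------------
# 2D convolution (stride 1, same zero padding), NCHW layout


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """[B,C,H,W] -> patches [B,H,W,C*kh*kw] with zero 'same' padding."""
    b, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, c, h, w, kh, kw),
        strides=(s[0], s[1], s[2], s[3], s[2], s[3]),
        writeable=False,
    )
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(b, h, w, c * kh * kw)


def _col2im(cols: np.ndarray, c: int, h: int, w: int, kh: int, kw: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    b = cols.shape[0]
    ph, pw = kh // 2, kw // 2
    xp = np.zeros((b, c, h + 2 * ph, w + 2 * pw), dtype=cols.dtype)
    cols = cols.reshape(b, h, w, c, kh, kw)
    for di in range(kh):
        for dj in range(kw):
            xp[:, :, di : di + h, dj : dj + w] += cols[:, :, :, :, di, dj].transpose(
                0, 3, 1, 2
            )
    return xp[:, :, ph : ph + h, pw : pw + w]


def conv2d(x, weight, bias) -> Tensor:
    """2D correlation: x [B,Cin,H,W], weight [Cout,Cin,kh,kw], bias [Cout]."""
    x, weight, bias = _lift(x), _lift(weight), _lift(bias)
    b, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    cols = _im2col(x.data, kh, kw)  # [B,H,W,Cin*kh*kw]
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out = cols @ wmat.T + bias.data  # [B,H,W,Cout]
    out = out.transpose(0, 3, 1, 2)

    def vjp_x(g):
        gmat = g.transpose(0, 2, 3, 1)  # [B,H,W,Cout]
        dcols = gmat @ wmat  # [B,H,W,Cin*kh*kw]
        return _col2im(dcols, cin, h, w, kh, kw)

    def vjp_w(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, cout)
        dw = gmat.T @ cols.reshape(-1, cin * kh * kw)
        return dw.reshape(cout, cin, kh, kw)

    def vjp_b(g):
        return g.sum(axis=(0, 2, 3))

    return _node(out, (x, weight, bias), (vjp_x, vjp_w, vjp_b))
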