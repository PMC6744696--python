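"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical engine behind the fully convolutional regression
network.  It implements exactly the operations the architecture needs —
2-D convolution (stride 1 or 2), transposed convolution with kernel size
equal to its stride, batch normalization, ELU, dropout, channel
concatenation, bottom/right zero padding and the elementwise arithmetic
used by the training objective — each with a hand-written vector-Jacobian
product.  Convolutions are lowered to GEMM via im2col so the heavy lifting
runs in BLAS.

Arrays follow the NCHW layout (batch, channels, height, width).  The
engine is dtype-agnostic: the network runs in float32, while gradient
oracles in the test-suite run the same code in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "backward"]


class Tensor:
    """A node in the computation tape.

    Holds the forward value, the accumulated gradient, and the closures
    that propagate an output gradient to each parent.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._vjps: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


class Parameter(Tensor):
    """A leaf tensor holding learnable weights."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _result(data, parents_and_vjps):
    """Build an op output, keeping only differentiable parents on the tape."""
    kept = [(p, f) for p, f in parents_and_vjps if p.requires_grad]
    out = Tensor(data, requires_grad=bool(kept))
    if kept:
        out._parents = tuple(p for p, _ in kept)
        out._vjps = tuple(f for _, f in kept)
    return out


def backward(root: Tensor, seed_grad=None) -> None:
    """Backpropagate from ``root``, accumulating ``.grad`` on every
    reachable tensor with ``requires_grad``."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    if seed_grad is None:
        seed_grad = np.ones_like(root.data)
    root.grad = np.asarray(seed_grad, dtype=root.data.dtype)
    for node in reversed(topo):
        g = node.grad
        if g is None:
            continue
        for parent, vjp in zip(node._parents, node._vjps):
            contrib = vjp(g)
            if parent.grad is None:
                parent.grad = contrib
            else:
                parent.grad = parent.grad + contrib


def zero_grads(tensors) -> None:
    for t in tensors:
        t.grad = None


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return _result(a.data + b.data, [(a, lambda g: g), (b, lambda g: g)])


def sub_const(a: Tensor, c) -> Tensor:
    return _result(a.data - c, [(a, lambda g: g)])


def mul(a: Tensor, b: Tensor) -> Tensor:
    da, db = a.data, b.data
    return _result(da * db, [(a, lambda g: g * db), (b, lambda g: g * da)])


def mul_const(a: Tensor, c) -> Tensor:
    return _result(a.data * c, [(a, lambda g: g * c)])


def sum_all(a: Tensor) -> Tensor:
    shape, dtype = a.data.shape, a.data.dtype
    return _result(
        a.data.sum(), [(a, lambda g: np.broadcast_to(g, shape).astype(dtype, copy=False))]
    )


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    return _result(s, [(a, lambda g: g * s * (1.0 - s))])


def elu(a: Tensor, alpha: float = 1.0) -> Tensor:
    x = a.data
    neg = x <= 0
    out = np.where(neg, alpha * np.expm1(x), x)

    def vjp(g):
        return g * np.where(neg, out + alpha, 1.0)

    return _result(out, [(a, vjp)])


def dropout(a: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; the mask is drawn from ``rng`` so that training is
    reproducible under a fixed seed."""
    if rate <= 0.0:
        return a
    keep = (rng.random(a.data.shape) >= rate).astype(a.data.dtype)
    scale = 1.0 / (1.0 - rate)
    m = keep * scale
    return _result(a.data * m, [(a, lambda g: g * m)])


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)
    return _result(
        out, [(a, lambda g: g[:, :ca]), (b, lambda g: g[:, ca:])]
    )


def pad_bottom_right(a: Tensor, dh: int, dw: int) -> Tensor:
    """Zero-pad the spatial dims on the bottom/right edges only (the repo-wide
    convention for matching upsampled maps to their skip connections)."""
    if dh == 0 and dw == 0:
        return a
    h, w = a.data.shape[2], a.data.shape[3]
    out = np.pad(a.data, ((0, 0), (0, 0), (0, dh), (0, dw)))
    return _result(out, [(a, lambda g: g[:, :, :h, :w])])


def crop_bottom_right(a: Tensor, h: int, w: int) -> Tensor:
    if a.data.shape[2] == h and a.data.shape[3] == w:
        return a
    H, W = a.data.shape[2], a.data.shape[3]

    def vjp(g):
        out = np.zeros(a.data.shape, dtype=g.dtype)
        out[:, :, :h, :w] = g
        return out

    return _result(np.ascontiguousarray(a.data[:, :, :h, :w]), [(a, vjp)])


# ---------------------------------------------------------------------------
# convolution via im2col / col2im
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - kh) // stride + 1
    wo = (x.shape[3] - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, ho, wo, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, n, c, h, w, kh, kw, stride, pad, ho, wo):
    hp, wp = h + 2 * pad, w + 2 * pad
    dx = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    blocks = cols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += blocks[
                :, :, :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad : pad + h, pad : pad + w]
    return dx


def conv2d(x: Tensor, weight: Parameter, bias: Parameter, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution, NCHW; weight is (out_ch, in_ch, kh, kw)."""
    n, c, h, w = x.data.shape
    co, ci, kh, kw = weight.data.shape
    assert ci == c, f"channel mismatch: input {c}, weight {ci}"
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(co, ci * kh * kw)
    out = cols @ wmat.T
    if bias is not None:
        out += bias.data
    out = out.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)

    def vjp_x(g):
        gf = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
        dcols = gf @ wmat
        return _col2im(dcols, n, c, h, w, kh, kw, stride, pad, ho, wo)

    def vjp_w(g):
        gf = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
        return (gf.T @ cols).reshape(co, ci, kh, kw)

    parents = [(x, vjp_x), (weight, vjp_w)]
    if bias is not None:
        parents.append((bias, lambda g: g.sum(axis=(0, 2, 3))))
    return _result(np.ascontiguousarray(out), parents)


def conv_transpose2d(x: Tensor, weight: Parameter, bias: Parameter, stride: int) -> Tensor:
    """Transposed convolution with kernel size equal to the stride.

    With non-overlapping kernels this is an exact block expansion: each input
    pixel paints an s-by-s patch of the output, so the whole op is a single
    tensordot.  Weight is (in_ch, out_ch, s, s); spatial size goes H -> H*s.
    """
    n, c, h, w = x.data.shape
    ci, co, s, s2 = weight.data.shape
    assert ci == c and s == s2 == stride
    # (n, h, w, co, s, s) -> (n, co, h, s, w, s) -> (n, co, h*s, w*s)
    out = np.tensordot(x.data, weight.data, axes=([1], [0]))
    out = out.transpose(0, 3, 1, 4, 2, 5).reshape(n, co, h * s, w * s)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    def _blocks(g):
        return g.reshape(n, co, h, s, w, s).transpose(0, 2, 4, 1, 3, 5)  # n,h,w,co,s,s

    def vjp_x(g):
        return np.tensordot(_blocks(g), weight.data, axes=([3, 4, 5], [1, 2, 3])).transpose(
            0, 3, 1, 2
        )

    def vjp_w(g):
        # sum over batch and spatial positions: (c, co, s, s)
        return np.tensordot(x.data, _blocks(g), axes=([0, 2, 3], [0, 1, 2]))

    parents = [(x, vjp_x), (weight, vjp_w)]
    if bias is not None:
        parents.append((bias, lambda g: g.sum(axis=(0, 2, 3))))
    return _result(np.ascontiguousarray(out), parents)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batch_norm(
    x: Tensor,
    gamma: Parameter,
    beta: Parameter,
    mean: np.ndarray,
    var: np.ndarray,
    eps: float,
    batch_stats: bool,
) -> Tensor:
    """Per-channel normalization.

    ``batch_stats`` selects between normalizing with the statistics of the
    current mini-batch (training) and with the supplied running statistics
    (evaluation, or a frozen block).  The running-statistics branch is a
    plain affine map, so its backward is trivial.
    """
    inv = 1.0 / np.sqrt(var + eps)
    bshape = (1, -1, 1, 1)
    xhat = (x.data - mean.reshape(bshape)) * inv.reshape(bshape)
    out = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)

    if batch_stats:
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def vjp_x(g):
            dgamma = (g * xhat).sum(axis=(0, 2, 3))
            dbeta = g.sum(axis=(0, 2, 3))
            coef = (gamma.data * inv).reshape(bshape)
            return coef * (
                g - dbeta.reshape(bshape) / m - xhat * dgamma.reshape(bshape) / m
            )

    else:

        def vjp_x(g):
            return g * (gamma.data * inv).reshape(bshape)

    return _result(
        out,
        [
            (x, vjp_x),
            (gamma, lambda g: (g * xhat).sum(axis=(0, 2, 3))),
            (beta, lambda g: g.sum(axis=(0, 2, 3))),
        ],
    )
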