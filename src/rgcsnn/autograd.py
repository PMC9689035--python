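"""Reverse-mode automatic differentiation on numpy arrays.

A small tape engine providing exactly the operations the spiking U-net
needs: 'same' convolutions, average / adaptive-average pooling, bilinear
resizing, channel concatenation, elementwise arithmetic, dense layers and
a Heaviside spike nonlinearity whose backward pass is the rectangular
surrogate window.  Forward spike emission is hard (binary); the backward
substitutes ``1/a1`` on ``|u - v_th| < a1/2`` (straight-through
surrogate).  A ``relaxed`` mode replaces the step by its integrated
piecewise-linear ramp, for which the rectangle is the exact derivative —
used for finite-difference gradient verification.

Convolutions lower to im2col + BLAS matmul, chunked over the batch axis
to bound transient memory; their backward recomputes the column buffer
rather than storing it.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "tensor", "parameter", "add", "sub", "mul", "scale",
    "conv2d", "linear", "avg_pool2d", "adaptive_avg_pool2d",
    "bilinear_resize", "concat", "spike", "take_step", "stack_steps",
    "sum_steps", "softmax_cross_entropy", "backward",
]

# Default compute dtype.  float32 keeps the convolution GEMMs fast; the
# finite-difference gradient checks switch to float64 via set_dtype().
_DTYPE = np.float32


def set_dtype(dtype):
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


def get_dtype():
    return _DTYPE


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward_fn

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        if isinstance(other, Tensor):
            return mul(self, other)
        return scale(self, float(other))

    __rmul__ = __mul__

    def backward(self):
        backward(self)


def tensor(data):
    return Tensor(data)


def parameter(data):
    return Tensor(data, requires_grad=True)


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(np.broadcast_to(g, t.data.shape), dtype=t.data.dtype)
    else:
        t.grad += g


def backward(loss: Tensor):
    """Backpropagate from a scalar loss through the tape."""
    if loss.data.size != 1:
        raise ValueError("backward() requires a scalar loss")
    topo, seen = [], set()
    stack = [(loss, False)]
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
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward_fn=bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward_fn=bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data
    ad, bd = a.data, b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * bd, ad.shape))
        _accum(b, _unbroadcast(g * ad, bd.shape))

    return Tensor(out_data, parents=(a, b), backward_fn=bwd)


def scale(a: Tensor, c: float) -> Tensor:
    def bwd(g):
        _accum(a, g * c)

    return Tensor(a.data * c, parents=(a,), backward_fn=bwd)


# ---------------------------------------------------------------------------
# convolution


def _flatten_batch(x: np.ndarray):
    """[..., C, H, W] -> ([N, C, H, W], leading shape)."""
    lead = x.shape[:-3]
    return x.reshape((-1,) + x.shape[-3:]), lead


def _pad_flat_cl(x: np.ndarray, p: int):
    """[N, C, H, W] -> zero-padded channels-last flat buffer [N, Hp*Wp, C]."""
    N, C, H, W = x.shape
    Hp, Wp = H + 2 * p, W + 2 * p
    xp = np.zeros((N, Hp, Wp, C), dtype=x.dtype)
    xp[:, p:p + H, p:p + W, :] = x.transpose(0, 2, 3, 1)
    return xp.reshape(N, Hp * Wp, C), Wp


def _conv_same(x: np.ndarray, w: np.ndarray, cache: dict | None = None) -> np.ndarray:
    """Stride-1 'same' cross-correlation, x [N,C,H,W], w [O,C,k,k] -> [N,O,H,W].

    The convolution is lowered to k*k GEMMs over contiguous slices of a
    flattened padded buffer; entries belonging to pad columns are computed
    but discarded by a strided view (no im2col column matrix is built).
    """
    N, C, H, W = x.shape
    O, _, k, _ = w.shape
    p = k // 2
    if cache is not None and "xf" in cache:
        xf, Wp = cache["xf"], cache["Wp"]
    else:
        xf, Wp = _pad_flat_cl(x, p)
        if cache is not None:
            cache["xf"], cache["Wp"] = xf, Wp
    wmats = np.ascontiguousarray(w.transpose(2, 3, 1, 0)).reshape(k * k, C, O)
    L = (H - 1) * Wp + W
    acc = np.zeros((N, L, O), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            off = di * Wp + dj
            acc += xf[:, off:off + L, :] @ wmats[di * k + dj]
    s = acc.strides
    view = np.lib.stride_tricks.as_strided(
        acc, shape=(N, H, W, O), strides=(s[0], Wp * s[1], s[1], s[2]))
    return np.ascontiguousarray(view.transpose(0, 3, 1, 2))


def _conv_wgrad(xf: np.ndarray, Wp: int, gout: np.ndarray, k: int,
                H: int, W: int) -> np.ndarray:
    """Weight gradient for _conv_same from its cached pad buffer."""
    N = gout.shape[0]
    O = gout.shape[1]
    C = xf.shape[-1]
    L = (H - 1) * Wp + W
    idx = (np.arange(H)[:, None] * Wp + np.arange(W)).ravel()
    gbuf = np.zeros((N, L, O), dtype=gout.dtype)
    gbuf[:, idx, :] = gout.transpose(0, 2, 3, 1).reshape(N, H * W, O)
    gw = np.empty((k * k, C, O), dtype=xf.dtype)
    for di in range(k):
        for dj in range(k):
            off = di * Wp + dj
            gw[di * k + dj] = np.tensordot(
                xf[:, off:off + L, :], gbuf, axes=([0, 1], [0, 1]))
    return gw.reshape(k, k, C, O).transpose(3, 2, 0, 1)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same' convolution. x [..., C, H, W], w [O, C, k, k], b [O]."""
    xb, lead = _flatten_batch(x.data)
    cache: dict = {}
    out = _conv_same(xb, w.data, cache)
    if b is not None:
        out += b.data[None, :, None, None]
    O = w.data.shape[0]
    k = w.data.shape[2]
    H, W = xb.shape[-2:]
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gf = np.ascontiguousarray(g.reshape((-1, O) + g.shape[-2:]))
        if b is not None:
            _accum(b, gf.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            _accum(w, _conv_wgrad(cache["xf"], cache["Wp"], gf, k, H, W))
        if x.requires_grad:
            # dx = 'same' convolution of gout with the rotated, axis-swapped kernel
            w_rot = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # [C, O, k, k]
            gx = _conv_same(gf, np.ascontiguousarray(w_rot))
            _accum(x, gx.reshape(x.data.shape))
        cache.clear()

    return Tensor(out.reshape(lead + out.shape[1:]), parents=parents, backward_fn=bwd)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Dense layer: x [..., F] @ w [F, O] (+ b [O])."""
    out = x.data @ w.data
    if b is not None:
        out = out + b.data
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if b is not None:
            _accum(b, g.reshape(-1, g.shape[-1]).sum(axis=0))
        xf = x.data.reshape(-1, x.data.shape[-1])
        gf = g.reshape(-1, g.shape[-1])
        _accum(w, xf.T @ gf)
        _accum(x, (g @ w.data.T).reshape(x.data.shape))

    return Tensor(out, parents=parents, backward_fn=bwd)


# ---------------------------------------------------------------------------
# pooling / resizing


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k×k average pooling over the trailing two axes."""
    d = x.data
    H, W = d.shape[-2:]
    if H % k or W % k:
        raise ValueError(f"spatial size {(H, W)} not divisible by pool size {k}")
    shaped = d.reshape(d.shape[:-2] + (H // k, k, W // k, k))
    out = shaped.mean(axis=(-3, -1))

    def bwd(g):
        ge = np.repeat(np.repeat(g, k, axis=-2), k, axis=-1) / (k * k)
        _accum(x, ge)

    return Tensor(out, parents=(x,), backward_fn=bwd)


def _adaptive_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic averaging matrix [n_out, n_in] with floor/ceil bin edges."""
    A = np.zeros((n_out, n_in))
    for i in range(n_out):
        s = (i * n_in) // n_out
        e = -(-((i + 1) * n_in) // n_out)  # ceil
        A[i, s:e] = 1.0 / (e - s)
    return A


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Bilinear interpolation matrix [n_out, n_in], half-pixel-centre convention."""
    A = np.zeros((n_out, n_in))
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    for i in range(n_out):
        A[i, lo[i]] += 1 - frac[i]
        A[i, hi[i]] += frac[i]
    return A


def _apply_sep(x: Tensor, Ah: np.ndarray, Aw: np.ndarray) -> Tensor:
    """y[..., i, j] = sum_hw Ah[i,h] Aw[j,w] x[..., h, w] with exact adjoint."""
    out = np.einsum("...hw,ih,jw->...ij", x.data, Ah, Aw, optimize=True)

    def bwd(g):
        gx = np.einsum("...ij,ih,jw->...hw", g, Ah, Aw, optimize=True)
        _accum(x, gx)

    return Tensor(out, parents=(x,), backward_fn=bwd)


def adaptive_avg_pool2d(x: Tensor, out_size) -> Tensor:
    oh, ow = (out_size, out_size) if np.isscalar(out_size) else out_size
    H, W = x.data.shape[-2:]
    return _apply_sep(x, _adaptive_matrix(H, oh), _adaptive_matrix(W, ow))


def bilinear_resize(x: Tensor, out_size) -> Tensor:
    oh, ow = (out_size, out_size) if np.isscalar(out_size) else out_size
    H, W = x.data.shape[-2:]
    return _apply_sep(x, _interp_matrix(H, oh), _interp_matrix(W, ow))


def concat(tensors, axis: int) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, gpart)

    return Tensor(out, parents=tuple(tensors), backward_fn=bwd)


def lincomb(tensors, coeffs, const: float = 0.0) -> Tensor:
    """Fused elementwise ``sum_i c_i * t_i + const`` (one tape node).

    Used for the membrane recurrence, where chaining separate add/scale
    nodes would dominate the tape overhead.
    """
    out = None
    for t, c in zip(tensors, coeffs):
        term = t.data * c
        out = term if out is None else out + term
    if const != 0.0:
        out = out + const

    def bwd(g):
        for t, c in zip(tensors, coeffs):
            if t.requires_grad:
                _accum(t, g * c if c != 1.0 else g)

    return Tensor(out, parents=tuple(tensors), backward_fn=bwd)


# ---------------------------------------------------------------------------
# spiking nonlinearity


def spike(u: Tensor, v_th: float, a1: float, relaxed: bool = False) -> Tensor:
    """Threshold nonlinearity with rectangular surrogate derivative.

    Forward: hard Heaviside ``1[u > v_th]`` (strict inequality), or, in
    ``relaxed`` mode, the ramp ``clip((u - v_th)/a1 + 1/2, 0, 1)`` whose
    exact derivative is the same rectangle — the diagnostic used for
    numerical gradient checks.
    """
    if relaxed:
        out = np.clip((u.data - v_th) / a1 + 0.5, 0.0, 1.0)
    else:
        out = (u.data > v_th).astype(u.data.dtype)
    window = (np.abs(u.data - v_th) < a1 / 2).astype(u.data.dtype) / a1

    def bwd(g):
        _accum(u, g * window)

    return Tensor(out, parents=(u,), backward_fn=bwd)


# ---------------------------------------------------------------------------
# time-axis helpers (leading axis = simulation step)


def tile_steps(x: Tensor, t_steps: int) -> Tensor:
    """Repeat a static current map at every simulation step (new axis 0)."""
    out = np.broadcast_to(x.data, (t_steps,) + x.data.shape).copy()

    def bwd(g):
        _accum(x, g.sum(axis=0))

    return Tensor(out, parents=(x,), backward_fn=bwd)


def spiking_recurrence(currents: Tensor, *, mode: str = "rgc",
                       leak: float = 0.0, gain: float = 1.0,
                       const: float = 0.0, v_th: float = 0.5,
                       a1: float = 1.0, lif_decay: float = 0.5,
                       relaxed: bool = False) -> Tensor:
    """Unrolled spiking membrane recurrence as a single tape node.

    ``currents``: stacked synaptic input [T, ...].  RGC mode:

        u_t = (1 - leak)*u_{t-1} + gain*I_t + const - v_th*s_{t-1}

    LIF mode:  u_t = lif_decay * u_{t-1} * (1 - s_{t-1}) + I_t

    with s_t = 1[u_t > v_th] (or the piecewise-linear ramp when
    ``relaxed``).  The backward pass is truncated-free BPTT with the
    rectangular surrogate (1/a1 on |u - v_th| < a1/2) as ds/du — the
    exact derivative of the relaxed ramp, substituted straight-through
    for the hard step.
    """
    I = currents.data
    T = I.shape[0]
    a = 1.0 - leak
    us = np.empty_like(I)
    ss = np.empty_like(I)
    u = None
    s_prev = None
    for t in range(T):
        if mode == "lif":
            u = I[t] if u is None else lif_decay * u * (1.0 - s_prev) + I[t]
        else:
            base = gain * I[t] + const
            u = base if u is None else a * u + base - v_th * s_prev
        if relaxed:
            s_prev = np.clip((u - v_th) / a1 + 0.5, 0.0, 1.0)
        else:
            s_prev = (u > v_th).astype(I.dtype)
        us[t] = u
        ss[t] = s_prev

    def bwd(g):
        lam = None  # dL/du_{t+1}
        gI = np.empty_like(I)
        for t in range(T - 1, -1, -1):
            w = (np.abs(us[t] - v_th) < a1 / 2).astype(I.dtype) / a1
            gs = g[t].copy()
            if lam is not None:
                if mode == "lif":
                    gs -= lif_decay * us[t] * lam
                else:
                    gs -= v_th * lam
            new_lam = gs * w
            if lam is not None:
                if mode == "lif":
                    new_lam += lif_decay * (1.0 - ss[t]) * lam
                else:
                    new_lam += a * lam
            lam = new_lam
            gI[t] = lam if mode == "lif" else gain * lam
        _accum(currents, gI)

    return Tensor(ss, parents=(currents,), backward_fn=bwd)


def take_step(x: Tensor, t: int) -> Tensor:
    out = x.data[t]

    def bwd(g):
        if x.grad is None and x.requires_grad:
            x.grad = np.zeros_like(x.data)
        if x.requires_grad:
            x.grad[t] += g

    return Tensor(out, parents=(x,), backward_fn=bwd)


def stack_steps(tensors) -> Tensor:
    out = np.stack([t.data for t in tensors], axis=0)

    def bwd(g):
        for i, t in enumerate(tensors):
            _accum(t, g[i])

    return Tensor(out, parents=tuple(tensors), backward_fn=bwd)


def sum_steps(tensors) -> Tensor:
    """Elementwise sum of per-step tensors (rate accumulation over time)."""
    out = np.zeros_like(tensors[0].data)
    for t in tensors:
        out += t.data

    def bwd(g):
        for t in tensors:
            _accum(t, g)

    return Tensor(out, parents=tuple(tensors), backward_fn=bwd)


def softmax_cross_entropy(logits: Tensor, target: np.ndarray, class_axis: int = -1) -> Tensor:
    """Mean softmax cross-entropy.

    ``logits``: real evidence with a class axis; ``target``: integer class
    indices with the class axis removed.  Returns the scalar mean of
    ``-log p_true`` over every remaining position.
    """
    z = np.moveaxis(logits.data, class_axis, -1)
    target = np.asarray(target)
    if target.shape != z.shape[:-1]:
        raise ValueError(f"target shape {target.shape} does not match logits {z.shape[:-1]}")
    zmax = z.max(axis=-1, keepdims=True)
    ez = np.exp((z - zmax).astype(np.float64))
    p = ez / ez.sum(axis=-1, keepdims=True)
    n = int(np.prod(target.shape)) if target.shape else 1
    onehot = np.eye(z.shape[-1])[target]
    loss = -(onehot * np.log(np.clip(p, 1e-12, None))).sum(axis=-1).mean()

    def bwd(g):
        gz = (p - onehot) * (g / n)
        _accum(logits, np.moveaxis(gz, -1, class_axis))

    return Tensor(np.float64(loss), parents=(logits,), backward_fn=bwd)
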