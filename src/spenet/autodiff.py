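"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine — just the operations the pair transformer needs
(broadcasting arithmetic, batched matmul, softmax, layer norm, dropout,
fused sigmoid-BCE). Gradients are accumulated in float64 throughout; there
is no graph retention across backward calls.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the autodiff graph.

    The array dtype is preserved (integers promote to float64), so a model
    can run in float32 end to end while float64 remains available where
    precision matters (for example finite-difference checks).
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.requires_grad = requires_grad
        self.grad: Optional[Array] = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Optional[Callable[[Array], tuple]] = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph construction helpers ------------------------------------

    @staticmethod
    def _make(data: Array, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------

    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # keep python scalars in this tensor's dtype so float32 graphs
        # are not silently promoted to float64
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __matmul__(self, other):
        other = self._coerce(other)

        def back(g: Array):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor._make(self.data @ other.data, (self, other), back)

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor._make(
            self.data**e, (self,), lambda g: (g * e * self.data ** (e - 1.0),)
        )

    # -- shape ops -------------------------------------------------------

    def reshape(self, *shape):
        orig = self.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def back(g: Array):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ---------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    # -- backprop ----------------------------------------------------------

    def backward(self, grad: Optional[Array] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, Array] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis`."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def back(g: Array):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return (s * (g - dot),)

    return Tensor._make(s, (x,), back)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Fused affine map over the last axis: x @ w + b.

    Collapses all leading axes into one GEMM for both passes — markedly
    faster than broadcasting a batched matmul against a 2-D weight.
    """
    d_in, d_out = w.shape
    lead = x.shape[:-1]
    xf = x.data.reshape(-1, d_in)
    out = xf @ w.data + b.data

    def back(g: Array):
        gf = g.reshape(-1, d_out)
        return (
            (gf @ w.data.T).reshape(x.shape),
            xf.T @ gf,
            gf.sum(axis=0),
        )

    return Tensor._make(out.reshape(*lead, d_out), (x, w, b), back)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with learnable scale/shift.

    Single fused op with the standard analytic backward.
    """
    mu = x.data.mean(axis=-1, keepdims=True)
    centered = x.data - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = centered * inv
    out = xhat * gamma.data + beta.data

    def back(g: Array):
        gh = g * gamma.data
        m1 = gh.mean(axis=-1, keepdims=True)
        m2 = (gh * xhat).mean(axis=-1, keepdims=True)
        dx = (gh - m1 - xhat * m2) * inv
        axes = tuple(range(g.ndim - 1))
        return dx, (g * xhat).sum(axis=axes), g.sum(axis=axes)

    return Tensor._make(out, (x, gamma, beta), back)


def multi_head_attention(
    x_q: Tensor,
    x_kv: Tensor,
    wq: Tensor, bq: Tensor,
    wk: Tensor, bk: Tensor,
    wv: Tensor, bv: Tensor,
    wo: Tensor, bo: Tensor,
    heads: int,
    key_bias: Array,
    drop_mask: Optional[Array] = None,
) -> Tensor:
    """Fused multi-head attention (projections, scaled masked softmax,
    optional attention dropout, output projection) as one tape node.

    key_bias is added to the pre-softmax scores (shape broadcastable to
    (B, 1, 1, n_k); use a large negative value at padded keys). drop_mask,
    if given, multiplies the attention weights (inverted-dropout mask,
    shape (B, heads, n_q, n_k)).
    """
    B, nq, d = x_q.shape
    nk = x_kv.shape[1]
    dh = d // heads
    scale = np.asarray(1.0 / np.sqrt(dh), dtype=x_q.data.dtype)

    xqf = np.ascontiguousarray(x_q.data.reshape(-1, d))
    xkf = np.ascontiguousarray(x_kv.data.reshape(-1, d))

    def split(flat: Array, n: int) -> Array:
        return np.ascontiguousarray(
            flat.reshape(B, n, heads, dh).transpose(0, 2, 1, 3)
        )

    Q = split(xqf @ wq.data + bq.data, nq)
    K = split(xkf @ wk.data + bk.data, nk)
    V = split(xkf @ wv.data + bv.data, nk)

    S = Q @ K.transpose(0, 1, 3, 2) * scale + key_bias
    S -= S.max(axis=-1, keepdims=True)
    np.exp(S, out=S)
    S /= S.sum(axis=-1, keepdims=True)
    A = S  # attention weights (renamed in place)
    Ad = A * drop_mask if drop_mask is not None else A
    ctx = (Ad @ V).transpose(0, 2, 1, 3).reshape(-1, d)
    ctx = np.ascontiguousarray(ctx)
    out = (ctx @ wo.data + bo.data).reshape(B, nq, d)

    ones_q = np.ones((1, B * nq), dtype=out.dtype)
    ones_k = np.ones((1, B * nk), dtype=out.dtype)

    def back(g: Array):
        gf = g.reshape(-1, d)
        g_ctx = (gf @ wo.data.T).reshape(B, nq, heads, dh).transpose(0, 2, 1, 3)
        gWo = ctx.T @ gf
        gbo = (ones_q @ gf)[0]
        gAd = g_ctx @ V.transpose(0, 1, 3, 2)
        gV = Ad.transpose(0, 1, 3, 2) @ g_ctx
        gA = gAd * drop_mask if drop_mask is not None else gAd
        gS = A * (gA - (gA * A).sum(axis=-1, keepdims=True))
        gQ = (gS @ K) * scale
        gK = (gS.transpose(0, 1, 3, 2) @ Q) * scale

        def unsplit(t: Array, n: int) -> Array:
            return np.ascontiguousarray(t.transpose(0, 2, 1, 3).reshape(-1, d))

        gQf, gKf, gVf = unsplit(gQ, nq), unsplit(gK, nk), unsplit(gV, nk)
        g_xq = (gQf @ wq.data.T).reshape(B, nq, d)
        g_xkv = (gKf @ wk.data.T + gVf @ wv.data.T).reshape(B, nk, d)
        return (
            g_xq, g_xkv,
            xqf.T @ gQf, (ones_q @ gQf)[0],
            xkf.T @ gKf, (ones_k @ gKf)[0],
            xkf.T @ gVf, (ones_k @ gVf)[0],
            gWo, gbo,
        )

    return Tensor._make(out, (x_q, x_kv, wq, bq, wk, bk, wv, bv, wo, bo), back)


def feed_forward(x: Tensor, w1: Tensor, b1: Tensor, w2: Tensor, b2: Tensor) -> Tensor:
    """Fused position-wise feed-forward block: relu(x W1 + b1) W2 + b2."""
    lead = x.shape[:-1]
    d_in = x.shape[-1]
    xf = np.ascontiguousarray(x.data.reshape(-1, d_in))
    h = xf @ w1.data + b1.data
    np.maximum(h, 0, out=h)
    out = h @ w2.data + b2.data
    ones = np.ones((1, xf.shape[0]), dtype=out.dtype)

    def back(g: Array):
        gf = g.reshape(-1, w2.shape[1])
        gh = gf @ w2.data.T
        gh *= h > 0
        return (
            (gh @ w1.data.T).reshape(x.shape),
            xf.T @ gh, (ones @ gh)[0],
            h.T @ gf, (ones @ gf)[0],
        )

    return Tensor._make(out.reshape(*lead, w2.shape[1]), (x, w1, b1, w2, b2), back)


def residual_layer_norm(
    x: Tensor, sub: Tensor, gamma: Tensor, beta: Tensor,
    drop_mask: Optional[Array] = None, eps: float = 1e-5,
) -> Tensor:
    """Fused transformer block tail: LayerNorm(x + dropout(sub)).

    Equivalent to dropout + residual add + layer_norm but as a single tape
    node (one backward closure, no intermediate big tensors on the tape).
    """
    sub_d = sub.data * drop_mask if drop_mask is not None else sub.data
    y = x.data + sub_d
    mu = y.mean(axis=-1, keepdims=True)
    centered = y - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = centered * inv
    out = xhat * gamma.data + beta.data

    def back(g: Array):
        gh = g * gamma.data
        m1 = gh.mean(axis=-1, keepdims=True)
        m2 = (gh * xhat).mean(axis=-1, keepdims=True)
        dy = (gh - m1 - xhat * m2) * inv
        axes = tuple(range(g.ndim - 1))
        d_sub = dy * drop_mask if drop_mask is not None else dy
        return dy, d_sub, (g * xhat).sum(axis=axes), g.sum(axis=axes)

    return Tensor._make(out, (x, sub, gamma, beta), back)


def dropout_mask(shape, rate: float, rng: np.random.Generator, dtype) -> Array:
    """Inverted-dropout multiplier mask."""
    keep = 1.0 - rate
    dtype = np.float32 if np.dtype(dtype) == np.float32 else np.float64
    u = rng.random(shape, dtype=dtype)
    mask = (u < keep).astype(dtype)
    mask /= np.asarray(keep, dtype=dtype)
    return mask


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    return x * Tensor(dropout_mask(x.shape, rate, rng, x.data.dtype))


def bce_with_logits(logits: Tensor, labels: Array) -> Tensor:
    """Mean binary cross-entropy on logits (fused, numerically stable).

    loss_i = max(z,0) - z*y + log(1 + exp(-|z|)); gradient is
    (sigmoid(z) - y)/N, implemented analytically.
    """
    y = np.asarray(labels, dtype=np.float64)
    if y.shape != logits.shape:
        raise ValueError(f"labels shape {y.shape} != logits shape {logits.shape}")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary 0/1")
    z = logits.data
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = max(z.size, 1)

    def back(g: Array):
        sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        return (g * (sig - y) / n,)

    return Tensor._make(np.array(per.mean()), (logits,), back)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g: Array):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), back)


class Parameter(Tensor):
    """Trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimiser over a list of Parameters.

    Moments and updates run on one flat buffer (parameter gradients are
    gathered per step), which keeps the per-step cost independent of the
    number of parameter tensors.
    """

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        sizes = [p.data.size for p in self.params]
        self._offsets = np.concatenate([[0], np.cumsum(sizes)])
        n = int(self._offsets[-1])
        dtype = self.params[0].data.dtype if self.params else np.float64
        self.m = np.zeros(n, dtype=dtype)
        self.v = np.zeros(n, dtype=dtype)
        self._g = np.zeros(n, dtype=dtype)
        self._scratch = np.zeros(n, dtype=dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        g, s = self._g, self._scratch
        for i, p in enumerate(self.params):
            lo, hi = self._offsets[i], self._offsets[i + 1]
            if p.grad is None:
                g[lo:hi] = 0.0
            else:
                g[lo:hi] = p.grad.reshape(-1)
        self.m *= self.b1
        self.m += (1.0 - self.b1) * g
        np.square(g, out=g)
        self.v *= self.b2
        self.v += (1.0 - self.b2) * g
        # update = lr_t * m / (sqrt(v) + eps'), bias corrections folded into lr_t
        b2c = np.sqrt(1.0 - self.b2**self.t)
        lr_t = self.lr * b2c / (1.0 - self.b1**self.t)
        np.sqrt(self.v, out=s)
        s += self.eps * b2c
        np.divide(self.m, s, out=s)
        s *= lr_t
        for i, p in enumerate(self.params):
            lo, hi = self._offsets[i], self._offsets[i + 1]
            p.data -= s[lo:hi].reshape(p.data.shape)
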