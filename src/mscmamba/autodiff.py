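"""Minimal reverse-mode automatic differentiation over numpy arrays.

Every trainable component in this package is built from the :class:`Tensor`
primitives below.  The design is deliberately small: a ``Tensor`` wraps a
float64 numpy array, records its parents and a backward closure, and
``backward()`` walks the graph in reverse topological order accumulating
gradients.  Broadcasting follows numpy semantics; gradients of broadcast
operands are reduced back to the operand shape.

The module-level helper functions (:func:`exp`, :func:`sigmoid`,
:func:`silu`, ...) are *generic*: they accept either a ``Tensor`` or a plain
ndarray and return the same kind.  The mathematical layers in the rest of
the package are written against these helpers once and therefore run both
as plain numpy reference code and inside the training graph.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "is_tensor",
    "asdata",
    "exp",
    "log",
    "sqrt",
    "tanh",
    "sigmoid",
    "softplus",
    "silu",
    "phi1",
    "clip",
    "matmul",
    "concatenate",
    "stack",
    "take",
    "sum_",
    "mean_",
    "softmax",
    "causal_conv_op",
    "selective_scan_op",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` (shape of a broadcast result) back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum away extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph: value, gradient, and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    # make numpy defer mixed ndarray/Tensor arithmetic to our operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    # ------------------------------------------------------------------ info
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep: sequential scans)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in visited and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ------------------------------------------------------------- operators
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / other.data**2)

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    # (..., n) @ (n,) -> (...,): g has shape (...)
                    self._accumulate(g[..., None] * other.data)
                else:
                    self._accumulate(
                        _unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                     self.data.shape))
            if other.requires_grad:
                if self.data.ndim == 1 and other.data.ndim >= 2:
                    other._accumulate(np.outer(self.data, g) if g.ndim == 1
                                      else np.swapaxes(self.data[..., None] * g[..., None, :], -1, -2))
                elif other.data.ndim == 1:
                    other._accumulate((g[..., None] * self.data).reshape(-1, self.data.shape[-1]).sum(0))
                else:
                    other._accumulate(
                        _unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                     other.data.shape))

        out._backward = bw
        return out

    # -------------------------------------------------------------- reshapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (slice, int, type(Ellipsis), type(None)))
                    for p in parts)

        def bw(g):
            full = np.zeros_like(self.data)
            if basic:  # basic indexing selects each element at most once
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accumulate(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / val)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - val**2))
        return out


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def asdata(x) -> np.ndarray:
    """Underlying ndarray of either a Tensor or array-like."""
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


# ---------------------------------------------------------------------------
# generic functional helpers (ndarray in -> ndarray out; Tensor in -> Tensor)
# ---------------------------------------------------------------------------

def exp(x):
    return x.exp() if isinstance(x, Tensor) else np.exp(x)


def log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def sqrt(x):
    return x.sqrt() if isinstance(x, Tensor) else np.sqrt(x)


def tanh(x):
    return x.tanh() if isinstance(x, Tensor) else np.tanh(x)


def _sigmoid_np(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid(x):
    if isinstance(x, Tensor):
        val = _sigmoid_np(x.data)
        out = Tensor(val, parents=(x,))
        out._backward = lambda g: x._accumulate(g * val * (1.0 - val))
        return out
    return _sigmoid_np(np.asarray(x, dtype=np.float64))


def _softplus_np(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def softplus(x):
    if isinstance(x, Tensor):
        val = _softplus_np(x.data)
        sig = _sigmoid_np(x.data)
        out = Tensor(val, parents=(x,))
        out._backward = lambda g: x._accumulate(g * sig)
        return out
    return _softplus_np(np.asarray(x, dtype=np.float64))


def silu(x):
    """Sigmoid-weighted linear unit, x * sigmoid(x)."""
    if isinstance(x, Tensor):
        sig = _sigmoid_np(x.data)
        val = x.data * sig
        out = Tensor(val, parents=(x,))
        out._backward = lambda g: x._accumulate(g * (sig + x.data * sig * (1.0 - sig)))
        return out
    x = np.asarray(x, dtype=np.float64)
    return x * _sigmoid_np(x)


_PHI1_TAYLOR_CUT = 1e-6


def _phi1_np(x: np.ndarray) -> np.ndarray:
    """(e^x - 1)/x with the removable singularity at 0 filled by Taylor."""
    x = np.asarray(x, dtype=np.float64)
    small = np.abs(x) < _PHI1_TAYLOR_CUT
    safe = np.where(small, 1.0, x)
    out = np.where(small, 1.0 + x / 2.0 + x**2 / 6.0, np.expm1(safe) / safe)
    return out


def _phi1_grad_np(x: np.ndarray) -> np.ndarray:
    # d/dx (e^x-1)/x = (e^x (x-1) + 1) / x^2 ; Taylor: 1/2 + x/3 + x^2/8
    small = np.abs(x) < 1e-4
    safe = np.where(small, 1.0, x)
    exact = (np.exp(safe) * (safe - 1.0) + 1.0) / safe**2
    return np.where(small, 0.5 + x / 3.0 + x**2 / 8.0, exact)


def phi1(x):
    """First exponential-integrator function (e^x − 1)/x, ZOH input factor."""
    if isinstance(x, Tensor):
        out = Tensor(_phi1_np(x.data), parents=(x,))
        out._backward = lambda g: x._accumulate(g * _phi1_grad_np(x.data))
        return out
    return _phi1_np(x)


def clip(x, lo: float, hi: float):
    """Clamp with straight-through gradient inside the active range."""
    if isinstance(x, Tensor):
        val = np.clip(x.data, lo, hi)
        mask = (x.data > lo) & (x.data < hi)
        out = Tensor(val, parents=(x,))
        out._backward = lambda g: x._accumulate(g * mask)
        return out
    return np.clip(x, lo, hi)


def matmul(a, b):
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        a = a if isinstance(a, Tensor) else Tensor(a)
        return a @ b
    return np.asarray(a) @ np.asarray(b)


def concatenate(xs, axis=0):
    if any(isinstance(x, Tensor) for x in xs):
        xs = [x if isinstance(x, Tensor) else Tensor(x) for x in xs]
        out = Tensor(np.concatenate([x.data for x in xs], axis=axis), parents=tuple(xs))
        sizes = [x.data.shape[axis] for x in xs]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for x, lo, hi in zip(xs, offsets[:-1], offsets[1:]):
                if x.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    x._accumulate(g[tuple(sl)])

        out._backward = bw
        return out
    return np.concatenate(xs, axis=axis)


def stack(xs, axis=0):
    if any(isinstance(x, Tensor) for x in xs):
        xs = [x if isinstance(x, Tensor) else Tensor(x) for x in xs]
        out = Tensor(np.stack([x.data for x in xs], axis=axis), parents=tuple(xs))

        def bw(g):
            for i, x in enumerate(xs):
                if x.requires_grad:
                    x._accumulate(np.take(g, i, axis=axis))

        out._backward = bw
        return out
    return np.stack(xs, axis=axis)


def take(x, indices, axis=0):
    """Integer-array gather along ``axis`` (used e.g. for upsampling)."""
    indices = np.asarray(indices, dtype=np.intp)
    if isinstance(x, Tensor):
        out = Tensor(np.take(x.data, indices, axis=axis), parents=(x,))

        def bw(g):
            full = np.zeros_like(x.data)
            np.add.at(np.moveaxis(full, axis, 0), indices, np.moveaxis(g, axis, 0))
            x._accumulate(full)

        out._backward = bw
        return out
    return np.take(x, indices, axis=axis)


def sum_(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(x, axis=axis, keepdims=keepdims)


def mean_(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.mean(axis=axis, keepdims=keepdims)
    return np.mean(x, axis=axis, keepdims=keepdims)


def softmax(x, axis=-1):
    """Shift-invariant softmax; the max-shift is treated as a constant."""
    shift = asdata(x).max(axis=axis, keepdims=True)
    e = exp(x - shift)
    return e / sum_(e, axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# fused causal-convolution op
# ---------------------------------------------------------------------------

def _causal_conv_np(u: np.ndarray, k: np.ndarray) -> np.ndarray:
    """out[..., t, d] = Σ_j k[d, j]·u[..., t−j, d] with zero left-padding;
    ``k`` is (K,) shared or (D, K) depthwise."""
    T = u.shape[-2]
    K = k.shape[-1]
    out = np.zeros_like(u)
    for j in range(min(K, T)):
        wj = k[..., j]  # (D,) or scalar
        if j == 0:
            out += wj * u
        else:
            out[..., j:, :] += wj * u[..., : T - j, :]
    return out


def causal_conv_op(u, kernel):
    """Depthwise causal convolution as a single fused autodiff node."""
    ud, kd = asdata(u), asdata(kernel)
    T, K = ud.shape[-2], kd.shape[-1]
    val = _causal_conv_np(ud, kd)
    if not (isinstance(u, Tensor) or isinstance(kernel, Tensor)):
        return val
    parents = tuple(x for x in (u, kernel) if isinstance(x, Tensor))
    out = Tensor(val, parents=parents)

    def bw(g):
        if isinstance(u, Tensor) and u.requires_grad:
            # correlation: du[t] = Σ_j k[j]·g[t+j]
            du = np.zeros_like(ud)
            for j in range(min(K, T)):
                wj = kd[..., j]
                if j == 0:
                    du += wj * g
                else:
                    du[..., : T - j, :] += wj * g[..., j:, :]
            u._accumulate(du)
        if isinstance(kernel, Tensor) and kernel.requires_grad:
            dk = np.zeros_like(kd)
            red = tuple(range(g.ndim - 1))  # reduce all but the channel axis
            for j in range(min(K, T)):
                if j == 0:
                    prod = (g * ud).sum(axis=red)
                else:
                    prod = (g[..., j:, :] * ud[..., : T - j, :]).sum(axis=red)
                if kd.ndim == 2:
                    dk[:, j] = prod
                else:
                    dk[j] = prod.sum()
            kernel._accumulate(dk)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# fused selective-scan op
# ---------------------------------------------------------------------------

def _scan_forward(u, A, delta, B_sel, C_sel, h0):
    """Per-channel diagonal selective scan, numpy forward.

    Shapes: u (..., T, D); A (N,); delta (..., T, D) or (..., T, 1);
    B_sel, C_sel (..., T, N); h0 (..., D, N) or None.
    Returns v (..., T, D), h_states (..., T, D, N).

    The per-step discretization (Ā_t = exp(δ_t A), B̄_t = δ_t φ1(δ_t A) B_t)
    is vectorized over time; only the linear state recurrence itself runs
    as a Python loop.
    """
    T, D = u.shape[-2], u.shape[-1]
    N = A.shape[0]
    lead = u.shape[:-2]
    dl = np.broadcast_to(delta, lead + (T, D))
    B_sel = np.broadcast_to(B_sel, lead + (T, N))
    C_sel = np.broadcast_to(C_sel, lead + (T, N))
    x = dl[..., None] * A                                  # (..., T, D, N)
    Abar = np.exp(x)
    p1 = _phi1_np(x)
    drive = (dl[..., None] * p1 * B_sel[..., None, :]) * u[..., None]
    h = np.zeros(lead + (D, N)) if h0 is None else \
        np.broadcast_to(h0.astype(np.float64), lead + (D, N)).copy()
    hs = np.empty(lead + (T, D, N))
    for t in range(T):
        h = Abar[..., t, :, :] * h + drive[..., t, :, :]
        hs[..., t, :, :] = h
    v = np.einsum("...tn,...tdn->...td", C_sel, hs)
    return v, (hs, x, Abar, p1)


def _scan_backward(gv, u, A, delta, B_sel, C_sel, h0, cache):
    """Adjoint of the scan; returns grads for u, A, delta, B, C, h0.

    Only the adjoint recurrence λ_{t-1} = Ā_t (λ_t + ∂v_t/∂h_t) loops over
    time; every other factor is vectorized, reusing the forward's
    discretization factors.
    """
    hs, x, Abar, p1 = cache
    T, D = u.shape[-2], u.shape[-1]
    N = A.shape[0]
    lead = u.shape[:-2]
    dl = np.broadcast_to(delta, lead + (T, D))
    B_sel = np.broadcast_to(B_sel, lead + (T, N))
    C_sel = np.broadcast_to(C_sel, lead + (T, N))
    # λ_t = ∂L/∂h_t (including the direct readout term at t)
    lam_all = np.empty(lead + (T, D, N))
    lam = np.zeros(lead + (D, N))
    for t in range(T - 1, -1, -1):
        lam = lam + gv[..., t, :, None] * C_sel[..., t, None, :]
        lam_all[..., t, :, :] = lam
        lam = lam * Abar[..., t, :, :]
    h_prev = np.empty_like(hs)
    h_prev[..., 1:, :, :] = hs[..., :-1, :, :]
    h_prev[..., 0, :, :] = 0.0 if h0 is None else h0
    dC = np.einsum("...td,...tdn->...tn", gv, hs)
    dAbar = lam_all * h_prev
    dBbar = lam_all * u[..., None]      # adjoint of B̄_t (drive = B̄_t u_t)
    Bt = B_sel[..., None, :]
    du = (lam_all * dl[..., None] * p1 * Bt).sum(-1)
    dB = (dBbar * dl[..., None] * p1).sum(-2)
    dx = dAbar * Abar + dBbar * dl[..., None] * _phi1_grad_np(x) * Bt
    ddelta = (dx * A).sum(-1) + (dBbar * p1 * Bt).sum(-1)
    dA = (dx * dl[..., None]).reshape(-1, N).sum(0)
    return du, dA, ddelta, dB, dC, lam


def selective_scan_op(u, A, delta, B_sel, C_sel, h0=None):
    """Selective scan as one fused autodiff node (forward loop + adjoint).

    Accepts Tensors or ndarrays; returns (v, h_final) of the matching kind.
    The per-step semantics equal the naive recurrence
    ``h_t = exp(δ_t A) h_{t-1} + δ_t φ1(δ_t A) B_t u_t`` with readout
    ``v_t[d] = C_t · h_t[d]`` (per-channel diagonal state).
    """
    tensors = [x for x in (u, A, delta, B_sel, C_sel, h0) if isinstance(x, Tensor)]
    ud, Ad = asdata(u), asdata(A)
    dd, Bd, Cd = asdata(delta), asdata(B_sel), asdata(C_sel)
    h0d = None if h0 is None else asdata(h0)
    v, cache = _scan_forward(ud, Ad, dd, Bd, Cd, h0d)
    h_final = cache[0][..., -1, :, :].copy() if ud.shape[-2] > 0 else h0d
    if not tensors:
        return v, h_final

    parents = tuple(x for x in (u, A, delta, B_sel, C_sel, h0) if isinstance(x, Tensor))
    out = Tensor(v, parents=parents)

    def bw(gv):
        du, dA, ddelta, dB, dC, dh0 = _scan_backward(gv, ud, Ad, dd, Bd, Cd, h0d,
                                                     cache)
        if isinstance(u, Tensor) and u.requires_grad:
            u._accumulate(du)
        if isinstance(A, Tensor) and A.requires_grad:
            A._accumulate(dA)
        if isinstance(delta, Tensor) and delta.requires_grad:
            delta._accumulate(_unbroadcast(ddelta, delta.data.shape))
        if isinstance(B_sel, Tensor) and B_sel.requires_grad:
            B_sel._accumulate(dB)
        if isinstance(C_sel, Tensor) and C_sel.requires_grad:
            C_sel._accumulate(dC)
        if h0 is not None and isinstance(h0, Tensor) and h0.requires_grad:
            h0._accumulate(dh0)

    out._backward = bw
    return out, h_final
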