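"""State-space sequence-modeling primitives.

The continuous-time layer is the linear dynamical system

    dh/dt = A h + B u,        v = C h,

with hidden state ``h ∈ R^N`` driven by the input ``u ∈ R^D``.  For
discrete sequences the system is discretized under a zero-order hold
(inputs held constant over each step Δt):

    h_k = Ā h_{k-1} + B̄ u_k,   v_k = C h_k,
    Ā = exp(Δt·A),             B̄ = A^{-1}(exp(Δt·A) − I) B.

Two evaluation modes are provided:

* *time-invariant* (LTI): fixed (A, B, C) and a single Δt — the literal
  recurrence above, equivalent to convolution with the kernel
  ``k_j = C Ā^j B̄``;
* *selective*: Δt, B and C are produced per time step from the input by
  learned projections (:func:`compute_selection`), the state matrix A is
  diagonal and each input channel carries its own N-dimensional state.

All sequence functions take arrays shaped ``(..., T, D)`` (leading batch
dimensions optional) and work on both plain ndarrays and autodiff
:class:`~mscmamba.autodiff.Tensor` values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from . import autodiff as ad
from .autodiff import asdata

__all__ = [
    "ContinuousSSMParams",
    "DiscreteSSMParams",
    "SelectionOutputs",
    "ProjectionParams",
    "SelectionParams",
    "zoh_discretize",
    "ssm_step",
    "lti_scan",
    "compute_selection",
    "selective_scan",
    "causal_conv",
    "linear_project",
    "init_selection_params",
    "stable_diagonal_A",
]


# ---------------------------------------------------------------------------
# parameter bundles
# ---------------------------------------------------------------------------

@dataclass
class ContinuousSSMParams:
    """Continuous-time (A, B, C); A may be a dense N×N matrix or a length-N
    diagonal (``diagonal`` mode).  The stable parameterization requires every
    eigenvalue (diagonal entry) to have negative real part."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=np.float64)
        self.B = np.asarray(self.B, dtype=np.float64)
        self.C = np.asarray(self.C, dtype=np.float64)
        if self.A.ndim not in (1, 2):
            raise ValueError("A must be a vector (diagonal mode) or a matrix")
        if self.A.ndim == 2 and self.A.shape[0] != self.A.shape[1]:
            raise ValueError("dense A must be square")
        n = self.N
        if n < 1:
            raise ValueError("state dimension N must be >= 1")
        if self.B.ndim != 2 or self.B.shape[0] != n:
            raise ValueError(f"B must have shape (N={n}, D)")
        if self.C.ndim != 2 or self.C.shape[1] != n:
            raise ValueError(f"C must have shape (D_out, N={n})")

    @property
    def diagonal(self) -> bool:
        return self.A.ndim == 1

    @property
    def N(self) -> int:
        return self.A.shape[0]

    @property
    def D(self) -> int:
        return self.B.shape[1]

    def is_stable(self) -> bool:
        eig = self.A if self.diagonal else np.linalg.eigvals(self.A)
        return bool(np.all(np.real(eig) < 0))


@dataclass
class DiscreteSSMParams:
    """ZOH-discretized (Ā, B̄) at step size ``delta_t``."""

    A_bar: np.ndarray
    B_bar: np.ndarray
    delta_t: float

    def __post_init__(self):
        self.A_bar = np.asarray(self.A_bar, dtype=np.float64)
        self.B_bar = np.asarray(self.B_bar, dtype=np.float64)
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")


@dataclass
class SelectionOutputs:
    """Per-time-step (Δ_t, B_t, C_t) produced by the selection mechanism.

    ``delta_seq`` is (..., T, D) or (..., T, 1) with strictly positive
    entries; ``B_seq`` and ``C_seq`` are (..., T, N) (the broadcastable
    per-channel form) for selective scans, or (T, N, D) / (T, D_out, N)
    full matrices for the shared-state recurrence.
    """

    delta_seq: object
    B_seq: object
    C_seq: object

    def __len__(self) -> int:
        return asdata(self.delta_seq).shape[-2]


@dataclass
class ProjectionParams:
    """Affine map parameters ``y = x Wᵀ + b``."""

    W: np.ndarray
    b: np.ndarray | None = None

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64) if not ad.is_tensor(self.W) else self.W
        if self.b is not None and not ad.is_tensor(self.b):
            self.b = np.asarray(self.b, dtype=np.float64)


@dataclass
class SelectionParams:
    """Projection set of the selection mechanism: input -> (Δ, B, C).

    ``const_B``/``const_C`` hold learned constant vectors used in
    time-invariant mode (plain fixed-(B, C) recurrence, no input
    dependence); they are ignored in selective mode.
    """

    delta: ProjectionParams
    B: ProjectionParams
    C: ProjectionParams
    const_B: object | None = None
    const_C: object | None = None


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

_TAYLOR_CUT = 1e-6


def zoh_discretize(params: ContinuousSSMParams, delta_t: float) -> DiscreteSSMParams:
    """Zero-order-hold discretization of a continuous system.

    Ā = exp(Δt·A);  B̄ = A^{-1}(exp(Δt·A) − I) B = Δt·φ1(Δt·A)·B where
    φ1(x) = (e^x − 1)/x.  Near-singular Δt·A (|eigenvalue·Δt| < 1e-6) uses
    the 3-term Taylor expansion of φ1, which removes the singularity at
    A → 0 (limit B̄ → Δt·B).
    """
    if not np.isscalar(delta_t) or delta_t <= 0:
        raise ValueError("delta_t must be a positive scalar")
    A, B = params.A, params.B
    if params.diagonal:
        x = delta_t * A
        A_bar = np.exp(x)
        B_bar = delta_t * ad.phi1(x)[:, None] * B
    else:
        x = delta_t * A
        A_bar = scipy.linalg.expm(x)
        eig = np.linalg.eigvals(x)
        if np.min(np.abs(eig)) < _TAYLOR_CUT:
            # Taylor: Δt·(I + x/2 + x²/6)·B
            B_bar = delta_t * (B + x @ B / 2.0 + x @ x @ B / 6.0)
        else:
            B_bar = delta_t * np.linalg.solve(x, A_bar - np.eye(A.shape[0])) @ B
    if not (np.all(np.isfinite(A_bar)) and np.all(np.isfinite(B_bar))):
        eig = A if params.diagonal else np.linalg.eigvals(A)
        bad = eig[~np.isfinite(np.exp(delta_t * np.real(eig)))]
        raise FloatingPointError(
            f"non-finite discretization; offending eigenvalue(s): {bad}")
    return DiscreteSSMParams(A_bar=A_bar, B_bar=B_bar, delta_t=float(delta_t))


def ssm_step(h_prev, u_k, d: DiscreteSSMParams, C):
    """One step of the discrete recurrence: h_k = Ā h_{k-1} + B̄ u_k, v_k = C h_k."""
    h_prev = np.asarray(h_prev, dtype=np.float64)
    u_k = np.atleast_1d(np.asarray(u_k, dtype=np.float64))
    C = np.asarray(C, dtype=np.float64)
    A_bar, B_bar = d.A_bar, np.atleast_2d(d.B_bar)
    if B_bar.shape[1] != u_k.shape[0]:
        raise ValueError("input dimension does not match B_bar")
    if A_bar.ndim == 1:
        if h_prev.shape[0] != A_bar.shape[0]:
            raise ValueError("state dimension mismatch")
        h_k = A_bar * h_prev + B_bar @ u_k
    else:
        if h_prev.shape[0] != A_bar.shape[1]:
            raise ValueError("state dimension mismatch")
        h_k = A_bar @ h_prev + B_bar @ u_k
    v_k = np.atleast_2d(C) @ h_k
    return h_k, v_k


def lti_scan(u_seq, cont: ContinuousSSMParams, delta_t: float, h0=None):
    """Time-invariant evaluation: iterate :func:`ssm_step` over the sequence.

    ``u_seq`` is (T, D); returns (v_seq (T, D_out), h_final (N,)).
    """
    u_seq = np.asarray(u_seq, dtype=np.float64)
    d = zoh_discretize(cont, delta_t)
    h = np.zeros(cont.N) if h0 is None else np.asarray(h0, dtype=np.float64)
    vs = []
    for k in range(u_seq.shape[0]):
        h, v = ssm_step(h, u_seq[k], d, cont.C)
        vs.append(v)
    return np.stack(vs), h


# ---------------------------------------------------------------------------
# selection + selective scan
# ---------------------------------------------------------------------------

def linear_project(x, p: ProjectionParams):
    """Affine map per time step (or per vector): y = x Wᵀ + b."""
    W = p.W
    Wd = asdata(W)
    xd = asdata(x)
    if xd.shape[-1] != Wd.shape[-1]:
        raise ValueError(
            f"input dim {xd.shape[-1]} does not match W input dim {Wd.shape[-1]}")
    y = ad.matmul(x, W.transpose((1, 0)) if ad.is_tensor(W) else Wd.T)
    if p.b is not None:
        y = y + p.b
    return y


def compute_selection(u_seq, params: SelectionParams,
                      time_invariant: bool = False) -> SelectionOutputs:
    """Input-dependent selection: Δ_t = softplus(linear(u_t)), B_t and C_t
    linear in u_t.  Deterministic given parameters and input.

    With ``time_invariant=True`` the outputs are constant over time
    (Δ = softplus(bias), B and C the learned constants), reproducing the
    plain fixed-parameter recurrence.
    """
    if time_invariant:
        if params.const_B is None or params.const_C is None:
            raise ValueError("time-invariant mode requires const_B/const_C")
        delta = ad.softplus(params.delta.b).reshape((1, 1))
        N = asdata(params.const_B).shape[0]
        return SelectionOutputs(delta_seq=delta,
                                B_seq=params.const_B.reshape((1, N)),
                                C_seq=params.const_C.reshape((1, N)))
    delta = ad.softplus(linear_project(u_seq, params.delta))
    B_seq = linear_project(u_seq, params.B)
    C_seq = linear_project(u_seq, params.C)
    return SelectionOutputs(delta_seq=delta, B_seq=B_seq, C_seq=C_seq)


def init_selection_params(rng: np.random.Generator, d_model: int, state_dim: int,
                          delta_init_range=(0.01, 0.1), trainable: bool = False
                          ) -> SelectionParams:
    """Uniform init for B/C projections; the Δ bias is set so that the initial
    softplus output lands in ``delta_init_range``."""
    lim = 1.0 / np.sqrt(d_model)
    delta0 = rng.uniform(*delta_init_range)
    b_delta = np.full(1, np.log(np.expm1(delta0)))  # softplus^{-1}
    mk = (lambda a: ad.Tensor(a, requires_grad=True)) if trainable else (lambda a: a)
    return SelectionParams(
        delta=ProjectionParams(W=mk(rng.normal(0.0, 0.02, (1, d_model))),
                               b=mk(b_delta)),
        B=ProjectionParams(W=mk(rng.uniform(-lim, lim, (state_dim, d_model))), b=None),
        C=ProjectionParams(W=mk(rng.uniform(-lim, lim, (state_dim, d_model))), b=None),
        const_B=mk(rng.uniform(-lim, lim, state_dim)),
        const_C=mk(rng.uniform(-lim, lim, state_dim)),
    )


def stable_diagonal_A(a_log) -> object:
    """Stable diagonal state matrix A = −exp(a_log) (< 0 elementwise)."""
    return -ad.exp(a_log)


def selective_scan(u_seq, A, sel: SelectionOutputs, h0=None):
    """Selective scan with per-step (Δ_t, B_t, C_t) and diagonal stable A.

    Per-channel state semantics: every input channel d carries its own
    N-dimensional state driven by the scalar u[t, d]; B_t, C_t ∈ R^N are
    shared across channels (the broadcastable form of the full T×N×D
    selection).  The output at step k depends only on inputs 1..k.

    ``u_seq``: (..., T, D); returns (v_seq (..., T, D), h_final (..., D, N)).
    Plain-ndarray inputs produce plain ndarrays; Tensor inputs stay in the
    autodiff graph (fused scan node).
    """
    ud = asdata(u_seq)
    dl = asdata(sel.delta_seq)
    Bd = asdata(sel.B_seq)
    T = ud.shape[-2]
    if dl.shape[-2] not in (1, T) or Bd.shape[-2] not in (1, T):
        raise ValueError("selection length does not match input length")
    if np.any(dl <= 0):
        raise ValueError("delta entries must be strictly positive")
    return ad.selective_scan_op(u_seq, A, sel.delta_seq, sel.B_seq, sel.C_seq, h0)


# ---------------------------------------------------------------------------
# causal convolution
# ---------------------------------------------------------------------------

def causal_conv(u_seq, kernel):
    """Causal 1-D convolution along time with zero left-padding.

    ``kernel`` is (K,) (shared across channels) or (D, K) (one kernel per
    channel, depthwise).  Output keeps the input length and follows the
    convolution convention out[t] = Σ_j kernel[j]·u[t−j]: kernel[0]
    multiplies the current sample, kernel[K−1] the oldest.
    """
    kd = asdata(kernel)
    if kd.ndim not in (1, 2):
        raise ValueError("kernel must be (K,) or (D, K)")
    K = kd.shape[-1]
    if K < 1:
        raise ValueError("kernel width K must be >= 1")
    ud = asdata(u_seq)
    if kd.ndim == 2 and kd.shape[0] != ud.shape[-1]:
        raise ValueError("per-channel kernel count does not match channels")
    return ad.causal_conv_op(u_seq, kernel)
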