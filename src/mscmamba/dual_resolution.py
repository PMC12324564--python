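"""Dual-resolution (outer/inner) selective-SSM branches with state-norm
selective attention.

The outer branch processes the full-resolution stream X1 (fast, transient
dynamics); the inner branch processes a temporally average-pooled stream X2
at 1/r resolution (slow trends).  Each branch is a linear projection →
causal convolution → SiLU → selective scan.  Per-step attention weights

    a_k = sigmoid(γ·‖C h_k‖₂ + β)

recalibrate the branch outputs against their temporal mean,

    ṽ_k = a_k ⊙ v_k + (1 − a_k) ⊙ AvgPool(v)_k,

so low-energy (low state-norm) time points are shrunk toward the global
context.  The recalibrated inner stream is upsampled by index repetition
⌊k/r⌋ and channel-concatenated with the outer stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import asdata
from .ssm_core import (
    ProjectionParams,
    SelectionParams,
    causal_conv,
    compute_selection,
    init_selection_params,
    linear_project,
    selective_scan,
    stable_diagonal_A,
)

__all__ = ["AttentionParams", "BranchParams", "downsample", "upsample_repeat",
           "run_branch", "integrate", "attention_weights",
           "attention_weights_from_outputs", "recalibrate",
           "init_branch_params", "init_attention_params"]


@dataclass
class AttentionParams:
    """γ, β of the state-norm attention plus the (optional) Q/K/V projections.

    a_k itself uses only ‖C h_k‖; W_q/W_k are carried for the reduced-
    dimension feature projections but are not consumed by the weight
    formula, and W_v (when present) projects the value stream that gets
    recalibrated.
    """

    gamma: object
    beta: object
    W_q: object | None = None
    W_k: object | None = None
    W_v: object | None = None
    pool_window: object = "global"
    norm: str = "l2"  # or "l2_squared"


@dataclass
class BranchParams:
    in_proj: ProjectionParams
    conv_kernel: object
    a_log: object
    selection: SelectionParams
    time_invariant: bool = False


def downsample(X, r: int):
    """Non-overlapping temporal average pooling with window ``r`` (≥ 2);
    a partial tail window is averaged over its actual length."""
    if r < 2:
        raise ValueError("downsampling factor r must be >= 2")
    T = asdata(X).shape[-2]
    n_full = T // r
    parts = []
    if n_full > 0:
        head = X[(Ellipsis, slice(0, n_full * r), slice(None))]
        D = asdata(X).shape[-1]
        lead = asdata(head).shape[:-2]
        head = head.reshape(lead + (n_full, r, D)) if ad.is_tensor(head) \
            else head.reshape(lead + (n_full, r, D))
        parts.append(ad.mean_(head, axis=-2))
    if T % r:
        tail = X[(Ellipsis, slice(n_full * r, T), slice(None))]
        parts.append(ad.mean_(tail, axis=-2, keepdims=True))
    if len(parts) == 1:
        return parts[0]
    return ad.concatenate(parts, axis=-2)


def upsample_repeat(X, r: int, T: int):
    """Nearest-step upsampling: output index k reads input index ⌊k/r⌋."""
    idx = np.minimum(np.arange(T) // r, asdata(X).shape[-2] - 1)
    return ad.take(X, idx, axis=-2)


def run_branch(X, params: BranchParams, return_states: bool = False):
    """linear projection → causal conv → SiLU → selective scan.

    Returns (v_seq, h_seq) where h_seq are the per-step hidden states
    (recomputed with the naive recurrence when ``return_states`` is True;
    the fused scan keeps them internal otherwise and returns the final
    state in their place).
    """
    u = linear_project(X, params.in_proj)
    c = ad.silu(causal_conv(u, params.conv_kernel))
    A = stable_diagonal_A(params.a_log)
    sel = compute_selection(c, params.selection,
                            time_invariant=params.time_invariant)
    v, h_last = selective_scan(c, A, sel)
    if return_states:
        from .autodiff import _scan_forward
        _, cache = _scan_forward(asdata(c), asdata(A), asdata(sel.delta_seq),
                                 asdata(sel.B_seq), asdata(sel.C_seq), None)
        return v, cache[0]
    return v, h_last


def integrate(v1_seq, v2_seq, r: int):
    """Upsample the inner stream to the outer length and concatenate along
    channels: V width = width(v1) + width(v2)."""
    T = asdata(v1_seq).shape[-2]
    if T == 0 or asdata(v2_seq).shape[-2] == 0:
        raise ValueError("cannot integrate empty sequences")
    v2_up = upsample_repeat(v2_seq, r, T)
    return ad.concatenate([v1_seq, v2_up], axis=-1)


def _norm_last(x, squared: bool):
    s = ad.sum_(x * x, axis=-1)
    if squared:
        return s
    if ad.is_tensor(s):  # eps keeps sqrt differentiable at exactly 0
        return ad.sqrt(s + 1e-12)
    return np.sqrt(s)


def attention_weights(h_seq, C, p: AttentionParams):
    """a_k = sigmoid(γ·‖C h_k‖ + β) per time step, from explicit hidden
    states and a fixed output matrix C.  ``h_seq`` is (..., T, N) or the
    per-channel form (..., T, D, N); the norm is over the readout vector."""
    h = asdata(h_seq) if not ad.is_tensor(h_seq) else h_seq
    y = ad.matmul(h, asdata(C).T if not ad.is_tensor(C) else C.transpose((1, 0)))
    if asdata(y).ndim >= 3 and asdata(h_seq).ndim >= 3:
        # per-channel states: flatten readout over (D, out) before the norm
        yd = asdata(y)
        if yd.ndim > asdata(h_seq).ndim - 1:
            lead = yd.shape[:-2]
            y = y.reshape(lead + (yd.shape[-2] * yd.shape[-1],))
    nrm = _norm_last(y, squared=(p.norm == "l2_squared"))
    return ad.sigmoid(p.gamma * nrm + p.beta)


def attention_weights_from_outputs(v_seq, p: AttentionParams):
    """Same weights computed from the branch outputs: in selective mode the
    per-step readout C_t h_t *is* v_t, so ‖C h_k‖ = ‖v_k‖."""
    nrm = _norm_last(v_seq, squared=(p.norm == "l2_squared"))
    return ad.sigmoid(p.gamma * nrm + p.beta)


def recalibrate(v_seq, a_seq, pool_window="global"):
    """ṽ_k = a_k·v_k + (1−a_k)·AvgPool(v)_k (channelwise temporal mean;
    a sliding centered window of ``pool_window`` steps when numeric)."""
    vd, ad_ = asdata(v_seq), asdata(a_seq)
    if vd.shape[-2] != ad_.shape[-1]:
        raise ValueError("attention length does not match sequence length")
    if pool_window == "global":
        pooled = ad.mean_(v_seq, axis=-2, keepdims=True)
    else:
        w = int(pool_window)
        T = vd.shape[-2]
        rows = []
        for t in range(T):
            lo, hi = max(0, t - w // 2), min(T, t + w // 2 + 1)
            rows.append(ad.mean_(v_seq[(Ellipsis, slice(lo, hi), slice(None))],
                                 axis=-2))
        pooled = ad.stack(rows, axis=-2)
    a = a_seq.reshape(asdata(a_seq).shape + (1,)) if ad.is_tensor(a_seq) \
        else ad_[..., None]
    return a * v_seq + (1.0 - a) * pooled


def init_branch_params(rng: np.random.Generator, d_model: int, state_dim: int,
                       conv_width: int = 4, trainable: bool = False) -> BranchParams:
    mk = (lambda a: ad.Tensor(a, requires_grad=True)) if trainable else (lambda a: a)
    lim = 1.0 / np.sqrt(d_model)
    kern = rng.normal(0.0, 0.02, (d_model, conv_width))
    kern[:, 0] += 1.0  # start near pass-through
    return BranchParams(
        in_proj=ProjectionParams(W=mk(rng.uniform(-lim, lim, (d_model, d_model))),
                                 b=mk(np.zeros(d_model))),
        conv_kernel=mk(kern),
        a_log=mk(rng.normal(0.0, 0.02, state_dim)),
        selection=init_selection_params(rng, d_model, state_dim, trainable=trainable),
    )


def init_attention_params(rng: np.random.Generator, d_model: int,
                          norm: str = "l2", trainable: bool = False
                          ) -> AttentionParams:
    mk = (lambda a: ad.Tensor(a, requires_grad=True)) if trainable else (lambda a: a)
    return AttentionParams(gamma=mk(np.zeros(1)), beta=mk(np.zeros(1)),
                           W_q=None, W_k=None, W_v=None,
                           pool_window="global", norm=norm)
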