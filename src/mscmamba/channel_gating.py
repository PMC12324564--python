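"""Channel-mixing / channel-independence dual pathway with a learned gate.

ROI time series mix information across brain regions (channels) to capture
functional coupling, while region-specific temporal signatures are better
preserved by strictly per-channel processing.  This module provides both
pathways and blends them per time step and channel with a logistic gate:

    X_mix = SiLU(X W_mixᵀ + b_mix)               (cross-channel affine + SiLU)
    X_ind = depthwise causal conv(X; W_ind)       (no cross-channel flow)
    G     = sigmoid(X W_gᵀ + b_g)                 (gate, values in (0,1))
    X_out = G ⊙ X_mix + (1 − G) ⊙ X_ind

X_out is elementwise a convex combination, hence always inside the interval
spanned by X_mix and X_ind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import asdata
from .ssm_core import causal_conv

__all__ = ["ChannelMixParams", "ChannelIndependentParams", "GateParams",
           "PathwayBundle", "channel_mix", "channel_independent",
           "gate_combine", "init_gating_params"]


@dataclass
class ChannelMixParams:
    W_mix: object  # (C, C)
    b_mix: object  # (C,)


@dataclass
class ChannelIndependentParams:
    W_ind: object  # (C, K) depthwise kernels, one width-K kernel per channel


@dataclass
class GateParams:
    W_g: object  # (C, C)
    b_g: object  # (C,)


@dataclass
class PathwayBundle:
    X_mix: object
    X_ind: object
    G: object
    X_out: object


def channel_mix(X, p: ChannelMixParams):
    """Cross-channel affine mixing followed by SiLU, applied per time step."""
    Wd = asdata(p.W_mix)
    if asdata(X).shape[-1] != Wd.shape[-1]:
        raise ValueError("channel count does not match W_mix")
    W_T = p.W_mix.transpose((1, 0)) if ad.is_tensor(p.W_mix) else Wd.T
    return ad.silu(ad.matmul(X, W_T) + p.b_mix)


def channel_independent(X, p: ChannelIndependentParams):
    """Depthwise causal convolution: channel j's output never depends on
    channel i ≠ j (exactly zero cross-channel Jacobian)."""
    kd = asdata(p.W_ind)
    if kd.ndim != 2:
        raise ValueError("W_ind must be (C, K)")
    if asdata(X).shape[-1] != kd.shape[0]:
        raise ValueError("channel count does not match W_ind")
    return causal_conv(X, p.W_ind)


def gate_combine(X, X_mix, X_ind, p: GateParams) -> PathwayBundle:
    """Blend the two pathways with G = sigmoid(X W_gᵀ + b_g)."""
    if asdata(X_mix).shape != asdata(X_ind).shape:
        raise ValueError("X_mix and X_ind must have equal shapes")
    Wd = asdata(p.W_g)
    W_T = p.W_g.transpose((1, 0)) if ad.is_tensor(p.W_g) else Wd.T
    G = ad.sigmoid(ad.matmul(X, W_T) + p.b_g)
    X_out = G * X_mix + (1.0 - G) * X_ind
    return PathwayBundle(X_mix=X_mix, X_ind=X_ind, G=G, X_out=X_out)


def init_gating_params(rng: np.random.Generator, n_channels: int, K: int = 5,
                       trainable: bool = False):
    """(mix, independent, gate) parameter triple.

    The depthwise kernels start at the identity filter (current sample
    weight 1) plus small noise so the pathway begins near pass-through.
    """
    mk = (lambda a: ad.Tensor(a, requires_grad=True)) if trainable else (lambda a: a)
    lim = 1.0 / np.sqrt(n_channels)
    W_ind = rng.normal(0.0, 0.02, (n_channels, K))
    W_ind[:, 0] += 1.0
    return (
        ChannelMixParams(W_mix=mk(rng.uniform(-lim, lim, (n_channels, n_channels))),
                         b_mix=mk(np.zeros(n_channels))),
        ChannelIndependentParams(W_ind=mk(W_ind)),
        GateParams(W_g=mk(rng.normal(0.0, 0.02, (n_channels, n_channels))),
                   b_g=mk(np.zeros(n_channels))),
    )
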