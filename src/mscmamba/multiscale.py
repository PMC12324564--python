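"""Multiscale contextual feature extraction.

Parallel causal-convolution branches with different temporal kernel widths
(default 3, 5, 7) each feed a SiLU nonlinearity and a selective state-space
scan; the branch outputs are fused back into a single stream, either by
channel concatenation followed by a linear projection (``concat_project``,
default) or by summation (``sum``).  Output length always equals input
length (causal zero padding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .ssm_core import (
    SelectionParams,
    ProjectionParams,
    causal_conv,
    compute_selection,
    init_selection_params,
    selective_scan,
    stable_diagonal_A,
)

__all__ = ["MultiscaleConfig", "BranchParams", "init_multiscale_params",
           "multiscale_extract", "silu"]

silu = ad.silu  # re-exported: x * sigmoid(x)


@dataclass
class MultiscaleConfig:
    kernel_widths: tuple = (3, 5, 7)
    d_model: int = 16
    fusion: str = "concat_project"  # or "sum"

    def __post_init__(self):
        self.kernel_widths = tuple(int(w) for w in self.kernel_widths)
        if len(self.kernel_widths) == 0:
            raise ValueError("kernel_widths must be nonempty")
        if any(w < 1 for w in self.kernel_widths):
            raise ValueError("kernel widths must be >= 1")
        if self.fusion not in ("concat_project", "sum"):
            raise ValueError("fusion must be 'concat_project' or 'sum'")


@dataclass
class BranchParams:
    """One conv→SiLU→SSM branch: depthwise causal kernel plus SSM params."""

    conv_kernel: object          # (d_model, w)
    a_log: object                # (N,) -> A = -exp(a_log)
    selection: SelectionParams
    time_invariant: bool = False


def init_multiscale_params(rng: np.random.Generator, cfg: MultiscaleConfig,
                           state_dim: int = 16, trainable: bool = False):
    """Branch parameters + fusion projection for :func:`multiscale_extract`."""
    mk = (lambda a: ad.Tensor(a, requires_grad=True)) if trainable else (lambda a: a)
    branches = []
    for w in cfg.kernel_widths:
        branches.append(BranchParams(
            conv_kernel=mk(rng.normal(0.0, 1.0 / np.sqrt(w), (cfg.d_model, w))),
            a_log=mk(rng.normal(0.0, 0.02, state_dim)),
            selection=init_selection_params(rng, cfg.d_model, state_dim,
                                            trainable=trainable),
        ))
    fusion_proj = None
    if cfg.fusion == "concat_project" and len(cfg.kernel_widths) > 1:
        k = len(cfg.kernel_widths)
        lim = 1.0 / np.sqrt(k * cfg.d_model)
        fusion_proj = ProjectionParams(
            W=mk(rng.uniform(-lim, lim, (cfg.d_model, k * cfg.d_model))),
            b=mk(np.zeros(cfg.d_model)))
    return branches, fusion_proj


def _run_branch(X, bp: BranchParams):
    c = causal_conv(X, bp.conv_kernel)
    s = ad.silu(c)
    A = stable_diagonal_A(bp.a_log)
    sel = compute_selection(s, bp.selection, time_invariant=bp.time_invariant)
    v, _ = selective_scan(s, A, sel)
    return v


def multiscale_extract(X, cfg: MultiscaleConfig, branch_params,
                       fusion_proj: ProjectionParams | None = None):
    """conv(w) → SiLU → selective SSM per kernel width, fused into one stream.

    ``X`` is (..., T, d_model); the output has the same shape.  ``sum``
    fusion is branch-order invariant; ``concat_project`` concatenates the
    branch outputs along channels and projects back to d_model.
    """
    outs = [_run_branch(X, bp) for bp in branch_params]
    if len(outs) == 1 and fusion_proj is None:
        return outs[0]
    if cfg.fusion == "sum":
        out = outs[0]
        for o in outs[1:]:
            out = out + o
        return out
    cat = ad.concatenate(outs, axis=-1)
    from .ssm_core import linear_project
    return linear_project(cat, fusion_proj)
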