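"""Full network assembly, optimization, training loop and evaluation.

Architecture (``msc_mamba`` variant), per block:

    x ── LayerNorm ── multiscale conv→SiLU→SSM branches ── dual-resolution
         outer/inner selective-SSM branches with state-norm attention ──
         concat + projection ──(+ residual)── channel mixing/independence gate

followed by temporal mean pooling and a 2-way softmax head.  Ablation
variants: ``mamba_ss`` (single scale, outer stream only), ``mamba_rs``
(no channel gating), ``mamba_original`` (plain selective-SSM stack).

Training minimizes CE + α·L_align + β·L_adapt with Adam (decoupled weight
decay), an 80/20 split stratified jointly by site and class, and early
stopping on validation cross-entropy.
"""

from __future__ import annotations

import io
import json
import warnings
import zipfile
from dataclasses import dataclass, asdict, is_dataclass
from pathlib import Path

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor, asdata
from . import channel_gating as cg
from . import dual_resolution as dr
from . import multiscale as ms
from . import objectives as obj
from .ssm_core import ProjectionParams, linear_project

__all__ = ["ModelConfig", "ClassifierHead", "OptimizerState", "EvalReport",
           "MSCMambaModel", "build_model", "classify", "adam_step", "Adam",
           "train", "evaluate", "collect_tensors", "forward_flops",
           "layer_norm", "VARIANTS"]

VARIANTS = ("msc_mamba", "mamba_ss", "mamba_rs", "mamba_original")


@dataclass
class ModelConfig:
    """Architecture + loss-weight + training configuration (YAML-serializable)."""

    variant: str = "msc_mamba"
    d_model: int = 16
    n_blocks: int = 2
    state_dim: int = 16
    kernel_widths: tuple = (3, 5, 7)
    conv_width: int = 4           # Mamba-internal causal conv width K
    gating_conv_width: int = 5    # depthwise K of the channel-independent path
    r: int = 2                    # inner-branch downsampling factor
    attention_norm: str = "l2"    # or "l2_squared"
    fusion: str = "concat_project"
    alpha: float = 0.1            # weight of the alignment loss
    beta: float = 0.1             # weight of the MMD adaptation loss
    loss_ramp_epochs: int = 10    # linear ramp-in of alpha/beta from 0
    dropout: float = 0.1
    time_invariant: bool = False
    seed: int = 0
    # optimization
    lr: float = 1e-3
    weight_decay: float = 5e-4
    batch_size: int = 32
    epochs: int = 40
    patience: int = 8
    val_fraction: float = 0.2

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self.kernel_widths = tuple(int(w) for w in self.kernel_widths)

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["kernel_widths"] = list(d["kernel_widths"])
        s = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_yaml(cls, src) -> "ModelConfig":
        text = Path(src).read_text() if isinstance(src, (str, Path)) and (
            "\n" not in str(src) and Path(str(src)).exists()) else str(src)
        return cls(**yaml.safe_load(text))


@dataclass
class ClassifierHead:
    W: object
    b: object
    n_classes: int = 2


@dataclass
class OptimizerState:
    """Adam state over a flat list of parameter arrays."""

    theta: list
    m: list
    v: list
    t: int = 0
    eta: float = 1e-3
    eps: float = 1e-8
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.0

    @classmethod
    def fresh(cls, theta, **kw) -> "OptimizerState":
        theta = [np.asarray(p, dtype=np.float64) for p in theta]
        return cls(theta=theta, m=[np.zeros_like(p) for p in theta],
                   v=[np.zeros_like(p) for p in theta], **kw)


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def layer_norm(x, g, b, eps: float = 1e-5):
    """Normalize over the channel (last) axis, then scale/shift."""
    mu = ad.mean_(x, axis=-1, keepdims=True)
    xc = x - mu
    var = ad.mean_(xc * xc, axis=-1, keepdims=True)
    return xc / ad.sqrt(var + eps) * g + b


def classify(V_pooled, head: ClassifierHead):
    """Softmax over the 2 head logits."""
    Wd = asdata(head.W)
    W_T = head.W.transpose((1, 0)) if ad.is_tensor(head.W) else Wd.T
    logits = ad.matmul(V_pooled, W_T) + head.b
    return ad.softmax(logits, axis=-1)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def collect_tensors(objct, out=None) -> list:
    """Recursively collect trainable Tensors from nested params structures."""
    if out is None:
        out = []
    if isinstance(objct, Tensor):
        if objct.requires_grad and not any(objct is t for t in out):
            out.append(objct)
    elif is_dataclass(objct) and not isinstance(objct, type):
        for f in objct.__dataclass_fields__:
            collect_tensors(getattr(objct, f), out)
    elif isinstance(objct, dict):
        for v in objct.values():
            collect_tensors(v, out)
    elif isinstance(objct, (list, tuple)):
        for v in objct:
            collect_tensors(v, out)
    return out


class MSCMambaModel:
    """The assembled network: parameters + config + forward pass."""

    def __init__(self, cfg: ModelConfig, n_channels: int):
        self.cfg = cfg
        self.n_channels = int(n_channels)
        rng = np.random.default_rng(cfg.seed)
        self.params = self._init_params(rng)

    # ------------------------------------------------------------ init
    def _init_params(self, rng) -> dict:
        cfg = self.cfg
        d = cfg.d_model
        mk = lambda a: Tensor(a, requires_grad=True)
        lim_in = 1.0 / np.sqrt(self.n_channels)
        params = {
            "in_proj": ProjectionParams(
                W=mk(rng.uniform(-lim_in, lim_in, (d, self.n_channels))),
                b=mk(np.zeros(d))),
            "blocks": [],
            "head": ClassifierHead(W=mk(rng.uniform(-1 / np.sqrt(d), 1 / np.sqrt(d),
                                                    (2, d))),
                                   b=mk(np.zeros(2))),
        }
        widths = cfg.kernel_widths if cfg.variant in ("msc_mamba", "mamba_rs") \
            else cfg.kernel_widths[:1]
        for _ in range(cfg.n_blocks):
            blk = {"ln_g": mk(np.ones(d)), "ln_b": mk(np.zeros(d))}
            if cfg.variant == "mamba_original":
                blk["branch"] = dr.init_branch_params(
                    rng, d, cfg.state_dim, cfg.conv_width, trainable=True)
                blk["branch"].time_invariant = cfg.time_invariant
                blk["out_proj"] = ProjectionParams(
                    W=mk(rng.uniform(-1 / np.sqrt(d), 1 / np.sqrt(d), (d, d))),
                    b=mk(np.zeros(d)))
            else:
                ms_cfg = ms.MultiscaleConfig(kernel_widths=widths, d_model=d,
                                             fusion=cfg.fusion)
                branches, fusion = ms.init_multiscale_params(
                    rng, ms_cfg, cfg.state_dim, trainable=True)
                for bp in branches:
                    bp.time_invariant = cfg.time_invariant
                blk["ms_cfg"] = ms_cfg
                blk["ms_branches"] = branches
                blk["ms_fusion"] = fusion
                blk["outer"] = dr.init_branch_params(
                    rng, d, cfg.state_dim, cfg.conv_width, trainable=True)
                blk["outer"].time_invariant = cfg.time_invariant
                blk["outer_attn"] = dr.init_attention_params(
                    rng, d, cfg.attention_norm, trainable=True)
                v_width = d
                if cfg.variant in ("msc_mamba", "mamba_rs"):
                    blk["inner"] = dr.init_branch_params(
                        rng, d, cfg.state_dim, cfg.conv_width, trainable=True)
                    blk["inner"].time_invariant = cfg.time_invariant
                    blk["inner_attn"] = dr.init_attention_params(
                        rng, d, cfg.attention_norm, trainable=True)
                    v_width = 2 * d
                blk["v_proj"] = ProjectionParams(
                    W=mk(rng.uniform(-1 / np.sqrt(v_width), 1 / np.sqrt(v_width),
                                     (d, v_width))),
                    b=mk(np.zeros(d)))
            if cfg.variant in ("msc_mamba", "mamba_ss"):
                blk["gating"] = cg.init_gating_params(
                    rng, d, cfg.gating_conv_width, trainable=True)
            params["blocks"].append(blk)
        return params

    # ---------------------------------------------------------- forward
    def _mssm(self, y, blk):
        cfg = self.cfg
        if cfg.variant == "mamba_original":
            v, _ = dr.run_branch(y, blk["branch"])
            return linear_project(v, blk["out_proj"])
        stream = ms.multiscale_extract(y, blk["ms_cfg"], blk["ms_branches"],
                                       blk["ms_fusion"])
        v1, _ = dr.run_branch(stream, blk["outer"])
        a1 = dr.attention_weights_from_outputs(v1, blk["outer_attn"])
        v1 = dr.recalibrate(v1, a1, blk["outer_attn"].pool_window)
        if "inner" in blk:
            x2 = dr.downsample(stream, cfg.r)
            v2, _ = dr.run_branch(x2, blk["inner"])
            a2 = dr.attention_weights_from_outputs(v2, blk["inner_attn"])
            v2 = dr.recalibrate(v2, a2, blk["inner_attn"].pool_window)
            V = dr.integrate(v1, v2, cfg.r)
        else:
            V = v1
        return linear_project(V, blk["v_proj"])

    def forward(self, X, training: bool = False, rng=None):
        """X: (B, T, C) → (probs (B, 2), pooled penultimate features (B, d))."""
        Xd = np.asarray(X, dtype=np.float64)
        if Xd.ndim == 2:
            Xd = Xd[None]
        x = linear_project(Xd, self.params["in_proj"])
        for blk in self.params["blocks"]:
            y = layer_norm(x, blk["ln_g"], blk["ln_b"])
            m = self._mssm(y, blk)
            if training and self.cfg.dropout > 0:
                if rng is None:
                    rng = np.random.default_rng(self.cfg.seed)
                keep = (rng.random(asdata(m).shape) >= self.cfg.dropout)
                m = m * (keep / (1.0 - self.cfg.dropout))
            x = x + m
            if "gating" in blk:
                mixp, indp, gatep = blk["gating"]
                bundle = cg.gate_combine(x, cg.channel_mix(x, mixp),
                                         cg.channel_independent(x, indp), gatep)
                x = bundle.X_out
        pooled = ad.mean_(x, axis=-2)
        probs = classify(pooled, self.params["head"])
        return probs, pooled

    def predict_proba(self, X) -> np.ndarray:
        probs, _ = self.forward(X, training=False)
        return asdata(probs)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=-1)

    # ------------------------------------------------------------- misc
    def tensors(self) -> list:
        return collect_tensors(self.params)

    def parameter_count(self) -> int:
        return int(sum(t.size for t in self.tensors()))

    def set_flat(self, arrays) -> None:
        for t, a in zip(self.tensors(), arrays):
            t.data = np.asarray(a, dtype=np.float64).reshape(t.data.shape)

    def get_flat(self) -> list:
        return [t.data.copy() for t in self.tensors()]

    # ------------------------------------------------------- persistence
    def save(self, path) -> Path:
        """Single-file archive: config YAML + one .npy per parameter."""
        path = Path(path)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.yaml", self.cfg.to_yaml())
            zf.writestr("meta.json", json.dumps({"n_channels": self.n_channels}))
            for i, t in enumerate(self.tensors()):
                buf = io.BytesIO()
                np.save(buf, t.data)
                zf.writestr(f"param_{i:04d}.npy", buf.getvalue())
        return path

    @classmethod
    def load(cls, path) -> "MSCMambaModel":
        with zipfile.ZipFile(Path(path)) as zf:
            cfg = ModelConfig.from_yaml(zf.read("config.yaml").decode())
            meta = json.loads(zf.read("meta.json").decode())
            model = cls(cfg, meta["n_channels"])
            names = sorted(n for n in zf.namelist() if n.startswith("param_"))
            arrays = [np.load(io.BytesIO(zf.read(n)), allow_pickle=False)
                      for n in names]
        model.set_flat(arrays)
        return model


def build_model(cfg: ModelConfig, n_channels: int) -> MSCMambaModel:
    """Assemble the network for ``cfg.variant`` (see module docstring)."""
    return MSCMambaModel(cfg, n_channels)


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

def adam_step(state: OptimizerState, grads) -> OptimizerState:
    """One Adam update with bias correction and decoupled weight decay."""
    grads = [np.asarray(g, dtype=np.float64) for g in grads]
    if any(not np.all(np.isfinite(g)) for g in grads):
        raise FloatingPointError("non-finite gradient passed to adam_step")
    t = state.t + 1
    b1, b2 = state.beta1, state.beta2
    new_theta, new_m, new_v = [], [], []
    for p, g, m, v in zip(state.theta, grads, state.m, state.v):
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        m_hat = m / (1 - b1**t)
        v_hat = v / (1 - b2**t)
        p = p - state.eta * m_hat / (np.sqrt(v_hat) + state.eps)
        if state.weight_decay:
            p = p - state.eta * state.weight_decay * p
        new_theta.append(p)
        new_m.append(m)
        new_v.append(v)
    return OptimizerState(theta=new_theta, m=new_m, v=new_v, t=t,
                          eta=state.eta, eps=state.eps, beta1=b1, beta2=b2,
                          weight_decay=state.weight_decay)


class Adam:
    """In-place Adam over a list of Tensors (same math as :func:`adam_step`)."""

    def __init__(self, tensors, lr=1e-3, weight_decay=0.0,
                 betas=(0.9, 0.999), eps=1e-8):
        self.tensors = list(tensors)
        self.state = OptimizerState.fresh([t.data for t in self.tensors],
                                          eta=lr, eps=eps, beta1=betas[0],
                                          beta2=betas[1],
                                          weight_decay=weight_decay)

    def step(self) -> None:
        grads = [t.grad if t.grad is not None else np.zeros_like(t.data)
                 for t in self.tensors]
        self.state = adam_step(self.state, grads)
        for t, p in zip(self.tensors, self.state.theta):
            t.data = p

    def zero_grad(self) -> None:
        for t in self.tensors:
            t.grad = None


# ---------------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------------

def _stratified_split(y, sites, val_fraction, rng):
    """80/20 split stratified jointly by (site, class); cells with a single
    subject stay in the training fold."""
    y = np.asarray(y)
    sites = np.asarray(sites)
    train_idx, val_idx = [], []
    for s in np.unique(sites):
        for c in np.unique(y):
            idx = np.nonzero((sites == s) & (y == c))[0]
            if idx.size == 0:
                continue
            idx = rng.permutation(idx)
            n_val = int(round(val_fraction * idx.size))
            if val_fraction > 0 and idx.size >= 2 and n_val == 0:
                n_val = 1
            val_idx.extend(idx[:n_val])
            train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx, dtype=int)), \
        np.sort(np.array(val_idx, dtype=int))


def _stratified_batches(y, sites, batch_size, rng):
    """Deal each (site, class) cell round-robin so every batch covers the
    represented cells as evenly as possible."""
    y = np.asarray(y)
    sites = np.asarray(sites)
    n = len(y)
    n_batches = max(1, int(np.ceil(n / batch_size)))
    batches = [[] for _ in range(n_batches)]
    k = 0
    for s in np.unique(sites):
        for c in np.unique(y):
            idx = np.nonzero((sites == s) & (y == c))[0]
            for i in rng.permutation(idx):
                batches[k % n_batches].append(i)
                k += 1
    return [np.array(b, dtype=int) for b in batches if b]


def train(dataset, cfg: ModelConfig, verbose: bool = False):
    """Train the configured variant on a :class:`SubjectDataset`-like object
    (attributes X (n,T,C), y, sites).  Returns (model, history)."""
    X, y, sites = np.asarray(dataset.X, dtype=np.float64), \
        np.asarray(dataset.y), np.asarray(dataset.sites)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least 2 classes")
    multi_site = len(np.unique(sites)) >= 2
    if not multi_site and (cfg.alpha > 0 or cfg.beta > 0):
        warnings.warn("single-site dataset: alignment/adaptation losses skipped",
                      stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    tr, va = _stratified_split(y, sites, cfg.val_fraction, rng)
    model = build_model(cfg, X.shape[2])
    tensors = model.tensors()
    optimizer = Adam(tensors, lr=cfg.lr, weight_decay=cfg.weight_decay)
    use_align = multi_site and (cfg.alpha > 0 or cfg.beta > 0)

    history = {"epochs": [], "train_idx": tr, "val_idx": va}
    best = (np.inf, None, -1)
    for epoch in range(cfg.epochs):
        # alignment weights ramp in linearly so the classifier signal is
        # established before the cross-site penalties constrain the features
        ramp = 1.0 if cfg.loss_ramp_epochs <= 0 else \
            min(1.0, (epoch + 1) / cfg.loss_ramp_epochs)
        weights = obj.LossWeights(alpha=ramp * cfg.alpha, beta=ramp * cfg.beta)
        ep = {"epoch": epoch, "ce": 0.0, "align": 0.0, "adapt": 0.0,
              "total": 0.0}
        nb = 0
        for bidx in _stratified_batches(y[tr], sites[tr], cfg.batch_size, rng):
            idx = tr[bidx]
            probs, feats = model.forward(X[idx], training=True, rng=rng)
            ce = obj.cross_entropy(y[idx], probs[:, 1])
            if use_align:
                # standardize within the batch so the alignment/adaptation
                # penalties compare feature *structure* across sites and
                # cannot be satisfied by shrinking all features to zero
                mu = feats.mean(axis=0, keepdims=True)
                fc = feats - mu
                sd = ad.sqrt(ad.mean_(fc * fc, axis=0, keepdims=True) + 1e-6)
                groups = obj.group_features(fc / sd, sites[idx], y[idx])
                # average over (class, site-pair) terms so alpha/beta mean
                # the same thing regardless of how many sites the batch has
                n_pairs = sum(len(groups.sites_for(c)) *
                              (len(groups.sites_for(c)) - 1) // 2
                              for c in groups.classes)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    align = obj.alignment_loss(groups) / max(n_pairs, 1)
                    adapt = obj.adaptation_loss(groups) / max(n_pairs, 1)
            else:
                align = adapt = 0.0
            loss = obj.total_loss(ce, align, adapt, weights)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            ep["ce"] += float(asdata(ce))
            ep["align"] += float(asdata(align))
            ep["adapt"] += float(asdata(adapt))
            ep["total"] += float(asdata(loss))
            nb += 1
        for k in ("ce", "align", "adapt", "total"):
            ep[k] /= max(nb, 1)
        if va.size:
            val_probs = model.predict_proba(X[va])
            ep["val_ce"] = float(asdata(obj.cross_entropy(y[va], val_probs[:, 1])))
            ep["val_accuracy"] = float((val_probs.argmax(-1) == y[va]).mean())
        else:
            ep["val_ce"] = ep["ce"]
            ep["val_accuracy"] = np.nan
        history["epochs"].append(ep)
        if verbose:  # pragma: no cover
            print(json.dumps({k: (round(v, 4) if isinstance(v, float) else v)
                              for k, v in ep.items()}))
        if ep["val_ce"] < best[0] - 1e-6:
            best = (ep["val_ce"], model.get_flat(), epoch)
        elif epoch - best[2] >= cfg.patience:
            break
    if best[1] is not None:
        model.set_flat(best[1])
    return model, history


def confusion_report(y_true, y_pred) -> EvalReport:
    """Accuracy / precision / recall / confusion counts; positive class = 1."""
    y, pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y) == 0:
        raise ValueError("empty label vector")
    TP = int(np.sum((pred == 1) & (y == 1)))
    FP = int(np.sum((pred == 1) & (y == 0)))
    TN = int(np.sum((pred == 0) & (y == 0)))
    FN = int(np.sum((pred == 0) & (y == 1)))
    acc = (TP + TN) / len(y)
    prec = TP / (TP + FP) if TP + FP else 0.0
    rec = TP / (TP + FN) if TP + FN else 0.0
    return EvalReport(accuracy=acc, precision=prec, recall=rec,
                      TP=TP, FP=FP, TN=TN, FN=FN)


def evaluate(model: MSCMambaModel, dataset) -> EvalReport:
    """Accuracy / precision / recall from argmax predictions; the positive
    class is ``patient`` (label 1)."""
    X, y = np.asarray(dataset.X, dtype=np.float64), np.asarray(dataset.y)
    if len(y) == 0:
        raise ValueError("empty dataset")
    return confusion_report(y, model.predict(X))


# ---------------------------------------------------------------------------
# complexity accounting
# ---------------------------------------------------------------------------

def forward_flops(cfg: ModelConfig, T: int, C: int) -> int:
    """Analytically accumulated multiply-add count of one forward pass.

    Every term is proportional to the sequence length processed by the
    corresponding stage, so the total is affine (and asymptotically linear)
    in T.
    """
    d, N = cfg.d_model, cfg.state_dim
    total = 2 * T * d * C  # input projection
    widths = cfg.kernel_widths if cfg.variant in ("msc_mamba", "mamba_rs") \
        else cfg.kernel_widths[:1]

    def branch_flops(t):
        f = 2 * t * d * d          # in-projection
        f += 2 * t * d * cfg.conv_width
        f += 2 * t * d * (2 * N + 1)   # selection projections
        f += 6 * t * d * N             # scan recurrence
        return f

    for _ in range(cfg.n_blocks):
        total += 5 * T * d  # layer norm
        if cfg.variant == "mamba_original":
            total += branch_flops(T) + 2 * T * d * d
            continue
        for w in widths:
            total += 2 * T * d * w + branch_flops(T)  # conv + branch SSM
        if cfg.fusion == "concat_project" and len(widths) > 1:
            total += 2 * T * d * (len(widths) * d)
        total += branch_flops(T) + 4 * T * d  # outer + attention/recalibrate
        v_width = d
        if cfg.variant in ("msc_mamba", "mamba_rs"):
            t2 = int(np.ceil(T / cfg.r))
            total += branch_flops(t2) + 4 * t2 * d
            v_width = 2 * d
        total += 2 * T * d * v_width  # V projection
        if cfg.variant in ("msc_mamba", "mamba_ss"):
            total += 2 * 2 * T * d * d + 2 * T * d * cfg.gating_conv_width
    total += 2 * d * 2  # head
    return int(total)
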