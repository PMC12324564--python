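"""Training objectives: class-conditional multisite alignment, per-class
MMD distribution adaptation, cross-entropy, and their weighted combination.

Multisite fMRI features carry scanner/protocol nuisance structure.  Two
complementary penalties pull the learned representations together across
sites *within* each diagnostic class:

* alignment loss — squared Euclidean distance between per-(site, class)
  feature means, summed over classes and unordered site pairs:
      L_align = Σ_c Σ_{s1<s2} ‖F_{s1,c} − F_{s2,c}‖²₂
* adaptation loss — squared maximum mean discrepancy between the empirical
  per-(site, class) feature distributions with a Gaussian RBF kernel
  (biased V-statistic estimator, clamped at 0; median-heuristic bandwidth
  by default):
      L_adapt = Σ_c Σ_{s1<s2} MMD²(P_{s1,c}, P_{s2,c})

The full training objective is  CE + α·L_align + β·L_adapt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import asdata

__all__ = ["SiteClassFeatures", "LossWeights", "KernelSpec", "group_features",
           "alignment_loss", "mmd_squared", "adaptation_loss",
           "cross_entropy", "total_loss", "median_heuristic_bandwidth"]


@dataclass
class SiteClassFeatures:
    """Feature vectors grouped by (site, class).

    ``groups`` maps (site, class) -> feature block of shape (n_sc, d);
    blocks may be ndarrays or autodiff Tensors (during training the
    grouping is a differentiable gather from the batch feature matrix).
    """

    groups: dict

    def __post_init__(self):
        dims = {asdata(v).shape[-1] for v in self.groups.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent feature dimensions across groups: {dims}")

    @property
    def classes(self):
        return sorted({c for (_, c) in self.groups})

    def sites_for(self, c):
        return sorted({s for (s, cc) in self.groups if cc == c})

    def mean(self, s, c):
        return ad.mean_(self.groups[(s, c)], axis=0)


@dataclass
class LossWeights:
    alpha: float = 0.1
    beta: float = 0.1

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class KernelSpec:
    family: str = "gaussian_rbf"
    bandwidth: object = "median_heuristic"  # σ² > 0 or "median_heuristic"

    def __post_init__(self):
        if self.family != "gaussian_rbf":
            raise ValueError("only the gaussian_rbf kernel family is supported")
        if not isinstance(self.bandwidth, str) and self.bandwidth <= 0:
            raise ValueError("numeric bandwidth must be positive")


def group_features(F, sites, classes) -> SiteClassFeatures:
    """Split a feature matrix (n, d) into (site, class) groups.

    When ``F`` is a Tensor the per-group rows are gathered differentiably,
    so the alignment/adaptation losses backpropagate into the network.
    """
    sites = np.asarray(sites)
    classes = np.asarray(classes)
    groups = {}
    for s in np.unique(sites):
        for c in np.unique(classes):
            idx = np.nonzero((sites == s) & (classes == c))[0]
            if idx.size:
                groups[(s.item() if hasattr(s, "item") else s,
                        c.item() if hasattr(c, "item") else c)] = (
                    F[idx] if ad.is_tensor(F) else asdata(F)[idx])
    return SiteClassFeatures(groups=groups)


def _site_pairs(sites):
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            yield sites[i], sites[j]


def alignment_loss(features: SiteClassFeatures):
    """Σ_c Σ_{s1<s2} ‖F̄_{s1,c} − F̄_{s2,c}‖²₂ over unordered site pairs."""
    total = None
    any_pair = False
    for c in features.classes:
        sites = features.sites_for(c)
        for s1, s2 in _site_pairs(sites):
            any_pair = True
            d = features.mean(s1, c) - features.mean(s2, c)
            term = ad.sum_(d * d)
            total = term if total is None else total + term
    if not any_pair:
        warnings.warn("alignment_loss: fewer than 2 sites per class; returning 0",
                      stacklevel=2)
        return 0.0
    return total


def median_heuristic_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """σ² = median of pooled pairwise squared distances (guarded > 0)."""
    z = np.concatenate([np.atleast_2d(x), np.atleast_2d(y)], axis=0)
    sq = ((z[:, None, :] - z[None, :, :]) ** 2).sum(-1)
    m = float(np.median(sq[np.triu_indices_from(sq, k=1)])) if z.shape[0] > 1 else 1.0
    return m if m > 0 else 1.0


def _pairwise_sq_dists(a, b):
    aa = ad.sum_(a * a, axis=-1)
    bb = ad.sum_(b * b, axis=-1)
    bT = b.transpose((1, 0)) if ad.is_tensor(b) else asdata(b).T
    ab = ad.matmul(a, bT)
    d = aa.reshape((asdata(aa).shape[0], 1)) if ad.is_tensor(aa) else aa[:, None]
    sq = d + bb - 2.0 * ab
    return ad.clip(sq, 0.0, np.inf)


def mmd_squared(sample_a, sample_b, k: KernelSpec = KernelSpec()):
    """Biased (V-statistic) squared MMD with a Gaussian kernel,
    mean K_aa + mean K_bb − 2 mean K_ab, clamped at 0."""
    a2, b2 = asdata(sample_a), asdata(sample_b)
    a2 = np.atleast_2d(a2) if not ad.is_tensor(sample_a) else sample_a
    b2 = np.atleast_2d(b2) if not ad.is_tensor(sample_b) else sample_b
    if asdata(a2).size == 0 or asdata(b2).size == 0:
        raise ValueError("MMD samples must be nonempty")
    if asdata(a2).ndim == 1:
        a2 = a2.reshape((-1, 1))
    if asdata(b2).ndim == 1:
        b2 = b2.reshape((-1, 1))
    if k.bandwidth == "median_heuristic":
        sigma2 = median_heuristic_bandwidth(asdata(a2), asdata(b2))
    else:
        sigma2 = float(k.bandwidth)
    inv = 1.0 / (2.0 * sigma2)

    def kmean(x, y):
        return ad.mean_(ad.exp(_pairwise_sq_dists(x, y) * (-inv)))

    val = kmean(a2, a2) + kmean(b2, b2) - 2.0 * kmean(a2, b2)
    return ad.clip(val, 0.0, np.inf) if ad.is_tensor(val) else max(float(val), 0.0)


def adaptation_loss(features: SiteClassFeatures, k: KernelSpec = KernelSpec()):
    """Σ_c Σ_{s1<s2} MMD²(P_{s1,c}, P_{s2,c})."""
    total = None
    any_pair = False
    for c in features.classes:
        sites = features.sites_for(c)
        for s1, s2 in _site_pairs(sites):
            any_pair = True
            term = mmd_squared(features.groups[(s1, c)], features.groups[(s2, c)], k)
            total = term if total is None else total + term
    if not any_pair:
        warnings.warn("adaptation_loss: fewer than 2 sites per class; returning 0",
                      stacklevel=2)
        return 0.0
    return total


_EPS = 1e-7


def cross_entropy(y, y_hat):
    """Mean binary cross-entropy −(1/N)Σ[y log ŷ + (1−y) log(1−ŷ)];
    ŷ is the positive-class probability, clamped to [1e−7, 1−1e−7]."""
    yd = np.atleast_1d(np.asarray(asdata(y), dtype=np.float64))
    if not np.all(np.isin(yd, (0.0, 1.0))):
        raise ValueError("labels must be in {0, 1}")
    p = ad.clip(y_hat, _EPS, 1.0 - _EPS)
    ll = yd * ad.log(p) + (1.0 - yd) * ad.log(1.0 - p)
    return -ad.mean_(ll)


def total_loss(ce, align, adapt, w: LossWeights):
    """Training objective CE + α·L_align + β·L_adapt."""
    return ce + w.alpha * align + w.beta * adapt
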