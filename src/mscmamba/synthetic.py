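"""Synthetic multisite, two-class multivariate BOLD-like time series.

The generator emulates the statistical structure that a multiscale
selective-SSM classifier targets, without any biophysical forward model:

* a latent slow component — ``n_latent`` AR(1) factors with a
  *class-specific* autoregressive coefficient (long-range temporal
  structure that differs between patients and controls);
* a *class-specific low-rank cross-channel mixing* of those factors into
  the C observed channels (class information carried by the channel
  covariance, not by channel means);
* *site nuisances* — per-site multiplicative gain and additive offset
  applied to every subject of a site, white observation noise, and
  (optionally, ``site_mixing_sd`` > 0) a per-site perturbation of the
  spatial mixing pattern, emulating scanner/protocol-dependent spatial
  signal differences.

Because the class signal lives in dynamics and cross-channel coupling,
a linear classifier on per-channel temporal means stays near chance,
while features that see the covariance (e.g. Fisher-z functional
connectivity) separate the classes — :func:`planted_separability`
computes both reference accuracies.

``confound_strength`` skews the class ratio across sites (0 = balanced,
1 = fully alternating imbalance), creating the site-confounded regime in
which class-conditional cross-site alignment losses matter.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_pipeline import (SubjectDataset, SubjectRecord, fc_matrix,
                            write_manifest, write_subject_timeseries)

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_subject",
           "generate_dataset", "planted_separability", "export_dataset"]


@dataclass
class SimulationConfig:
    n_sites: int = 4
    subjects_per_site_per_class: int = 25
    T: int = 150
    C: int = 32
    n_latent: int = 5
    class_effect: float = 1.0       # scales the mixing-matrix difference
    site_gain_sd: float = 0.1
    site_offset_sd: float = 0.3
    site_mixing_sd: float = 0.0     # per-site spatial-pattern perturbation
    site_noise_factor_range: tuple = (1.0, 1.0)  # per-site noise_sd multiplier
    ar_coef_by_class: tuple = (0.3, 0.6)
    noise_sd: float = 0.5
    confound_strength: float = 0.0  # 0 balanced .. 1 fully skewed
    seed: int = 0

    def __post_init__(self):
        if any(abs(a) >= 1 for a in self.ar_coef_by_class):
            raise ValueError("AR coefficients must satisfy |phi| < 1")
        if min(self.site_gain_sd, self.site_offset_sd, self.noise_sd) < 0:
            raise ValueError("noise/site scales must be nonnegative")
        if self.subjects_per_site_per_class < 1:
            raise ValueError("subjects_per_site_per_class must be >= 1")
        if not 0.0 <= self.confound_strength <= 1.0:
            raise ValueError("confound_strength must be in [0, 1]")
        self.ar_coef_by_class = tuple(float(a) for a in self.ar_coef_by_class)
        self.site_noise_factor_range = tuple(
            float(v) for v in self.site_noise_factor_range)
        if min(self.site_noise_factor_range) < 0:
            raise ValueError("site noise factors must be nonnegative")


class SyntheticDataset(SubjectDataset):
    """Generated records plus the ground-truth configuration."""

    def __init__(self, records, ground_truth: SimulationConfig, site_params: dict):
        super().__init__(records)
        self.ground_truth = ground_truth
        self.site_params = site_params


def _mixing_matrices(cfg: SimulationConfig, rng: np.random.Generator):
    """Shared base mixing W0 and a class-contrast direction W1; class c mixes
    with W0 ± (class_effect/2)·W1.  Columns are unit-normalized."""
    W0 = rng.normal(0.0, 1.0, (cfg.C, cfg.n_latent))
    W1 = rng.normal(0.0, 1.0, (cfg.C, cfg.n_latent))
    W0 /= np.linalg.norm(W0, axis=0, keepdims=True)
    W1 /= np.linalg.norm(W1, axis=0, keepdims=True)
    out = []
    for c, sign in enumerate((-1.0, +1.0)):
        W = W0 + sign * 0.5 * cfg.class_effect * W1
        out.append(W / np.linalg.norm(W, axis=0, keepdims=True))
    return out


def _ar1(T: int, n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) factors with unit marginal variance and lag-1
    autocorrelation phi."""
    innov_sd = np.sqrt(1.0 - phi**2)
    z = np.empty((T, n))
    z[0] = rng.normal(0.0, 1.0, n)
    eps = rng.normal(0.0, innov_sd, (T - 1, n))
    for t in range(1, T):
        z[t] = phi * z[t - 1] + eps[t - 1]
    return z


def simulate_subject(label: int, site_gain: np.ndarray, site_offset: np.ndarray,
                     mixing: np.ndarray, cfg: SimulationConfig,
                     rng: np.random.Generator,
                     noise_sd: float | None = None) -> np.ndarray:
    """One subject's T×C series: mixed AR(1) latents + white noise, scaled
    and shifted by the subject's site nuisances."""
    phi = cfg.ar_coef_by_class[label]
    z = _ar1(cfg.T, cfg.n_latent, phi, rng)
    signal = z @ mixing.T
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    noise = rng.normal(0.0, sd, (cfg.T, cfg.C))
    return site_gain * (signal + noise) + site_offset


def _class_probabilities(cfg: SimulationConfig) -> np.ndarray:
    """Per-site probability of class 1; alternates around 0.5 with
    amplitude confound_strength/2."""
    signs = np.array([1.0 if s % 2 == 0 else -1.0 for s in range(cfg.n_sites)])
    return 0.5 + 0.5 * cfg.confound_strength * signs


def generate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Full site × class factorial design (skewed when confound_strength>0).

    A splittable RNG hierarchy (dataset → site → subject) keeps subject
    draws reproducible from the single config seed.
    """
    root = np.random.default_rng(cfg.seed)
    root_ss = np.random.SeedSequence(cfg.seed)
    site_ss = root_ss.spawn(cfg.n_sites)
    mixing = _mixing_matrices(cfg, root)
    p1 = _class_probabilities(cfg)
    records = []
    site_params = {}
    for s in range(cfg.n_sites):
        srng = np.random.default_rng(site_ss[s])
        gain = 1.0 + srng.normal(0.0, cfg.site_gain_sd, cfg.C)
        offset = srng.normal(0.0, cfg.site_offset_sd, cfg.C)
        site_mix = [mixing[c] for c in (0, 1)]
        if cfg.site_mixing_sd > 0:
            E = srng.normal(0.0, 1.0, (cfg.C, cfg.n_latent))
            E /= np.linalg.norm(E, axis=0, keepdims=True)
            site_mix = [W + cfg.site_mixing_sd * E for W in site_mix]
            site_mix = [W / np.linalg.norm(W, axis=0, keepdims=True)
                        for W in site_mix]
        lo, hi = cfg.site_noise_factor_range
        noise_sd = cfg.noise_sd * (lo if lo == hi else srng.uniform(lo, hi))
        site_params[f"site{s:02d}"] = {"gain": gain, "offset": offset,
                                       "noise_sd": noise_sd}
        n_total = 2 * cfg.subjects_per_site_per_class
        n1 = int(round(p1[s] * n_total))
        n1 = min(max(n1, 0), n_total)
        labels = np.array([1] * n1 + [0] * (n_total - n1))
        subj_ss = site_ss[s].spawn(n_total)
        for i, lab in enumerate(labels):
            ts = simulate_subject(int(lab), gain, offset, site_mix[lab], cfg,
                                  np.random.default_rng(subj_ss[i]),
                                  noise_sd=noise_sd)
            records.append(SubjectRecord(
                subject_id=f"sub-s{s:02d}-{i:03d}", site=f"site{s:02d}",
                label="patient" if lab == 1 else "control", timeseries=ts,
                age=float(np.round(
                    np.clip(np.random.default_rng(subj_ss[i]).normal(35, 10),
                            18, 65), 1)),
                sex="M" if i % 2 == 0 else "F",
                education=float(12 + (i % 8))))
    return SyntheticDataset(records, cfg, site_params)


def planted_separability(cfg: SimulationConfig, test_fraction: float = 0.3):
    """Reference accuracies that calibrate what the planted signal supports.

    (i) a linear classifier on per-channel temporal means — near chance by
    construction (class information lives in dynamics/coupling, not means);
    (ii) a linear classifier on Fisher-z functional-connectivity features —
    the upper reference that sees the covariance structure directly.
    """
    if cfg.class_effect < 0:
        raise ValueError("class_effect must be nonnegative")
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    ds = generate_dataset(cfg)
    y = ds.y
    means = ds.X.mean(axis=1)
    iu = np.triu_indices(cfg.C, k=1)
    fc = np.stack([fc_matrix(r.timeseries).values[iu] for r in ds])
    out = {}
    for name, feats in (("channel_mean_accuracy", means),
                        ("fc_feature_accuracy", fc)):
        Xtr, Xte, ytr, yte = train_test_split(
            feats, y, test_size=test_fraction, random_state=cfg.seed,
            stratify=y)
        clf = make_pipeline(StandardScaler(),
                            LogisticRegression(max_iter=2000, C=1.0))
        clf.fit(Xtr, ytr)
        out[name] = float(clf.score(Xte, yte))
    out["n_subjects"] = len(ds)
    return out


def export_dataset(ds: SyntheticDataset, out_dir) -> Path:
    """Write the dataset in the text formats of the data pipeline plus a
    ground-truth YAML; reloadable via :func:`~mscmamba.data_pipeline.load_dataset`."""
    out_dir = Path(out_dir)
    ts_dir = out_dir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in ds.records:
        write_subject_timeseries(r, ts_dir / f"{r.subject_id}.csv")
        rows.append({"subject_id": r.subject_id, "site": r.site,
                     "label": r.label, "age": r.age, "sex": r.sex,
                     "education": r.education})
    pd.DataFrame(rows).to_csv(out_dir / "phenotypes.tsv", sep="\t", index=False)
    write_manifest(out_dir)
    gt = asdict(ds.ground_truth)
    gt["ar_coef_by_class"] = list(gt["ar_coef_by_class"])
    with open(out_dir / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(gt, fh)
    return out_dir
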