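# mscmamba

Multiscale, dual-resolution **selective state-space (Mamba-style)
classification of ROI-level BOLD time series**, with class-conditional
cross-site alignment and MMD distribution-adaptation losses for multisite
fMRI studies.

## The problem

Resting-state fMRI gives each subject a T×C matrix: T time points of the
BOLD signal averaged within C atlas regions (ROIs).  Classifying subjects
(e.g. patients vs. healthy controls) from these series requires capturing
long-range temporal dependencies and cross-regional coupling, and — in
multisite cohorts — tolerating scanner- and protocol-dependent nuisance
variation that differs systematically between sites.

## The model

The core layer is a linear dynamical system used as a sequence primitive,

    h_k = Ā h_{k−1} + B̄ u_k,   v_k = C h_k,
    Ā = exp(Δt·A),             B̄ = A⁻¹(exp(Δt·A) − I)B,

evaluated as a *selective scan*: Δt, B and C are produced from the input at
every time step, so the recurrence filters its input adaptively while
remaining O(T).  Around this primitive the network stacks, per block:
multiscale causal-conv branches (widths 3/5/7) feeding SSMs; an outer
(full-resolution) and inner (average-pooled) branch pair whose outputs are
recalibrated by state-norm attention a_k = σ(γ‖C h_k‖₂ + β) and
concatenated; and a channel-mixing / channel-independence dual pathway
blended by a learned sigmoid gate.  Training minimizes

    CE + α·Σ_c Σ_{s1<s2} ‖F̄_{s1,c} − F̄_{s2,c}‖²₂
       + β·Σ_c Σ_{s1<s2} MMD²(P_{s1,c}, P_{s2,c}),

pulling same-class feature distributions together across sites.  Ablation
variants (`mamba_ss`, `mamba_rs`, `mamba_original`) switch off the
multiscale, gating, or all additions.  See `docs/methods.md` for the full
model description and design decisions.

Everything trains on a small reverse-mode autodiff engine over numpy
(`mscmamba.autodiff`) with a fused, gradient-checked selective-scan node —
the package has no deep-learning framework dependency.

## Worked example

```python
import numpy as np
from mscmamba import SimulationConfig, generate_dataset, planted_separability
from mscmamba.estimators import MSCMambaClassifier

# synthetic multisite benchmark: 4 sites x 2 classes x 25 subjects,
# T=150 time points, C=32 regions; class signal planted in AR dynamics
# and cross-channel coupling, not channel means
cfg = SimulationConfig(seed=1)
ds = generate_dataset(cfg)
print(planted_separability(cfg))
# {'channel_mean_accuracy': 0.533..., 'fc_feature_accuracy': 1.0, 'n_subjects': 200}

clf = MSCMambaClassifier(d_model=12, state_dim=4, epochs=60, patience=12, seed=0)
clf.fit(ds.X, ds.y, sites=ds.sites)
best = min(clf.history_["epochs"], key=lambda e: e["val_ce"])
print(round(best["val_accuracy"], 3))
# 0.975
```

The two `planted_separability` numbers are linear-readout references: a
logistic regression on per-channel temporal means stays near chance (0.53 —
the classes have identical means by construction), while one on Fisher-z
functional-connectivity features reaches 1.0 (the signal lives in the
covariance structure).  The network's 0.975 validation accuracy shows it
recovers that temporal/cross-channel signal from the raw series.

The same flows are available from a shell:

```bash
msc-mamba simulate --config sim.yaml --out data/
msc-mamba train --config cfg.yaml --data data/ --out run/
msc-mamba evaluate --model run/model.zip --data data/
msc-mamba ablate --data data/ --variants msc_mamba,mamba_ss,mamba_rs,mamba_original
```

Datasets are plain text: one CSV per subject (rows = time points, columns =
regions), a TSV phenotype table, and a YAML manifest.  `mscmamba.data_pipeline`
also provides the dataset-side math: ROI averaging of labeled voxel series,
subject/site exclusion filters (inclusive 18–65 age bounds, required-field
and quality checks, minimum 10 subjects per group per site), and Fisher-z
Pearson connectivity matrices.

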