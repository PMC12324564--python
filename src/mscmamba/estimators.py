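"""scikit-learn style estimators and feature transformers.

:class:`MSCMambaClassifier` wraps the full network behind the standard
``fit`` / ``predict`` / ``predict_proba`` contract (``get_params`` /
``set_params`` / ``clone`` compatible), taking ``X`` as an (n, T, C) array
of per-subject ROI time series and an optional per-subject ``sites`` array
that activates the multisite alignment losses.

:class:`ChannelMeanFeatures` and :class:`FisherZConnectivityFeatures` are
stateless transformers mapping time series to flat feature vectors; they
compose with sklearn pipelines and are the feature extractors behind the
linear reference classifiers used to probe planted separability.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data_pipeline import fc_matrix
from .model import ModelConfig, MSCMambaModel, evaluate, train

__all__ = ["MSCMambaClassifier", "ChannelMeanFeatures",
           "FisherZConnectivityFeatures"]


class _ArrayDataset:
    def __init__(self, X, y, sites):
        self.X = X
        self.y = y
        self.sites = sites


def _check_timeseries_X(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError("X must be (n_subjects, T, C) time series")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains NaN/Inf")
    return X


class MSCMambaClassifier(ClassifierMixin, BaseEstimator):
    """Multiscale dual-resolution selective-SSM classifier.

    Parameters mirror :class:`~mscmamba.model.ModelConfig`; see there for
    the architecture.  After ``fit``: ``model_`` (the trained network),
    ``history_`` (per-epoch loss/metric log), ``classes_``.

    Examples
    --------
    >>> clf = MSCMambaClassifier(epochs=5, seed=0)
    >>> clf.fit(X, y, sites=sites).score(X_val, y_val)  # doctest: +SKIP
    """

    def __init__(self, variant="msc_mamba", d_model=16, n_blocks=2,
                 state_dim=16, kernel_widths=(3, 5, 7), conv_width=4,
                 gating_conv_width=5, r=2, attention_norm="l2",
                 fusion="concat_project", alpha=0.1, beta=0.1,
                 loss_ramp_epochs=10, dropout=0.1, time_invariant=False,
                 seed=0, lr=1e-3, weight_decay=5e-4, batch_size=32,
                 epochs=40, patience=8, val_fraction=0.2):
        self.variant = variant
        self.d_model = d_model
        self.n_blocks = n_blocks
        self.state_dim = state_dim
        self.kernel_widths = kernel_widths
        self.conv_width = conv_width
        self.gating_conv_width = gating_conv_width
        self.r = r
        self.attention_norm = attention_norm
        self.fusion = fusion
        self.alpha = alpha
        self.beta = beta
        self.loss_ramp_epochs = loss_ramp_epochs
        self.dropout = dropout
        self.time_invariant = time_invariant
        self.seed = seed
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.val_fraction = val_fraction

    # ------------------------------------------------------------------
    def _config(self) -> ModelConfig:
        return ModelConfig(**{k: getattr(self, k)
                              for k in ModelConfig.__dataclass_fields__})

    def fit(self, X, y, sites=None):
        X = _check_timeseries_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("binary classification requires exactly 2 classes")
        y01 = np.searchsorted(self.classes_, y)
        if sites is None:
            sites = np.zeros(len(y), dtype=int)
        ds = _ArrayDataset(X, y01, np.asarray(sites))
        self.model_, self.history_ = train(ds, self._config())
        self.config_ = self.model_.cfg
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(_check_timeseries_X(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=-1)]

    def evaluation_report(self, X, y, sites=None):
        """Accuracy/precision/recall + confusion counts on labeled data."""
        check_is_fitted(self, "model_")
        y01 = np.searchsorted(self.classes_, np.asarray(y))
        return evaluate(self.model_, _ArrayDataset(_check_timeseries_X(X),
                                                   y01, sites))


class ChannelMeanFeatures(TransformerMixin, BaseEstimator):
    """Per-channel temporal means: (n, T, C) → (n, C)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        return _check_timeseries_X(X).mean(axis=1)


class FisherZConnectivityFeatures(TransformerMixin, BaseEstimator):
    """Upper-triangle Fisher-z functional connectivity: (n, T, C) → (n, C(C−1)/2)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X = _check_timeseries_X(X)
        iu = np.triu_indices(X.shape[2], k=1)
        return np.stack([fc_matrix(x).values[iu] for x in X])
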