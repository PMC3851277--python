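"""Feature standardization and PCA dimension reduction.

Morphological features are z-score standardized and projected onto the
leading principal components that together account for a target fraction
(default 95%) of the variance.  Components are not whitened: the downstream
HMM covariances absorb scale, and the covariance ridge is calibrated on this
scale.  The reduction is fitted per analysis unit (one knockdown movie plus
its pooled plate-matched controls) — the same population the HMM is trained
on — though nothing prevents a global fit.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .data_model import serializable
from .errors import InsufficientDataError, ModelError


@serializable("pca_model")
class StandardizedPCA(TransformerMixin, BaseEstimator):
    """z-score standardization followed by variance-targeted PCA.

    Parameters
    ----------
    variance_target : float in (0, 1], default 0.95
        Retain the smallest number of components whose cumulative explained
        variance ratio reaches the target.

    Attributes
    ----------
    feature_means_, feature_sds_ : per-feature standardization parameters
        (length p, the original feature count).
    kept_features_ : indices of features with non-zero variance; constant
        features are dropped with a warning before PCA.
    components_ : (k_, p_kept) orthonormal loadings.
    explained_variance_ratio_ : (k_,) on the standardized scale.
    k_ : retained dimensionality.
    """

    def __init__(self, variance_target: float = 0.95):
        self.variance_target = variance_target

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise InsufficientDataError("need at least two rows to standardize and fit a PCA")
        if not (0.0 < self.variance_target <= 1.0):
            raise ModelError(f"variance_target must lie in (0, 1], got {self.variance_target}")
        self.feature_means_ = X.mean(axis=0)
        self.feature_sds_ = X.std(axis=0, ddof=0)
        keep = self.feature_sds_ > 0.0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance feature(s) before PCA",
                stacklevel=2,
            )
        if not keep.any():
            raise InsufficientDataError("all features have zero variance")
        self.kept_features_ = np.flatnonzero(keep)
        Z = (X[:, keep] - self.feature_means_[keep]) / self.feature_sds_[keep]
        pca = PCA(svd_solver="full").fit(Z)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, self.variance_target - 1e-10) + 1)
        k = min(k, cum.size)
        self.components_ = pca.components_[:k]
        self.explained_variance_ratio_ = pca.explained_variance_ratio_[:k]
        self.full_explained_variance_ratio_ = pca.explained_variance_ratio_
        self.k_ = k
        return self

    def transform(self, X) -> np.ndarray:
        """Project rows onto the retained components (no whitening)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.feature_means_.shape[0]:
            raise ModelError(
                f"expected {self.feature_means_.shape[0]} features, got {X.shape[1]}"
            )
        if X.shape[0] == 0:
            return np.empty((0, self.k_))
        keep = self.kept_features_
        Z = (X[:, keep] - self.feature_means_[keep]) / self.feature_sds_[keep]
        return Z @ self.components_.T

    def to_dict(self) -> dict:
        return {
            "variance_target": self.variance_target,
            "feature_means": self.feature_means_,
            "feature_sds": self.feature_sds_,
            "kept_features": self.kept_features_,
            "components": self.components_,
            "explained_variance_ratio": self.explained_variance_ratio_,
            "k": self.k_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizedPCA":
        model = cls(variance_target=d["variance_target"])
        model.feature_means_ = np.asarray(d["feature_means"], dtype=float)
        model.feature_sds_ = np.asarray(d["feature_sds"], dtype=float)
        model.kept_features_ = np.asarray(d["kept_features"], dtype=int)
        model.components_ = np.asarray(d["components"], dtype=float)
        model.explained_variance_ratio_ = np.asarray(d["explained_variance_ratio"], dtype=float)
        model.k_ = int(d["k"])
        return model


def fit_preprocessor(X, variance_target: float = 0.95) -> StandardizedPCA:
    return StandardizedPCA(variance_target=variance_target).fit(X)


def transform(model: StandardizedPCA, X) -> np.ndarray:
    return model.transform(X)
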