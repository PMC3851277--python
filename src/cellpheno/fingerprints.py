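"""Phenotypic fingerprints of gene knockdowns.

Abnormal cells pooled across all genes that survive the replicate filter are
clustered by a 20-component Gaussian mixture fitted on their z-scored
original features — the universal abnormal-phenotype classes.  A knockdown's
fingerprint is the vector of relative (hard) cluster assignments of its
abnormal cells; gene fingerprints average the replicate fingerprints.
Fingerprints are compared by Euclidean distance, grouped by average-linkage
hierarchical clustering, and the coherence of two siRNA sets targeting the
same gene is summarized by a within/between distance-ratio score.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import euclidean
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .data_model import serializable
from .errors import ModelError, UndefinedFingerprintError, UndefinedScoreError


@serializable("fingerprint")
@dataclass
class Fingerprint:
    """Probability vector of an owner's abnormal cells over the universal classes."""

    owner: object
    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)

    def to_dict(self) -> dict:
        return {"owner": self.owner, "vector": self.vector}

    @classmethod
    def from_dict(cls, d: dict) -> "Fingerprint":
        return cls(**d)


class UniversalPhenotypeGMM(BaseEstimator):
    """Full-covariance Gaussian mixture over pooled abnormal cells.

    Features are z-scored globally before fitting (constant features get unit
    scale).  Components are initialized by k-means from a fixed seed; the
    covariance ridge matches the HMM's regularization.
    """

    def __init__(self, n_components: int = 20, ridge: float = 0.08, random_state: int | None = 0):
        self.n_components = n_components
        self.ridge = ridge
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.n_components:
            raise ModelError(
                f"{X.shape[0]} pooled abnormal cells cannot support {self.n_components} components"
            )
        self.feature_means_ = X.mean(axis=0)
        sds = X.std(axis=0, ddof=0)
        self.feature_sds_ = np.where(sds > 0, sds, 1.0)
        Z = (X - self.feature_means_) / self.feature_sds_
        self.gmm_ = GaussianMixture(
            n_components=self.n_components,
            covariance_type="full",
            reg_covar=self.ridge,
            init_params="kmeans",
            n_init=1,
            max_iter=500,
            random_state=self.random_state,
        ).fit(Z)
        self.weights_ = self.gmm_.weights_
        self.means_ = self.gmm_.means_
        self.covariances_ = self.gmm_.covariances_
        return self

    def predict(self, X) -> np.ndarray:
        """Hard argmax-responsibility class for each cell."""
        X = np.asarray(X, dtype=float)
        Z = (X - self.feature_means_) / self.feature_sds_
        return self.gmm_.predict(Z)


def fit_universal_gmm(X, n_components: int = 20, seed: int | None = 0, ridge: float = 0.08) -> UniversalPhenotypeGMM:
    return UniversalPhenotypeGMM(n_components=n_components, ridge=ridge, random_state=seed).fit(X)


def fingerprint(X_owner, gmm: UniversalPhenotypeGMM, owner: object = None) -> Fingerprint:
    """Relative hard cluster assignments of one owner's abnormal cells."""
    X_owner = np.asarray(X_owner, dtype=float)
    if X_owner.shape[0] == 0:
        raise UndefinedFingerprintError(f"owner {owner!r} has no abnormal cells")
    labels = gmm.predict(X_owner)
    counts = np.bincount(labels, minlength=gmm.n_components).astype(float)
    return Fingerprint(owner=owner, vector=counts / counts.sum())


def average_gene_fingerprint(replicate_fps: Sequence[Fingerprint], owner: object = None) -> Fingerprint:
    """Arithmetic mean of replicate fingerprints, renormalized to sum 1."""
    if len(replicate_fps) == 0:
        raise UndefinedFingerprintError("no replicate fingerprints to average")
    M = np.mean([fp.vector for fp in replicate_fps], axis=0)
    return Fingerprint(owner=owner if owner is not None else replicate_fps[0].owner, vector=M / M.sum())


@dataclass
class FingerprintClustering:
    """Average-linkage grouping of fingerprints with a display-ready heatmap."""

    owners: list
    matrix: np.ndarray  # raw fingerprints, one row per owner
    linkage: np.ndarray  # scipy linkage (merge) table
    leaf_order: np.ndarray

    @property
    def display_matrix(self) -> np.ndarray:
        """Heatmap matrix: rows in leaf order, entries z-scored per column
        (display only; clustering operates on the raw vectors)."""
        M = self.matrix[self.leaf_order]
        sd = M.std(axis=0, ddof=0)
        return (M - M.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels in the original fingerprint order."""
        return fcluster(self.linkage, t=n_clusters, criterion="maxclust")


def cluster_fingerprints(fps: Sequence[Fingerprint], on_zscores: bool = False) -> FingerprintClustering:
    """Group fingerprints by average-linkage clustering on Euclidean distance.

    ``on_zscores`` switches the clustering input to per-column z-scored
    vectors; by default the raw fingerprint vectors are clustered and the
    z-scoring only affects the display matrix.
    """
    if len(fps) < 2:
        raise ModelError("need at least two fingerprints to cluster")
    M = np.vstack([fp.vector for fp in fps])
    data = M
    if on_zscores:
        sd = M.std(axis=0, ddof=0)
        data = (M - M.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    Z = linkage(data, method="average", metric="euclidean")
    return FingerprintClustering(
        owners=[fp.owner for fp in fps], matrix=M, linkage=Z, leaf_order=leaves_list(Z)
    )


def sirna_score(
    fps_S1: Sequence[Fingerprint],
    fps_S2: Sequence[Fingerprint],
    normalized_pairs: bool = False,
) -> float:
    """Within/between fingerprint-distance ratio for two siRNA sets.

    ``score = [(Σ within-S1 d + Σ within-S2 d) / (|S1|+|S2|)] /
    [(Σ between d) / (|S1|·|S2|)]`` with unordered within-set pairs.  A low
    score means replicates of the same siRNA sit tighter together than
    fingerprints across siRNAs.  ``normalized_pairs`` replaces the set-size
    normalizer ``1/(|S1|+|S2|)`` by the actual within-pair count.
    """
    if len(fps_S1) < 2 or len(fps_S2) < 2:
        raise UndefinedScoreError("each siRNA set needs at least two fingerprints")
    V1 = [np.atleast_1d(np.asarray(fp.vector, dtype=float)) for fp in fps_S1]
    V2 = [np.atleast_1d(np.asarray(fp.vector, dtype=float)) for fp in fps_S2]
    within = sum(euclidean(a, b) for a, b in combinations(V1, 2)) + sum(
        euclidean(a, b) for a, b in combinations(V2, 2)
    )
    between = sum(euclidean(a, b) for a in V1 for b in V2)
    if between == 0.0:
        raise UndefinedScoreError("between-set distance is zero: fingerprint sets coincide")
    n_within = (
        len(V1) * (len(V1) - 1) / 2 + len(V2) * (len(V2) - 1) / 2
        if normalized_pairs
        else len(V1) + len(V2)
    )
    return (within / n_within) / (between / (len(V1) * len(V2)))
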