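"""Unsupervised views of the cohort: classical MDS, average-linkage
hierarchical clustering, and Gaussian-mixture subgroup selection.

Classical (Torgerson) multidimensional scaling of the Euclidean distances
between sample profiles gives the 2-D map in which tumours separate from
nontumoral tissue; average-linkage clustering of the same distances gives
the dendrogram; and a Gaussian mixture fitted to the MDS coordinates, with
the number of components chosen by BIC over {1, 2, 3}, probes for tumour
subgroups.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio.stats.ordination import pcoa
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_array

from .matrix import ExpressionMatrix


@dataclasses.dataclass
class MDSResult:
    coordinates: np.ndarray  # samples × k
    eigenvalues: np.ndarray  # k, non-increasing
    explained: np.ndarray    # fraction of positive-eigenvalue variance per axis
    sample_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"MDS{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


class ClassicalMDS(TransformerMixin, BaseEstimator):
    """Torgerson scaling of Euclidean distances (principal coordinates).

    ``fit_transform(X)`` takes samples × features and returns samples ×
    ``n_components`` coordinates whose pairwise distances reproduce the input
    Euclidean distances up to the spectral truncation.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        X = check_array(X, dtype=float)
        n = X.shape[0]
        if self.n_components >= n:
            raise ValueError(
                f"n_components={self.n_components} needs >= {self.n_components + 1} samples"
            )
        dm = squareform(pdist(X, metric="euclidean"))
        res = pcoa(dm, number_of_dimensions=n - 1)
        coords = res.samples.to_numpy()[:, : self.n_components]
        eig = res.eigvals.to_numpy()
        pos = eig[eig > 0]
        self.eigenvalues_ = eig[: self.n_components]
        self.explained_ = (
            self.eigenvalues_.clip(min=0) / pos.sum() if pos.size else self.eigenvalues_
        )
        self.embedding_ = coords
        return coords


def classical_mds(m: ExpressionMatrix, k: int = 2) -> MDSResult:
    """Classical MDS of sample profiles (samples as points, genes as axes)."""
    if k >= m.n_samples:
        raise ValueError(f"k={k} requires more than {m.n_samples} samples")
    est = ClassicalMDS(n_components=k)
    coords = est.fit_transform(m.values.T)
    return MDSResult(
        coordinates=coords,
        eigenvalues=est.eigenvalues_,
        explained=est.explained_,
        sample_ids=list(m.samples),
    )


# --------------------------------------------------------------------------
# Hierarchical clustering


@dataclasses.dataclass
class Dendrogram:
    """Agglomerative merge tree (scipy linkage encoding) over the samples."""

    linkage: np.ndarray  # (n-1) × 4 scipy linkage matrix
    sample_ids: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels (1..n_clusters) from cutting the tree."""
        return hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        """Nested-parenthesis export with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def hcluster(m: ExpressionMatrix, metric: str = "euclidean", linkage: str = "average") -> Dendrogram:
    """Average-linkage agglomerative clustering of samples."""
    if m.n_samples < 2:
        raise ValueError("clustering needs >= 2 samples")
    Z = hierarchy.linkage(m.values.T, method=linkage, metric=metric)
    return Dendrogram(linkage=Z, sample_ids=list(m.samples))


# --------------------------------------------------------------------------
# Gaussian-mixture subgroup selection


@dataclasses.dataclass
class GMMFit:
    n_components: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    bic: float
    assignments: np.ndarray
    bic_per_k: dict[int, float]


class GaussianMixtureSelector(BaseEstimator):
    """Fit diagonal-covariance Gaussian mixtures for each candidate component
    count and keep the minimal-BIC model.

    EM uses k-means++ seeding with ``n_init`` restarts at a fixed
    ``random_state``; results are fully reproducible.
    """

    def __init__(
        self,
        k_candidates=(1, 2, 3),
        n_init: int = 10,
        tol: float = 1e-8,
        max_iter: int = 500,
        random_state: int = 0,
    ):
        self.k_candidates = k_candidates
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        kmax = max(self.k_candidates)
        if X.shape[0] < 3 * kmax:
            raise ValueError(f"need >= {3 * kmax} samples for k up to {kmax}")
        fits = {}
        bics = {}
        for k in self.k_candidates:
            gm = GaussianMixture(
                n_components=k,
                covariance_type="diag",
                n_init=self.n_init,
                tol=self.tol,
                max_iter=self.max_iter,
                init_params="k-means++",
                random_state=self.random_state,
            )
            gm.fit(X)
            fits[k] = gm
            bics[k] = float(gm.bic(X))
        best_k = min(bics, key=bics.get)
        best = fits[best_k]
        if not best.converged_:
            raise RuntimeError(
                f"EM did not converge for the minimal-BIC model (k={best_k}) "
                f"after {self.n_init} restarts"
            )
        self.best_k_ = best_k
        self.bic_per_k_ = bics
        self.model_ = best
        self.labels_ = best.predict(X)
        return self

    def predict(self, X):
        return self.model_.predict(check_array(X, dtype=float))


def gmm_select(coords: np.ndarray, k_candidates=(1, 2, 3), random_state: int = 0) -> GMMFit:
    """BIC-selected Gaussian mixture on MDS coordinates."""
    sel = GaussianMixtureSelector(k_candidates=k_candidates, random_state=random_state)
    sel.fit(np.asarray(coords, dtype=float))
    gm = sel.model_
    return GMMFit(
        n_components=sel.best_k_,
        means=gm.means_,
        variances=gm.covariances_,
        weights=gm.weights_,
        bic=sel.bic_per_k_[sel.best_k_],
        assignments=sel.labels_,
        bic_per_k=sel.bic_per_k_,
    )
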