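"""Sample-structure views: PCA and agglomerative hierarchical clustering.

Both views treat samples as observations and probes as variables.
Missing beta values are mean-imputed per probe *for these views only*
(the calling machinery never imputes).  PCA uses probe-wise mean
centering without unit-variance scaling, since beta values are already
bounded and comparable across probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .io import BetaMatrix

__all__ = ["PCAResult", "Dendrogram", "pca", "hcluster"]


@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: pd.DataFrame                 # samples x components
    explained_variance_fraction: np.ndarray
    centering: np.ndarray                # per-probe means used for centering
    loadings: pd.DataFrame               # probes x components

    def frame(self) -> pd.DataFrame:
        return self.scores


@dataclass
class Dendrogram:
    """Agglomerative merge tree over samples.

    ``linkage_matrix`` is the scipy (n-1) x 4 encoding; ``cut(k)``
    returns flat cluster labels; ``to_newick()`` serializes leaves with
    branch lengths equal to merge-height differences.
    """

    sample_ids: list[str]
    linkage_matrix: np.ndarray | None

    def cut(self, k: int) -> pd.Series:
        if self.linkage_matrix is None:
            return pd.Series([1], index=self.sample_ids)
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids)

    def merge_heights(self) -> np.ndarray:
        if self.linkage_matrix is None:
            return np.array([])
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        if self.linkage_matrix is None:
            return f"{self.sample_ids[0]};"
        tree = hierarchy.to_tree(self.linkage_matrix)
        return _root_newick(tree, self.sample_ids)


def _root_newick(tree, sample_ids) -> str:
    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{sample_ids[node.id]}:{length:.6g}"
        return f"({walk(node.left, node.dist)},{walk(node.right, node.dist)}):{length:.6g}"

    if tree.is_leaf():
        return f"{sample_ids[tree.id]};"
    inner = f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)})"
    return inner + ";"


def _imputed_sample_matrix(beta: BetaMatrix, probe_subset=None) -> tuple[np.ndarray, list[str]]:
    b = beta.beta if probe_subset is None else beta.beta.loc[list(probe_subset)]
    X = b.to_numpy(dtype=float)
    if np.isnan(X).any():
        means = np.nanmean(X, axis=1, keepdims=True)
        means = np.where(np.isfinite(means), means, 0.0)
        X = np.where(np.isfinite(X), X, np.broadcast_to(means, X.shape))
    return X.T.copy(), list(b.columns)  # samples x probes


def pca(beta: BetaMatrix, n_components: int = 2, probe_subset=None) -> PCAResult:
    """Principal components of the sample beta profiles via SVD.

    Deterministic sign convention: within each component the loading of
    largest magnitude is made positive.
    """
    D, samples = _imputed_sample_matrix(beta, probe_subset)
    n, m = D.shape
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    max_k = min(n, m)
    if n_components > max_k:
        warnings.warn(
            f"n_components={n_components} clipped to {max_k}", stacklevel=2
        )
        n_components = max_k
    center = D.mean(axis=0)
    Dc = D - center
    U, s, Vt = np.linalg.svd(Dc, full_matrices=False)
    total = float((s ** 2).sum())
    explained = (s ** 2) / total if total > 0 else np.zeros_like(s)
    for comp in range(len(s)):
        j = int(np.argmax(np.abs(Vt[comp])))
        if Vt[comp, j] < 0:
            Vt[comp] *= -1
            U[:, comp] *= -1
    scores = U[:, :n_components] * s[:n_components]
    cols = [f"PC{i + 1}" for i in range(n_components)]
    probe_index = (beta.beta.index if probe_subset is None
                   else pd.Index(list(probe_subset)))
    return PCAResult(
        sample_ids=samples,
        scores=pd.DataFrame(scores, index=samples, columns=cols),
        explained_variance_fraction=explained[:n_components],
        centering=center,
        loadings=pd.DataFrame(Vt[:n_components].T, index=probe_index, columns=cols),
    )


def hcluster(
    beta: BetaMatrix,
    probe_subset=None,
    linkage: str = "average",
    metric: str = "euclidean",
) -> Dendrogram:
    """Agglomerative clustering of samples (default average/Euclidean).

    Supervised mode passes the called probes as ``probe_subset``;
    unsupervised mode clusters on every probe.
    """
    if probe_subset is not None and len(list(probe_subset)) == 0:
        raise ValueError("probe_subset must be non-empty")
    D, samples = _imputed_sample_matrix(beta, probe_subset)
    if len(samples) == 1:
        return Dendrogram(sample_ids=samples, linkage_matrix=None)
    Z = hierarchy.linkage(D, method=linkage, metric=metric)
    return Dendrogram(sample_ids=samples, linkage_matrix=Z)
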