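"""Pairwise-RMSD hierarchical clustering with medoid representatives.

Similarity between conformers is the minimum Cα RMSD after optimal rigid
superposition (Kabsch, proper rotations only).  The full matrix is computed
from per-pair 3×3 cross-covariances: for centered coordinate sets X_i, X_j
with squared norms G_i, G_j,

    rmsd_ij^2 = (G_i + G_j - 2 * (s1 + s2 + sign(det C) * s3)) / n

where s1 >= s2 >= s3 are the singular values of C = X_i^T X_j.  This lets
millions of pairs be evaluated with batched 3×3 eigendecompositions instead
of per-pair SVD loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, fcluster, linkage
from scipy.spatial.distance import squareform

from .ensemble import Ensemble
from .errors import ContractError
from .geometry import rmsd_after_superposition

_LINKAGE_METHODS = ("average", "complete", "ward")


@dataclass
class ClusterParams:
    """Clustering tunables.

    mode
        ``maxclust`` cuts the dendrogram into a fixed number of clusters
        (bounds the pipeline's growth); ``threshold`` cuts at an RMSD height.
    maxclust
        Requested cluster count; the default 60 makes a 5-generation run
        with ≥60 pooled conformers per generation emit 300 conformers.
    threshold
        RMSD cut height in Å (mode='threshold' only).
    linkage
        Agglomeration rule: 'average' (default), 'complete' or 'ward'.
    """

    mode: str = "maxclust"
    maxclust: int = 60
    threshold: float | None = None
    linkage: str = "average"

    def validate(self) -> None:
        if self.mode not in ("maxclust", "threshold"):
            raise ContractError("mode must be 'maxclust' or 'threshold'")
        if self.mode == "maxclust" and self.maxclust < 1:
            raise ContractError("maxclust must be >= 1")
        if self.mode == "threshold" and (self.threshold is None or self.threshold <= 0):
            raise ContractError("threshold mode needs threshold > 0")
        if self.linkage not in _LINKAGE_METHODS:
            raise ContractError(f"linkage must be one of {_LINKAGE_METHODS}")


@dataclass
class ClusterResult:
    """Labels (1..K), medoid representative indices and cluster sizes."""

    labels: np.ndarray
    representatives: np.ndarray = field(default=None)  # type: ignore[assignment]
    sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0


def _sum_singular_values(cov: np.ndarray) -> np.ndarray:
    """sign-corrected singular-value sums of a (..., 3, 3) batch."""
    gram = np.einsum("...ki,...kj->...ij", cov, cov)
    lam = np.linalg.eigvalsh(gram)          # ascending
    sigma = np.sqrt(np.clip(lam, 0.0, None))
    det_sign = np.sign(np.linalg.det(cov))
    det_sign[det_sign == 0] = 1.0
    return sigma[..., 2] + sigma[..., 1] + det_sign * sigma[..., 0]


def pairwise_rmsd(
    ensemble: Ensemble, calpha_mask: np.ndarray, chunk: int = 256
) -> np.ndarray:
    """Symmetric M×M matrix of minimum superposed Cα RMSDs.

    ``chunk`` bounds the memory of the batched cross-covariance computation;
    it does not affect the result.
    """
    calpha_mask = np.asarray(calpha_mask, dtype=bool)
    n_ca = int(calpha_mask.sum())
    if n_ca < 3:
        raise ContractError(f"pairwise RMSD needs >= 3 Cα atoms, got {n_ca}")
    x = ensemble.coords[:, calpha_mask, :]
    m = x.shape[0]
    xc = x - x.mean(axis=1, keepdims=True)
    g = np.einsum("mik,mik->m", xc, xc)

    dist = np.zeros((m, m))
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        cov = np.einsum("ank,bnl->abkl", xc[start:stop], xc)
        d = _sum_singular_values(cov)
        sq = (g[start:stop, None] + g[None, :] - 2.0 * d) / n_ca
        dist[start:stop] = np.sqrt(np.clip(sq, 0.0, None))
    dist = 0.5 * (dist + dist.T)
    np.fill_diagonal(dist, 0.0)
    # the G_i + G_j - 2D form cancels catastrophically near zero; recompute
    # near-identical pairs from the explicit superposition residual
    near = np.argwhere(np.triu(dist < 1e-4, k=1))
    for i, j in near:
        exact = rmsd_after_superposition(x[i], x[j])
        dist[i, j] = dist[j, i] = exact
    return dist


def _validate_distance_matrix(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ContractError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ContractError("distance matrix must be symmetric")
    if np.any(dist < 0):
        raise ContractError("distance matrix must be non-negative")
    return 0.5 * (dist + dist.T)


def _relabel_by_first_appearance(raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        labels[i] = mapping[r]
    return labels


def cluster(dist: np.ndarray, params: ClusterParams | None = None) -> ClusterResult:
    """Agglomerative clustering of a distance matrix; labels are 1..K.

    In ``maxclust`` mode the dendrogram is cut into exactly
    ``min(maxclust, M)`` clusters; in ``threshold`` mode at the given RMSD
    height.  Labels are renumbered in order of first appearance, so the
    result is deterministic for a given matrix.
    """
    params = params or ClusterParams()
    params.validate()
    dist = _validate_distance_matrix(dist)
    m = dist.shape[0]
    if m == 1:
        labels = np.array([1])
    else:
        condensed = squareform(dist, checks=False)
        z = linkage(condensed, method=params.linkage)
        if params.mode == "maxclust":
            k = min(params.maxclust, m)
            raw = cut_tree(z, n_clusters=k).ravel()
        else:
            raw = fcluster(z, t=params.threshold, criterion="distance")
        labels = _relabel_by_first_appearance(raw)
    return ClusterResult(labels=labels)


def representatives(dist: np.ndarray, result: ClusterResult) -> ClusterResult:
    """Fill in per-cluster medoids (summed-distance minimizers).

    Ties are broken toward the lowest conformer index.
    """
    dist = _validate_distance_matrix(dist)
    labels = result.labels
    k = result.n_clusters
    reps = np.empty(k, dtype=int)
    sizes = np.empty(k, dtype=int)
    for c in range(1, k + 1):
        members = np.nonzero(labels == c)[0]
        sub = dist[np.ix_(members, members)]
        reps[c - 1] = members[int(np.argmin(sub.sum(axis=1)))]
        sizes[c - 1] = len(members)
    return ClusterResult(labels=labels, representatives=reps, sizes=sizes)


def save_distance_matrix(dist: np.ndarray, path) -> None:
    """Write the distance matrix as a plain-text square matrix."""
    np.savetxt(path, np.asarray(dist, dtype=float), fmt="%.6f")
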