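"""Embed a compound distance matrix, pick k by silhouette, cluster, sample.

The pipeline mirrors the ensemble-reduction workflow: metric
multidimensional scaling of the compound dissimilarity matrix, k-means over
a candidate range of cluster counts scored by mean silhouette, and per
cluster the lowest-energy member as representative (nearest-to-centroid
when energies are absent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.manifold import MDS
from sklearn.metrics import silhouette_score

from .dissimilarity import DEFAULT_ISOMORPHISM_CAP, DissimilarityMatrix, compound_matrix
from .ensemble_io import Ensemble
from .errors import ContractError

__all__ = ["ClusterConfig", "ClusteringResult", "embed", "choose_k", "cluster"]

#: Below this best-silhouette value the ensemble is treated as one cluster.
SINGLE_CLUSTER_THRESHOLD = 0.40


@dataclass
class ClusterConfig:
    metrics: tuple[str, ...] = ("rmsd", "dihedral", "energy")
    weights: dict[str, float] | None = None
    k_max: int = 10
    dims: int | None = None  # default min(n - 1, 5)
    seed: int = 2024
    single_cluster_threshold: float = SINGLE_CLUSTER_THRESHOLD
    isomorphism_cap: int = DEFAULT_ISOMORPHISM_CAP
    kmeans_restarts: int = 10


@dataclass
class ClusteringResult:
    """Partition of an ensemble plus the model-selection trace."""

    labels: np.ndarray
    k: int
    silhouette_by_k: dict[int, float]
    representatives: list[int]
    seed: int
    embedding: np.ndarray | None = None
    stress: float | None = None
    dissimilarity: DissimilarityMatrix | None = None

    def members(self, c: int) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.labels == c)]


def embed(D: DissimilarityMatrix | np.ndarray, dims: int, seed: int) -> tuple[np.ndarray, float]:
    """Metric multidimensional scaling of a dissimilarity matrix.

    Returns ``(coords, stress)``; coordinates are deterministic for a fixed
    seed.
    """
    values = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ContractError("embedding requires at least 2 structures")
    if dims < 1:
        raise ContractError("dims must be >= 1")
    mds = MDS(
        n_components=dims,
        dissimilarity="precomputed",
        random_state=seed,
        n_init=4,
        normalized_stress=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn chatters about stress on degenerate input
        coords = mds.fit_transform(values)
    return coords, float(mds.stress_)


def _kmeans(coords: np.ndarray, k: int, seed: int, restarts: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return km.fit_predict(coords)


def choose_k(
    coords: np.ndarray,
    k_max: int = 10,
    seed: int = 2024,
    single_cluster_threshold: float = SINGLE_CLUSTER_THRESHOLD,
    restarts: int = 10,
) -> tuple[int, dict[int, float]]:
    """Select the number of clusters by mean silhouette over k-means runs.

    Candidates are ``k = 2 .. min(k_max, n - 1)``; ties prefer the smaller k.
    Returns ``k = 1`` when fewer than 3 points exist or the best silhouette
    falls below ``single_cluster_threshold``.
    """
    if k_max < 1:
        raise ContractError("k_max must be >= 1")
    n = coords.shape[0]
    silhouette_by_k: dict[int, float] = {}
    if n < 3 or k_max < 2:
        return 1, silhouette_by_k
    for k in range(2, min(k_max, n - 1) + 1):
        labels = _kmeans(coords, k, seed, restarts)
        if len(np.unique(labels)) < 2:
            silhouette_by_k[k] = -1.0
            continue
        silhouette_by_k[k] = float(silhouette_score(coords, labels))
    if not silhouette_by_k:
        return 1, silhouette_by_k
    best_k = min(silhouette_by_k, key=lambda k: (-silhouette_by_k[k], k))
    if silhouette_by_k[best_k] < single_cluster_threshold:
        return 1, silhouette_by_k
    return best_k, silhouette_by_k


def pick_representatives(
    e: Ensemble, labels: np.ndarray, k: int, embedding: np.ndarray | None = None
) -> list[int]:
    """Per cluster: lowest-energy member (ties to the lowest index).

    Without energies the member nearest its cluster centroid in the
    embedding is used instead.
    """
    reps: list[int] = []
    use_energy = e.has_energies()
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            raise ContractError(f"cluster {c} is empty")
        if use_energy:
            energies = np.array([e[int(i)].energy for i in members])
            reps.append(int(members[int(np.argmin(energies))]))
        else:
            if embedding is None:
                reps.append(int(members[0]))
            else:
                centroid = embedding[members].mean(axis=0)
                d = np.linalg.norm(embedding[members] - centroid, axis=1)
                reps.append(int(members[int(np.argmin(d))]))
    return reps


def cluster(e: Ensemble, config: ClusterConfig | None = None) -> ClusteringResult:
    """Full pipeline: compound matrix, MDS embedding, silhouette k, k-means.

    Single-frame ensembles short-circuit to one cluster with frame 0 as
    representative.
    """
    config = config or ClusterConfig()
    n = len(e)
    if n == 1:
        return ClusteringResult(
            labels=np.zeros(1, dtype=int),
            k=1,
            silhouette_by_k={},
            representatives=[0],
            seed=config.seed,
        )
    D = compound_matrix(
        e,
        metrics=config.metrics,
        weights=config.weights,
        isomorphism_cap=config.isomorphism_cap,
    )
    dims = config.dims if config.dims is not None else min(n - 1, 5)
    coords, stress = embed(D, dims=dims, seed=config.seed)
    k, trace = choose_k(
        coords,
        k_max=config.k_max,
        seed=config.seed,
        single_cluster_threshold=config.single_cluster_threshold,
        restarts=config.kmeans_restarts,
    )
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        labels = _kmeans(coords, k, config.seed, config.kmeans_restarts)
        labels = _canonicalize_labels(labels)
        k = len(np.unique(labels))
    reps = pick_representatives(e, labels, k, embedding=coords)
    return ClusteringResult(
        labels=labels,
        k=k,
        silhouette_by_k=trace,
        representatives=reps,
        seed=config.seed,
        embedding=coords,
        stress=stress,
        dissimilarity=D,
    )


def _canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by first appearance so output is order-stable."""
    out = np.empty_like(labels)
    seen: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen)
        out[i] = seen[lab]
    return out
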