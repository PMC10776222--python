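"""2-D embedding of the distance matrix, projection validation, and
soft density-based clustering.

The pairwise DFTW matrix is projected to two dimensions with UMAP
(``n_neighbors=30``, ``min_dist=0``, precomputed metric); projection
quality is checked with the rank-based trustworthiness and continuity
measures (1 = perfect preservation). Clusters are then found on the 2-D
coordinates with HDBSCAN (``min_samples=30``, ``min_cluster_size=30``),
and every unit receives a *soft membership* vector over the K clusters:
a point is not assigned to a single cluster but to all of them with
varying probabilities, so that sparse/intermediate units still
contribute to downstream repertoire indices instead of being dropped.

Soft memberships are heavy-tailed (Cauchy) kernel affinities to each
cluster, ``r_c² / (r_c² + d_c(x)²)``, renormalized to the simplex.
When the original distance matrix is supplied, ``d_c(x)`` is the
distance from the unit to its nearest member of cluster ``c`` in the
*original* (acoustic) space and ``r_c`` the typical within-cluster
nearest-neighbor distance — membership then reflects acoustic
intermediacy and is unaffected by the arbitrary absolute scale of the
2-D layout; otherwise the same kernel runs on embedding coordinates
(centroid distance, RMS radius). The heavy tail keeps every membership
strictly positive, so intermediate points grade smoothly between
clusters instead of snapping to one-hot vectors; a point with vanishing
affinity to every cluster (degenerate geometry) gets the uniform vector
1/K, which maximizes its gradation — by construction such points are
intermediate between clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import HDBSCAN

NOISE = -1


@dataclass
class Embedding:
    coords: np.ndarray  # (n_units, 2)
    unit_ids: list[str]
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[0] != len(self.unit_ids):
            raise ValueError("coords row count must equal unit count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")


@dataclass
class SoftMembership:
    """Per-unit probability vector over K clusters plus a hard label.

    ``hard_label`` is a cluster index in [0, K) or :data:`NOISE` (-1)
    for density-unassignable points.
    """

    probs: np.ndarray
    hard_label: int
    unit_id: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 1 or self.probs.size < 1:
            raise ValueError("probs must be a nonempty vector")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) >= 1e-9:
            raise ValueError("probs must lie on the simplex")

    @property
    def K(self) -> int:
        return self.probs.size


def _validate_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-5):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distance matrix must be nonnegative")
    return D


def embed(
    dist,
    n_neighbors: int = 30,
    min_dist: float = 0.0,
    seed: int = 20240110,
) -> Embedding:
    """UMAP projection of a precomputed distance matrix to 2-D.

    ``n_neighbors`` is reduced (with a warning) when the dataset has too
    few points. Fixed seed ⇒ reproducible coordinates.
    """
    import umap  # deferred: slow import

    values = dist.values if hasattr(dist, "values") else dist
    D = _validate_distance_matrix(values)
    unit_ids = (
        list(dist.unit_ids) if hasattr(dist, "unit_ids") else [f"unit_{i:06d}" for i in range(len(D))]
    )
    n = D.shape[0]
    if n <= n_neighbors:
        warnings.warn(
            f"n_neighbors={n_neighbors} >= n_points={n}; reduced to {max(2, n - 1)}",
            stacklevel=2,
        )
        n_neighbors = max(2, n - 1)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", module="sklearn")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric="precomputed",
            random_state=seed,
        )
        coords = reducer.fit_transform(D)
    return Embedding(
        coords=np.asarray(coords, dtype=np.float64),
        unit_ids=unit_ids,
        seed=seed,
        params={"n_neighbors": n_neighbors, "min_dist": min_dist},
    )


def _neighbor_ranks(D: np.ndarray) -> np.ndarray:
    """ranks[i, j] = rank of j among i's neighbors (1 = nearest, self excluded).

    Ties resolve by point index (stable argsort), making both quality
    measures deterministic.
    """
    n = D.shape[0]
    order = np.argsort(D + np.diag(np.full(n, np.inf)), axis=1, kind="stable")
    ranks = np.empty((n, n), dtype=np.int64)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(n)[None, :] + 1  # self lands at rank n
    return ranks


def _rank_preservation(D_from: np.ndarray, D_to: np.ndarray, k: int) -> float:
    """Shared core of trustworthiness/continuity (Venna & Kaski).

    Penalizes points that are k-neighbors in ``D_to`` but not in
    ``D_from``, by their rank excess in ``D_from``.
    """
    n = D_from.shape[0]
    if not 1 <= k < n / 2:
        raise ValueError(f"k must satisfy 1 <= k < n/2 (got k={k}, n={n})")
    ranks_from = _neighbor_ranks(D_from)
    ranks_to = _neighbor_ranks(D_to)
    intruders = (ranks_to <= k) & (ranks_from > k)
    penalty = np.sum((ranks_from - k)[intruders])
    return 1.0 - 2.0 / (n * k * (2 * n - 3 * k - 1)) * penalty


def _embedding_distances(emb) -> np.ndarray:
    coords = emb.coords if hasattr(emb, "coords") else np.asarray(emb, dtype=np.float64)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def trustworthiness(dist, emb, k: int = 30) -> float:
    """Are embedded k-neighborhoods genuine? 1 = no intruders.

    Points that enter a point's embedded k-neighborhood without being
    original-space neighbors are penalized by their original rank excess.
    """
    D = _validate_distance_matrix(dist.values if hasattr(dist, "values") else dist)
    return _rank_preservation(D, _embedding_distances(emb), k)


def continuity(dist, emb, k: int = 30) -> float:
    """Are genuine k-neighborhoods preserved? 1 = no neighbors missing.

    Original-space neighbors missing from the embedded k-neighborhood
    are penalized by their embedded rank excess (the symmetric
    counterpart of :func:`trustworthiness`).
    """
    D = _validate_distance_matrix(dist.values if hasattr(dist, "values") else dist)
    return _rank_preservation(_embedding_distances(emb), D, k)


def cluster_soft(
    emb,
    min_samples: int = 30,
    min_cluster_size: int = 30,
    dist=None,
) -> tuple[list[SoftMembership], int]:
    """HDBSCAN on the 2-D embedding with soft membership vectors.

    ``dist`` (the original pairwise distance matrix, optional) anchors
    the soft memberships in acoustic space; without it the kernel runs
    on the embedding coordinates. Returns one :class:`SoftMembership`
    per unit (simplex over the K clusters; hard label = HDBSCAN label,
    noise = -1) and K. When no cluster is found at all, K = 1 and every
    point is uniform noise.
    """
    coords = emb.coords if hasattr(emb, "coords") else np.asarray(emb, dtype=np.float64)
    unit_ids = list(getattr(emb, "unit_ids", [f"unit_{i:06d}" for i in range(len(coords))]))
    n = coords.shape[0]
    if n < min_cluster_size:
        raise ValueError(f"{n} points < min_cluster_size={min_cluster_size}")

    labels = HDBSCAN(
        min_samples=min_samples, min_cluster_size=min_cluster_size, copy=True
    ).fit_predict(coords)
    cluster_ids = np.unique(labels[labels >= 0])
    K = int(cluster_ids.size)
    if K == 0:
        uniform = np.array([1.0])
        return [SoftMembership(uniform.copy(), NOISE, uid) for uid in unit_ids], 1

    # relabel clusters 0..K-1 in HDBSCAN order
    relabel = {int(c): i for i, c in enumerate(cluster_ids)}

    if dist is not None:
        D = _validate_distance_matrix(dist.values if hasattr(dist, "values") else dist)
        if D.shape[0] != n:
            raise ValueError("distance matrix size does not match embedding")
        d_to = np.empty((n, K))
        radii = np.empty(K)
        for k, c in enumerate(cluster_ids):
            members = np.flatnonzero(labels == c)
            sub = D[:, members].copy()
            sub[members, np.arange(members.size)] = np.inf  # selfless nearest member
            d_to[:, k] = sub.min(axis=1)
            radii[k] = max(np.median(d_to[members, k]), 1e-9)
    else:
        centroids = np.stack([coords[labels == c].mean(axis=0) for c in cluster_ids])
        d_to = np.sqrt(np.sum((coords[:, None, :] - centroids[None, :, :]) ** 2, axis=-1))
        radii = np.array(
            [
                max(np.sqrt(np.mean(d_to[labels == c, i] ** 2)), 1e-9)
                for i, c in enumerate(cluster_ids)
            ]
        )

    raw = radii[None, :] ** 2 / (radii[None, :] ** 2 + d_to**2)
    sums = raw.sum(axis=1)
    probs = np.where(sums[:, None] > 0, raw / np.maximum(sums, 1e-300)[:, None], 1.0 / K)

    memberships = []
    for i, uid in enumerate(unit_ids):
        hard = relabel[int(labels[i])] if labels[i] >= 0 else NOISE
        p = probs[i] / probs[i].sum()  # exact simplex
        memberships.append(SoftMembership(p, hard, uid))
    return memberships, K


def assignment_summary(memberships: list[SoftMembership]) -> tuple[int, float, float]:
    """(K, fraction hard-assigned, fraction noise); the fractions sum to 1."""
    if not memberships:
        raise ValueError("empty membership list")
    K = memberships[0].K
    n_noise = sum(1 for m in memberships if m.hard_label == NOISE)
    frac_noise = n_noise / len(memberships)
    return K, 1.0 - frac_noise, frac_noise
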