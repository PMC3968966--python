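"""Distance-matrix clustering: PAM, validity indices, and classical MDS.

Partitioning Around Medoids is run from a deterministic greedy BUILD seeding
followed by best-improvement SWAP, plus seeded random restarts; the lowest
total cost wins.  Because only a dissimilarity matrix exists (the KL
dissimilarity is not Euclidean and need not satisfy the triangle
inequality), scatter in the Davies-Bouldin index is measured around medoids
rather than centroids, and MDS embeddings clamp negative eigenvalues to
zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .distance import DistanceMatrix

__all__ = [
    "ClusteringResult",
    "DegenerateClusteringError",
    "pam_cluster",
    "silhouette_index",
    "davies_bouldin_index",
    "dunn_index",
    "select_num_clusters",
    "classical_mds",
]


class DegenerateClusteringError(ValueError):
    """Raised when a validity index is undefined for the given partition."""


@dataclass
class ClusteringResult:
    """PAM output: labels are 0-based cluster ids; ``medoids[k]`` is the
    subject index serving as center of cluster ``k``."""

    n_clusters: int
    labels: np.ndarray
    medoids: np.ndarray
    total_cost: float
    indices: dict[str, float] | None = None


def _distance_values(D) -> np.ndarray:
    vals = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(vals, vals.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    return vals


def _assign(D: np.ndarray, medoids: np.ndarray):
    medoids = np.sort(medoids)
    dist = D[:, medoids]
    labels = np.argmin(dist, axis=1)  # first minimum -> lowest medoid index
    cost = float(dist[np.arange(D.shape[0]), labels].sum())
    return medoids, labels, cost


def _build(D: np.ndarray, K: int) -> np.ndarray:
    N = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < K:
        current = np.min(D[:, medoids], axis=1)
        best_gain, best_c = -np.inf, None
        for c in range(N):
            if c in medoids:
                continue
            gain = float(np.maximum(current - D[:, c], 0.0).sum())
            if gain > best_gain:
                best_gain, best_c = gain, c
        medoids.append(best_c)
    return np.asarray(sorted(medoids))


def _swap(D: np.ndarray, medoids: np.ndarray):
    N = D.shape[0]
    medoids, labels, cost = _assign(D, medoids)
    while True:
        best = None
        med_set = set(medoids.tolist())
        for mi in range(len(medoids)):
            for h in range(N):
                if h in med_set:
                    continue
                cand = medoids.copy()
                cand[mi] = h
                cand, lab, c = _assign(D, cand)
                if c < cost - 1e-12 and (best is None or c < best[2]):
                    best = (cand, lab, c)
        if best is None:
            return medoids, labels, cost
        medoids, labels, cost = best


def pam_cluster(
    D, K: int, n_restarts: int = 5, seed: int = 0
) -> ClusteringResult:
    """Partitioning Around Medoids with BUILD seeding plus random restarts."""
    vals = _distance_values(D)
    N = vals.shape[0]
    if not 2 <= K <= N - 1:
        raise ValueError(f"K={K} out of the valid range [2, {N - 1}]")
    medoids, labels, cost = _swap(vals, _build(vals, K))
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        init = rng.choice(N, size=K, replace=False)
        m, lab, c = _swap(vals, init)
        if c < cost - 1e-12:
            medoids, labels, cost = m, lab, c
    return ClusteringResult(
        n_clusters=K, labels=labels, medoids=medoids, total_cost=cost
    )


def _check_partition(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise DegenerateClusteringError("validity indices need >= 2 clusters")
    return uniq


def silhouette_index(D, labels) -> float:
    """Mean silhouette width from a precomputed dissimilarity matrix.

    Subjects in singleton clusters score 0.  The one-point KL estimator can
    produce (slightly) negative dissimilarities, which scikit-learn refuses;
    those matrices fall back to the direct formula.
    """
    vals = _distance_values(D)
    labels = np.asarray(labels)
    _check_partition(labels)
    if (vals >= 0).all():
        return float(silhouette_score(vals, labels, metric="precomputed"))
    n = vals.shape[0]
    widths = np.zeros(n)
    for i in range(n):
        own = np.flatnonzero((labels == labels[i]) & (np.arange(n) != i))
        if own.size == 0:
            continue
        a = vals[i, own].mean()
        b = min(vals[i, labels == k].mean() for k in np.unique(labels) if k != labels[i])
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(widths.mean())


def davies_bouldin_index(D, labels, medoids) -> float:
    """Medoid-based Davies-Bouldin index (lower is better).

    Cluster scatter ``S_k`` is the mean distance of cluster members to their
    medoid; separation ``M_kj`` is the medoid-to-medoid distance.
    """
    vals = _distance_values(D)
    labels = np.asarray(labels)
    medoids = np.asarray(medoids)
    uniq = _check_partition(labels)
    K = uniq.size
    if medoids.size != K:
        raise ValueError("one medoid per cluster is required")
    scatter = np.array(
        [vals[labels == k, medoids[i]].mean() for i, k in enumerate(uniq)]
    )
    total = 0.0
    for i in range(K):
        worst = -np.inf
        for j in range(K):
            if i == j:
                continue
            M = vals[medoids[i], medoids[j]]
            if M <= 0:
                raise DegenerateClusteringError(
                    "coincident medoids: Davies-Bouldin index undefined"
                )
            worst = max(worst, (scatter[i] + scatter[j]) / M)
        total += worst
    return float(total / K)


def dunn_index(D, labels) -> float:
    """Single-linkage separation over complete diameter (higher is better)."""
    vals = _distance_values(D)
    labels = np.asarray(labels)
    uniq = _check_partition(labels)
    members = [np.flatnonzero(labels == k) for k in uniq]
    diam = 0.0
    for idx in members:
        if idx.size > 1:
            diam = max(diam, float(vals[np.ix_(idx, idx)].max()))
    sep = np.inf
    for a, b in itertools.combinations(range(len(members)), 2):
        sep = min(sep, float(vals[np.ix_(members[a], members[b])].min()))
    if diam == 0.0:
        if sep == 0.0:
            raise DegenerateClusteringError("all pairwise distances are zero")
        return float("inf")
    return sep / diam


def select_num_clusters(
    D, k_range, n_restarts: int = 5, seed: int = 0
) -> tuple[int, pd.DataFrame, dict[int, ClusteringResult]]:
    """Run PAM over a range of K and pick the Dunn-maximizing K.

    Returns ``(best_k, index_table, results_by_k)``.  The table has one row
    per K with the Davies-Bouldin, Silhouette and Dunn indices.  Ties in the
    Dunn index break toward the smaller K.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("empty K range")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(k_range)) % (2**31)
    rows = []
    results: dict[int, ClusteringResult] = {}
    for k, s in zip(k_range, seeds):
        res = pam_cluster(D, k, n_restarts=n_restarts, seed=int(s))
        try:
            db = davies_bouldin_index(D, res.labels, res.medoids)
        except DegenerateClusteringError:
            db = np.nan
        sil = silhouette_index(D, res.labels)
        try:
            dunn = dunn_index(D, res.labels)
        except DegenerateClusteringError:
            dunn = np.nan
        res.indices = {"davies_bouldin": db, "silhouette": sil, "dunn": dunn}
        results[k] = res
        rows.append(
            {"n_clusters": k, "davies_bouldin": db, "silhouette": sil, "dunn": dunn}
        )
    table = pd.DataFrame(rows).set_index("n_clusters")
    dunn_vals = table["dunn"].to_numpy()
    if np.isnan(dunn_vals).all():
        raise DegenerateClusteringError("Dunn index undefined for every K")
    best_pos = int(np.nanargmax(dunn_vals))  # first maximum -> smallest K
    best_k = k_range[best_pos]
    return best_k, table, results


def classical_mds(D, dims: int = 3) -> np.ndarray:
    """Torgerson (classical) multidimensional scaling.

    Double-centers the squared dissimilarities and embeds on the top
    eigenvectors scaled by the square roots of their eigenvalues.  Negative
    eigenvalues (the dissimilarity need not be Euclidean) are clamped to
    zero.
    """
    vals = _distance_values(D)
    N = vals.shape[0]
    if dims > N - 1:
        raise ValueError(f"dims={dims} exceeds N-1={N - 1}")
    J = np.eye(N) - np.ones((N, N)) / N
    B = -0.5 * J @ (vals**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1][:dims]
    lam = np.maximum(eigval[order], 0.0)
    return eigvec[:, order] * np.sqrt(lam)
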