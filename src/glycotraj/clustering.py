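"""Deterministic k-means over superposed coordinates with Davies-Bouldin
model selection.

Frames are superposed onto the iterative mean structure and flattened, so
Euclidean row distance divided by sqrt(n_atoms) approximates pairwise RMSD
(centroid arithmetic needs a vector space; the residual alignment error of
this approximation is small and bounded by tests).  Initialization is
seed-free and deterministic: frames are ranked by local density and accepted
greedily subject to a diversity (minimum-separation) constraint, in the
spirit of density-based deterministic initializers for MD clustering.  The
number of clusters is chosen by the lowest Davies-Bouldin index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conformation import apply_transform, mean_structure, superpose
from .model import Trajectory


def feature_matrix(traj: Trajectory, selection: np.ndarray) -> np.ndarray:
    """(n_frames, 3 * n_sel) matrix of superposed, flattened coordinates."""
    sel = np.asarray(selection, int)
    if sel.size == 0:
        raise ValueError("empty selection for clustering features")
    if traj.n_frames < 2:
        raise ValueError("clustering needs at least 2 frames")
    mean = mean_structure(traj, sel)
    rows = []
    for frame in traj.frames:
        rot, trans, _ = superpose(frame.coordinates, mean, sel)
        rows.append(apply_transform(frame.coordinates[sel], rot, trans).ravel())
    return np.array(rows)


def _density_diversity_seeds(features: np.ndarray, k: int, n_neighbors: int = 10) -> np.ndarray:
    """Deterministic seed selection: densest frames first, subject to being
    farther than the running k-th diversity quantile from chosen seeds."""
    n = features.shape[0]
    m = min(n_neighbors, n - 1)
    from scipy.spatial.distance import pdist, squareform

    dist = squareform(pdist(features))
    density_rank = np.argsort(np.sort(dist, axis=1)[:, 1 : m + 1].mean(axis=1), kind="stable")
    min_sep = np.quantile(dist[np.triu_indices(n, 1)], 1.0 / max(k, 2))
    seeds: list[int] = []
    for idx in density_rank:
        if all(dist[idx, s] > min_sep for s in seeds):
            seeds.append(int(idx))
        if len(seeds) == k:
            break
    # relax the separation constraint if too few qualified
    for idx in density_rank:
        if len(seeds) == k:
            break
        if idx not in seeds:
            seeds.append(int(idx))
    return np.array(seeds[:k])


def kmeans_deterministic(
    features: np.ndarray, k: int, max_iter: int = 500, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd's k-means with deterministic density-diversity initialization.

    Identical input always yields identical output (no randomness anywhere).
    Returns (labels, centroids).
    """
    x = np.asarray(features, float)
    n = x.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} frames")
    if k == 1:
        return np.zeros(n, dtype=int), x.mean(axis=0, keepdims=True)
    centroids = x[_density_diversity_seeds(x, k)].copy()
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        new_centroids = centroids.copy()
        for c in range(k):
            members = x[labels == c]
            if len(members):
                new_centroids[c] = members.mean(axis=0)
        shift = np.linalg.norm(new_centroids - centroids, axis=1).max()
        centroids = new_centroids
        if shift < tol:
            break
    return labels, centroids


def davies_bouldin(features: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst-case
    (s_i + s_j) / d(c_i, c_j) ratio, with s the mean distance to centroid.
    Lower is better."""
    x = np.asarray(features, float)
    labels = np.asarray(labels, int)
    k = centroids.shape[0]
    if k < 2:
        raise ValueError("Davies-Bouldin needs at least 2 clusters")
    s = np.empty(k)
    for c in range(k):
        members = x[labels == c]
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty")
        s[c] = np.linalg.norm(members - centroids[c], axis=1).mean()
    db = 0.0
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(centroids[i] - centroids[j])
            worst = max(worst, (s[i] + s[j]) / d)
        db += worst
    return db / k


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray
    populations: np.ndarray  # fractions, descending
    db_by_k: dict[int, float]
    representative_frames: np.ndarray  # frame index per cluster, same order as populations
    centroids: np.ndarray


def select_k(
    features: np.ndarray,
    k_range: range | list[int] | None = None,
    second_derivative: bool = False,
) -> ClusterResult:
    """Cluster for each k, choose the k with the lowest DB index (ties go to
    the smallest k), and report populations and representative frames.

    ``second_derivative=True`` instead picks the k maximizing the discrete
    second difference of the DB curve (an elbow criterion).
    """
    x = np.asarray(features, float)
    n = x.shape[0]
    ks = list(k_range) if k_range is not None else list(range(2, min(30, n - 1) + 1))
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError("k_range must lie within [2, n_frames - 1]")
    results = {}
    db_by_k: dict[int, float] = {}
    for k in ks:
        labels, centroids = kmeans_deterministic(x, k)
        if len(np.unique(labels)) < k:
            continue  # degenerate solution for this k
        db_by_k[k] = davies_bouldin(x, labels, centroids)
        results[k] = (labels, centroids)
    if not db_by_k:
        raise ValueError("no k in range produced a non-degenerate clustering")
    if second_derivative and len(db_by_k) >= 3:
        ks_sorted = sorted(db_by_k)
        vals = np.array([db_by_k[k] for k in ks_sorted])
        curv = vals[:-2] - 2 * vals[1:-1] + vals[2:]
        best_k = ks_sorted[1 + int(np.argmax(curv))]
    else:
        best_k = min(sorted(db_by_k), key=lambda k: db_by_k[k])
    labels, centroids = results[best_k]
    sizes = np.bincount(labels, minlength=best_k)
    order = np.argsort(-sizes, kind="stable")
    populations = sizes[order] / n
    reps = []
    for c in order:
        members = np.where(labels == c)[0]
        d = np.linalg.norm(x[members] - centroids[c], axis=1)
        reps.append(int(members[int(np.argmin(d))]))
    # relabel clusters in descending-population order
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array([remap[int(l)] for l in labels])
    return ClusterResult(
        k=best_k, labels=labels, populations=populations, db_by_k=db_by_k,
        representative_frames=np.array(reps), centroids=centroids[order],
    )
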