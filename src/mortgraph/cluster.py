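"""Shape-based clustering of country mortality trends.

Each country's train-years surface is age-standardized (every age column
z-scored over time), summarised by its first principal component — the
"overall trend" curve — and the m trend curves are clustered by k-means in
dynamic-time-warping geometry: assignment by smallest DTW distance to the
cluster barycenter, barycenter update by DTW barycenter averaging (DBA).
Model selection uses the mean silhouette coefficient on the DTW distance
matrix, with the SSE curve reported alongside for elbow diagnostics.

DTW here is the plain unconstrained recursion with absolute pointwise cost;
no Sakoe-Chiba windowing. DTW is not a metric (the triangle inequality can
fail), which is why silhouette is evaluated on the precomputed pairwise
matrix rather than assuming metric structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "PCResult", "ClusterModel", "standardize_ages", "first_pc",
    "dtw_distance", "dtw_path", "dtw_matrix", "dba_barycenter",
    "kmeans_shapes", "silhouette", "select_k",
]


# ----------------------------------------------------------------------
# Standardization and PCA
# ----------------------------------------------------------------------

def standardize_ages(matrix: np.ndarray) -> np.ndarray:
    """Z-score each age column over time; constant columns map to zeros."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a T x d matrix with T >= 2")
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0)
    out = np.zeros_like(matrix)
    live = sd > 0
    out[:, live] = (matrix[:, live] - mu[live]) / sd[live]
    return out


@dataclass
class PCResult:
    """First-principal-component summary of a standardized surface."""

    mean: np.ndarray          # (d,) column means of the input
    loading: np.ndarray       # (d,) unit-norm loading of the first component
    pc1: np.ndarray           # (T,) projection onto the first component
    proportions: np.ndarray   # (%) variance explained, descending

    def __post_init__(self):
        if not np.isclose(np.linalg.norm(self.loading), 1.0, atol=1e-9):
            raise ValueError("loading must have unit norm")


def first_pc(standardized: np.ndarray) -> PCResult:
    """Eigendecompose the age covariance and project onto the top direction.

    The loading sign is chosen so that the component correlates
    non-negatively with the cross-age mean series, i.e. the extracted curve
    tracks the overall trend rather than its mirror image.
    """
    Z = np.asarray(standardized, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("need a T x d matrix with T >= 2")
    if not np.any(Z):
        raise ValueError("degenerate all-zero input")
    mu = Z.mean(axis=0)
    C = Z - mu
    # SVD route; eigenvalues of the covariance are s^2 / (T - 1)
    _, s, vt = np.linalg.svd(C, full_matrices=False)
    lam = s ** 2 / (Z.shape[0] - 1)
    proportions = 100.0 * lam / lam.sum()
    loading = vt[0]
    pc1 = C @ loading
    overall = C.mean(axis=1)
    orient = float(pc1 @ overall)
    if orient < 0 or (orient == 0 and loading.sum() < 0):
        loading = -loading
        pc1 = -pc1
    return PCResult(Z.mean(axis=0), loading, pc1, proportions)


# ----------------------------------------------------------------------
# Dynamic time warping
# ----------------------------------------------------------------------

@njit(cache=True)
def _dtw_table(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.size, b.size
    acc = np.empty((na, nb))
    acc[0, 0] = abs(a[0] - b[0])
    for j in range(1, nb):
        acc[0, j] = acc[0, j - 1] + abs(a[0] - b[j])
    for i in range(1, na):
        acc[i, 0] = acc[i - 1, 0] + abs(a[i] - b[0])
        for j in range(1, nb):
            best = acc[i, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i - 1, j - 1] < best:
                best = acc[i - 1, j - 1]
            acc[i, j] = best + abs(a[i] - b[j])
    return acc


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Unconstrained DTW distance with absolute pointwise cost.

    Cumulative cost L(i,j) = |a_i - b_j| + min(L(i,j-1), L(i-1,j),
    L(i-1,j-1)); the distance is the bottom-right corner.
    """
    a = np.ascontiguousarray(a, dtype=np.float64).ravel()
    b = np.ascontiguousarray(b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("series must be non-empty")
    return float(_dtw_table(a, b)[-1, -1])


def dtw_path(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    """Optimal warping path (list of index pairs) by backtracking the DP.

    Ties prefer the diagonal step, then the vertical one; the convention
    only matters for barycenter averaging and is deterministic.
    """
    a = np.ascontiguousarray(a, dtype=np.float64).ravel()
    b = np.ascontiguousarray(b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("series must be non-empty")
    acc = _dtw_table(a, b)
    i, j = a.size - 1, b.size - 1
    path = [(i, j)]
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, up, left = acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
            if diag <= up and diag <= left:
                i, j = i - 1, j - 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return path


def dtw_matrix(series: list[np.ndarray]) -> np.ndarray:
    """Symmetric m x m matrix of pairwise DTW distances (zero diagonal)."""
    if len(series) < 2:
        raise ValueError("need at least 2 series")
    m = len(series)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = dtw_distance(series[i], series[j])
    return D


# ----------------------------------------------------------------------
# DTW k-means with barycenter averaging
# ----------------------------------------------------------------------

def dba_barycenter(members: list[np.ndarray], init: np.ndarray,
                   n_iter: int = 5) -> np.ndarray:
    """DTW barycenter averaging: align members to the current barycenter and
    average the values mapped onto each barycenter index."""
    center = np.asarray(init, dtype=float).copy()
    for _ in range(n_iter):
        sums = np.zeros_like(center)
        counts = np.zeros_like(center)
        for x in members:
            for ci, xi in ((ci, xi) for ci, xi in dtw_path(center, x)):
                sums[ci] += x[xi]
                counts[ci] += 1.0
        new = np.where(counts > 0, sums / np.maximum(counts, 1.0), center)
        if np.allclose(new, center, atol=1e-10):
            center = new
            break
        center = new
    return center


@dataclass
class ClusterModel:
    """Result of shape-based k-means on the trend curves."""

    k: int
    labels: np.ndarray
    barycenters: list[np.ndarray]
    sse: float
    silhouette_samples: np.ndarray | None = None
    silhouette_mean: float | None = None
    sse_history: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "k": self.k,
            "labels": [int(v) for v in self.labels],
            "sse": self.sse,
            "silhouette_mean": self.silhouette_mean,
            "silhouette_samples": (
                None if self.silhouette_samples is None
                else [float(v) for v in self.silhouette_samples]
            ),
            "barycenters": [[float(v) for v in b] for b in self.barycenters],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ClusterModel":
        p = json.loads(text)
        return cls(
            k=p["k"], labels=np.asarray(p["labels"], dtype=int),
            barycenters=[np.asarray(b) for b in p["barycenters"]],
            sse=p["sse"],
            silhouette_samples=(None if p["silhouette_samples"] is None
                                else np.asarray(p["silhouette_samples"])),
            silhouette_mean=p["silhouette_mean"],
        )


def _assign(series, centers) -> tuple[np.ndarray, np.ndarray]:
    dist = np.array([[dtw_distance(x, c) for c in centers] for x in series])
    return dist.argmin(axis=1), dist  # argmin breaks ties toward lower index


def kmeans_shapes(series: list[np.ndarray], k: int, n_init: int = 4,
                  seed: int = 0, max_iter: int = 20,
                  method: str = "dba",
                  pairwise: np.ndarray | None = None) -> ClusterModel:
    """k-means in DTW geometry; best of ``n_init`` seeded restarts by SSE.

    ``method="dba"`` updates barycenters by DTW barycenter averaging;
    ``method="medoids"`` runs a medoid update on the precomputed distance
    matrix instead (every centroid is a member series).
    """
    series = [np.asarray(s, dtype=float).ravel() for s in series]
    m = len(series)
    if not (1 <= k <= m):
        raise ValueError(f"k={k} outside [1, {m}]")
    if method not in ("dba", "medoids"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    best: ClusterModel | None = None
    for _ in range(n_init):
        order = rng.permutation(m)
        centers = [series[i].copy() for i in order[:k]]
        labels = np.full(m, -1)
        history: list[float] = []
        for _ in range(max_iter):
            new_labels, dist = _assign(series, centers)
            # keep clusters non-empty: give empty ones the worst-fit point
            for c in range(k):
                if not np.any(new_labels == c):
                    far = int(dist[np.arange(m), new_labels].argmax())
                    new_labels[far] = c
            sse = float((dist[np.arange(m), new_labels] ** 2).sum())
            history.append(sse)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                members = [series[i] for i in np.nonzero(labels == c)[0]]
                if method == "dba":
                    centers[c] = dba_barycenter(members, centers[c])
                else:
                    idx = np.nonzero(labels == c)[0]
                    sub = np.array([
                        [dtw_distance(series[i], series[j]) for j in idx]
                        for i in idx
                    ])
                    centers[c] = series[idx[int(sub.sum(axis=1).argmin())]].copy()
        _, dist = _assign(series, centers)
        sse = float((dist[np.arange(m), labels] ** 2).sum())
        model = ClusterModel(k, labels.copy(), [c.copy() for c in centers],
                             sse, sse_history=history)
        if best is None or model.sse < best.sse:
            best = model
    if k >= 2:
        D = dtw_matrix(series) if pairwise is None else np.asarray(pairwise)
        scores, mean = silhouette(D, best.labels)
        best.silhouette_samples, best.silhouette_mean = scores, mean
    return best


# ----------------------------------------------------------------------
# Silhouette and model selection
# ----------------------------------------------------------------------

def silhouette(D: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Silhouette scores S(i) = (b-a)/max(a,b) on a precomputed matrix.

    a(i) is the mean distance to own-cluster co-members, b(i) the smallest
    mean distance to another cluster. Members of singleton clusters score 0
    (the within-cluster mean is undefined there).
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = len(labels)
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        own[i] = False
        if not own.any():
            scores[i] = 0.0    # singleton cluster
            continue
        a = D[i, own].mean()
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return scores, float(scores.mean())


def select_k(series: list[np.ndarray], k_range=range(2, 9), n_init: int = 4,
             seed: int = 0, method: str = "dba"
             ) -> tuple[int, dict[int, float], dict[int, float]]:
    """Pick k maximising mean silhouette (ties to the smaller k).

    Returns (k*, per-k mean silhouette, per-k SSE); the SSE curve supports
    the usual elbow reading alongside the silhouette criterion.
    """
    series = [np.asarray(s, dtype=float).ravel() for s in series]
    m = len(series)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > m - 1:
        raise ValueError(f"k_range must lie within [2, {m - 1}]")
    D = dtw_matrix(series)
    sils: dict[int, float] = {}
    sses: dict[int, float] = {}
    for k in ks:
        model = kmeans_shapes(series, k, n_init=n_init, seed=seed,
                              method=method, pairwise=D)
        sils[k] = model.silhouette_mean
        sses[k] = model.sse
    k_star = max(ks, key=lambda k: (sils[k], -k))
    return k_star, sils, sses
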