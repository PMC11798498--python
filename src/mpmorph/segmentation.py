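"""Colour-space k-means segmentation with partition-entropy model selection.

A micrograph is flattened to its cloud of per-pixel RGB triples (spatial
position discarded), partitioned by Lloyd's k-means for each candidate k,
and each partition is scored with the Partition Entropy (PE) cluster
validity index. The candidate with the highest PE wins; ties go to the
smaller k.

PE conventions
--------------
The default score is the negative Shannon entropy of the cluster occupancy
fractions,

    PE(k) = sum_i P_i ln P_i,   P_i = n_i / n,

in natural-log units, so -ln k <= PE <= 0 with PE = 0 only when a single
cluster holds every point. Under crisp (hard) membership this is the only
occupancy-based reading whose sign and magnitude behave like a validity
index that is maximised at the best k: a near-balanced two-way split scores
close to -ln 2 ~ -0.693 and over-segmented partitions drift more negative.
Two sensitivity variants score the within-cluster distribution of the
256-level quantised BT.601 gray value instead of the occupancy
("gray_literal": +(1/n) sum over clusters of the gray-frequency entropy
contribution; "gray_literal_negated": its sign-flip); they are provided for
robustness checks, not selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import Micrograph

__all__ = [
    "FeatureSpace",
    "Clustering",
    "PEScore",
    "flatten_image",
    "unflatten",
    "run_kmeans",
    "partition_entropy",
    "select_from_scores",
    "select_optimal_k",
    "PE_VARIANTS",
]

PE_VARIANTS = ("occupancy", "gray_literal", "gray_literal_negated")


@dataclass
class FeatureSpace:
    """Flattened image: n = H*W points in RGB space, raster (row-major) order."""

    points: np.ndarray          # (n, 3)
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be n x 3")
        if self.points.shape[0] != self.height * self.width:
            raise ValueError("point count must equal H*W")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def pixel_index(self, row: int, col: int) -> int:
        return row * self.width + col

    def pixel_coords(self, index: int) -> tuple[int, int]:
        return divmod(index, self.width)


@dataclass
class Clustering:
    """Result of hard k-means on a feature space.

    ``labels`` are 1-based cluster ids (1..k); at convergence each point's
    label is its nearest centroid under Euclidean distance.
    """

    k: int
    centroids: np.ndarray       # (k, 3)
    labels: np.ndarray          # (n,), values in 1..k
    n_iter_run: int
    converged: bool

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=self.k) > self.k:
            raise ValueError("labels must lie in 1..k")

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    def occupancy(self) -> np.ndarray:
        """Cluster occupancy fractions P_i = n_i / n, i = 1..k."""
        counts = np.bincount(self.labels - 1, minlength=self.k)
        return counts / self.n


@dataclass(frozen=True)
class PEScore:
    k: int
    pe: float


def flatten_image(m: Micrograph) -> FeatureSpace:
    """Flatten a micrograph into RGB feature space in raster order."""
    h, w = m.shape
    return FeatureSpace(m.pixels.reshape(h * w, 3).copy(), h, w)


def unflatten(fs: FeatureSpace) -> np.ndarray:
    """Invert :func:`flatten_image`, returning the H x W x 3 pixel array."""
    return fs.points.reshape(fs.height, fs.width, 3).copy()


def run_kmeans(
    fs: FeatureSpace,
    k: int,
    seed: int,
    max_iter: int = 100,
    restarts: int = 1,
) -> Clustering:
    """Lloyd's k-means on the RGB point cloud.

    Initial centroids are k distinct data points drawn uniformly without
    replacement under ``seed``. Iterations alternate nearest-centroid
    assignment and mean updates, stopping early once the centroids are
    unchanged between successive iterations, else at ``max_iter`` (default
    100); the ``converged`` flag records which. A cluster left empty by an
    assignment step is re-seeded from the point farthest from its current
    centroid. With ``restarts > 1`` the run with the lowest within-cluster
    sum of squares is kept (restart r uses seed + r).
    """
    n = fs.n
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n = {n}, got {k}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best: Clustering | None = None
    best_wss = np.inf
    for r in range(restarts):
        c = _lloyd_once(fs.points, k, int(seed) + r, max_iter)
        wss = within_cluster_ss(fs.points, c)
        if wss < best_wss:
            best, best_wss = c, wss
    assert best is not None
    return best


def _lloyd_once(points: np.ndarray, k: int, seed: int, max_iter: int) -> Clustering:
    n = points.shape[0]
    rng = np.random.default_rng(seed)
    centroids = points[rng.choice(n, size=k, replace=False)].astype(float)
    labels = np.zeros(n, dtype=int)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        new_centroids = centroids.copy()
        for j in range(k):
            mask = labels == j
            if mask.any():
                new_centroids[j] = points[mask].mean(axis=0)
            else:
                # re-seed an empty cluster from the point farthest from its
                # own centroid, then let the next assignment step settle it
                far = d2[np.arange(n), labels].argmax()
                new_centroids[j] = points[far]
        if np.array_equal(new_centroids, centroids):
            converged = True
            break
        centroids = new_centroids
    # final assignment so labels match the returned centroids exactly
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    return Clustering(k=k, centroids=centroids, labels=labels + 1,
                      n_iter_run=n_iter, converged=converged)


def within_cluster_ss(points: np.ndarray, c: Clustering) -> float:
    """Within-cluster sum of squared Euclidean distances to centroids."""
    return float(((points - c.centroids[c.labels - 1]) ** 2).sum())


def partition_entropy(
    c: Clustering,
    variant: str = "occupancy",
    gray: np.ndarray | None = None,
) -> PEScore:
    """Score a hard clustering with the Partition Entropy index.

    The default ``occupancy`` variant returns ``sum_i P_i ln P_i`` over the
    cluster occupancy fractions (natural log, hence in [-ln k, 0]). The
    gray-value variants need the flattened grayscale image in ``gray`` and
    score the within-cluster 256-bin gray histogram instead.
    """
    if c.n < 1:
        raise ValueError("clustering has no points")
    if variant not in PE_VARIANTS:
        raise ValueError(f"unknown pe variant {variant!r}; choose from {PE_VARIANTS}")
    if variant == "occupancy":
        p = c.occupancy()
        nz = p[p > 0]
        return PEScore(k=c.k, pe=float((nz * np.log(nz)).sum()))
    if gray is None:
        raise ValueError("gray-value PE variants require the flattened gray image")
    gray = np.asarray(gray).ravel()
    if gray.shape[0] != c.n:
        raise ValueError("gray image length must match the number of points")
    levels = np.clip((gray * 255.0).round().astype(int), 0, 255)
    total = 0.0
    for j in range(1, c.k + 1):
        sel = levels[c.labels == j]
        if sel.size == 0:
            continue
        freq = np.bincount(sel, minlength=256) / c.n
        nz = freq[freq > 0]
        total += float((nz * np.log(nz)).sum())
    pe = -total  # literal reading: minus the summed p ln p terms, >= 0
    if variant == "gray_literal_negated":
        pe = -pe
    return PEScore(k=c.k, pe=pe)


def select_from_scores(scores: list[PEScore]) -> int:
    """Pick the k with maximal PE; ties break toward the smallest k."""
    if not scores:
        raise ValueError("no candidate scores")
    ordered = sorted(scores, key=lambda s: s.k)
    best = ordered[0]
    for s in ordered[1:]:
        if s.pe > best.pe:
            best = s
    return best.k


def select_optimal_k(
    m: Micrograph,
    k_range=range(2, 7),
    seed: int = 0,
    max_iter: int = 100,
    restarts: int = 1,
    pe_variant: str = "occupancy",
) -> tuple[int, list[PEScore]]:
    """Cluster for every candidate k and return (best k, all PE scores)."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    fs = flatten_image(m)
    gray = None
    if pe_variant != "occupancy":
        from .morphometry import to_grayscale

        gray = to_grayscale(m).ravel()
    scores = []
    for k in ks:
        c = run_kmeans(fs, k, seed=seed, max_iter=max_iter, restarts=restarts)
        if not c.converged:
            warnings.warn(f"k-means did not converge within {max_iter} iterations for k={k}")
        scores.append(partition_entropy(c, variant=pe_variant, gray=gray))
    return select_from_scores(scores), scores
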