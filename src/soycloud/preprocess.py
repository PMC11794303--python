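"""Denoising and ground (natural background) removal.

Two stages run before any per-plant analysis:

1. **Statistical outlier removal** — for each point, the mean distance to its
   ``n_neighbors`` nearest neighbors is computed; points whose mean distance
   exceeds ``mu + std_ratio * sigma`` (``mu``, ``sigma`` over the whole
   cloud) are dropped.  This removes isolated sensor noise while keeping the
   dense canopy and ground surfaces.
2. **RANSAC ground removal** — the single best-supported plane is fitted by
   random sample consensus and refined by a least-squares fit on its
   consensus set.  Points within ``dist_threshold`` of the refined plane, or
   below it along the upward normal, are classified as ground; the remainder
   are plant returns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pointcloud_io import PointCloud

__all__ = [
    "PlaneModel",
    "statistical_outlier_removal",
    "ransac_ground_removal",
    "background_classification_accuracy",
]


@dataclass
class PlaneModel:
    """Plane ``{p : normal . p = offset}`` with its RANSAC consensus set."""

    normal: np.ndarray  # unit 3-vector, oriented upward (normal[2] >= 0)
    offset: float
    inliers: np.ndarray  # int indices into the fitted cloud

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(self.normal)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("plane normal must be a unit vector")

    def signed_distance(self, coords: np.ndarray) -> np.ndarray:
        """Signed distance along the upward normal (positive = above)."""
        return coords @ self.normal - self.offset


def statistical_outlier_removal(
    cloud: PointCloud, n_neighbors: int = 10, std_ratio: float = 1.0
) -> tuple[PointCloud, np.ndarray]:
    """Drop points with anomalously large mean distance to their neighbors.

    Returns the filtered cloud (all label arrays filtered consistently) and
    the integer indices of the removed points.
    """
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    if std_ratio <= 0:
        raise ValueError("std_ratio must be positive")
    n = len(cloud)
    if n <= n_neighbors:
        raise ValueError(f"need more than {n_neighbors} points, got {n}")
    tree = cKDTree(cloud.coords)
    # k+1 because each point is its own nearest neighbor
    dists, _ = tree.query(cloud.coords, k=n_neighbors + 1)
    mean_dist = dists[:, 1:].mean(axis=1)
    mu = mean_dist.mean()
    sigma = mean_dist.std()
    keep = mean_dist <= mu + std_ratio * sigma
    removed = np.flatnonzero(~keep)
    return cloud.select(keep), removed


def _fit_plane_lsq(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares plane through >= 3 points; raises on degeneracy."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    # smallest right singular vector = plane normal
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set: cannot fit a plane")
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    return normal, float(normal @ centroid)


def ransac_ground_removal(
    cloud: PointCloud,
    dist_threshold: float = 0.05,
    n_iterations: int = 500,
    rng_seed: int = 0,
) -> tuple[PointCloud, PointCloud, PlaneModel]:
    """Split a cloud into (plants, ground) by robust plane fitting.

    RANSAC collects candidate planes by consensus size; among candidates
    whose support is within 70% of the best, the *lowest* near-horizontal
    plane is chosen — in a crop field both the soil and a dense canopy
    stratum are planar at field scale, and the ground is by definition the
    lowest of the strong planes.  Support during iteration is counted on a
    subsample (capped at 30k points) for speed; the final split uses every
    point.

    Ground is every point within ``dist_threshold`` of the refined plane *or
    below it* — keeping sub-plane pits (ground roughness, ranging noise) out
    of the plant set.  Returns ``(plants, ground, plane)``.
    """
    n = len(cloud)
    if n < 3:
        raise ValueError("need at least 3 points to fit a plane")
    if dist_threshold <= 0:
        raise ValueError("dist_threshold must be positive")
    coords = cloud.coords
    rng = np.random.default_rng(rng_seed)
    support = coords
    if n > 30000:
        support = coords[rng.choice(n, size=30000, replace=False)]
    centroid_xy = coords[:, :2].mean(axis=0)
    candidates: list[tuple[int, float, np.ndarray, float]] = []
    for _ in range(n_iterations):
        idx = rng.choice(n, size=3, replace=False)
        p0, p1, p2 = coords[idx]
        normal = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue  # collinear sample
        normal = normal / norm
        if normal[2] < 0:
            normal = -normal
        offset = normal @ p0
        count = int(
            np.count_nonzero(np.abs(support @ normal - offset) <= dist_threshold)
        )
        if normal[2] > 0.82:  # within ~35 deg of horizontal: ground candidate
            z0 = (offset - normal[:2] @ centroid_xy) / normal[2]
        else:
            z0 = np.inf  # tilted slab (canopy row, etc.): never "lowest"
        candidates.append((count, z0, normal, offset))
    if not candidates:
        raise ValueError("RANSAC failed: all samples degenerate (collinear cloud)")
    best_count = max(c[0] for c in candidates)
    strong = [c for c in candidates if c[0] >= 0.7 * best_count]
    z_lowest = min(c[1] for c in strong)
    if np.isfinite(z_lowest):
        # lowest stratum of strong planes (within one threshold of the
        # lowest), then best support inside it: picking the lowest plane
        # outright would bias the fit below the true surface
        stratum = [c for c in strong if c[1] <= z_lowest + dist_threshold]
        best_normal, best_offset = max(stratum, key=lambda c: c[0])[2:]
    else:  # no near-horizontal candidate: fall back to max support
        best_normal, best_offset = max(strong, key=lambda c: c[0])[2:]
    # least-squares refit on the consensus set
    consensus = np.abs(coords @ best_normal - best_offset) <= dist_threshold
    if np.count_nonzero(consensus) >= 3:
        try:
            best_normal, best_offset = _fit_plane_lsq(coords[consensus])
        except ValueError:
            pass  # keep the sampled plane if the consensus set is degenerate
    plane = PlaneModel(
        normal=best_normal,
        offset=best_offset,
        inliers=np.flatnonzero(
            np.abs(coords @ best_normal - best_offset) <= dist_threshold
        ),
    )
    signed = plane.signed_distance(coords)
    is_ground = signed < dist_threshold
    return cloud.select(~is_ground), cloud.select(is_ground), plane


def background_classification_accuracy(
    predicted_class: np.ndarray, true_class: np.ndarray
) -> float:
    """Point-wise plant-vs-background accuracy, (TP+TN)/(TP+TN+FP+FN)."""
    pred = np.asarray(predicted_class)
    true = np.asarray(true_class)
    if pred.shape != true.shape:
        raise ValueError(
            f"label length mismatch: {pred.shape} vs {true.shape}"
        )
    if pred.size == 0:
        raise ValueError("empty label arrays")
    return float(np.mean(pred == true))
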