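"""Individual-plant segmentation of a background-free canopy cloud.

Two methods:

* **Max-Min k-means** — Lloyd's algorithm started from Max-Min distance
  (farthest-point) initialization: the first center is a seeded-random
  point, the second the point farthest from it, and every further center
  the point maximizing its minimum distance to the centers chosen so far.
* **Watershed** — the cloud's XY footprint is rasterized to a binary
  occupancy image; the Euclidean distance transform of the occupancy is a
  topographic surface whose regional maxima (one per plant, after h-maxima
  suppression and a minimum-separation constraint) seed a watershed flood of
  the negative distance map.  Cell labels are indexed back to the points.

The watershed route is purely planimetric, which makes it robust to canopy
adhesion: two interpenetrating canopies still pinch the footprint at their
contact, producing separate distance-transform maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import h_maxima, local_maxima
from skimage.segmentation import watershed

from .pointcloud_io import PointCloud

__all__ = [
    "RasterGrid",
    "SegmentationResult",
    "maxmin_init",
    "kmeans_segment",
    "rasterize",
    "watershed_segment",
]


@dataclass
class RasterGrid:
    """XY binning of a cloud: cell (row, col) = floor((y-y0)/res), floor((x-x0)/res)."""

    origin: tuple[float, float]  # (x0, y0)
    resolution: float
    shape: tuple[int, int]  # (n_rows, n_cols)
    occupancy: np.ndarray  # bool (n_rows, n_cols)
    cell_of_point: np.ndarray  # (N, 2) int rows of (row, col) per point

    def point_index(self) -> dict[tuple[int, int], list[int]]:
        """Mapping occupied cell -> list of point indices."""
        out: dict[tuple[int, int], list[int]] = {}
        for i, (r, c) in enumerate(self.cell_of_point):
            out.setdefault((int(r), int(c)), []).append(i)
        return out


@dataclass
class SegmentationResult:
    """Per-point instance assignment plus per-instance summaries."""

    instance_label: np.ndarray  # (N,) int, -1 = unassigned
    n_instances: int
    counts: np.ndarray  # (n_instances,) point counts
    centroids: np.ndarray  # (n_instances, 3)

    @classmethod
    def from_labels(cls, coords: np.ndarray, labels: np.ndarray) -> "SegmentationResult":
        labels = np.asarray(labels, dtype=np.int64)
        ids = np.unique(labels[labels >= 0])
        # compact to 0..n-1 preserving order
        remap = {old: new for new, old in enumerate(ids)}
        compact = np.array([remap.get(l, -1) for l in labels], dtype=np.int64)
        n = len(ids)
        counts = np.bincount(compact[compact >= 0], minlength=n)
        centroids = np.zeros((n, 3))
        for k in range(n):
            centroids[k] = coords[compact == k].mean(axis=0)
        return cls(
            instance_label=compact, n_instances=n, counts=counts, centroids=centroids
        )


# ---------------------------------------------------------------------------
# Max-Min k-means

def maxmin_init(points: np.ndarray, k: int, rng_seed: int = 0) -> np.ndarray:
    """Max-Min distance (farthest-point) center initialization.

    Returns a ``(k, d)`` array of chosen data points.  Center 1 is a
    seeded-random point; each later center is the point with maximum
    distance to its nearest already-chosen center.
    """
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(rng_seed)
    centers = np.empty((k, points.shape[1]))
    centers[0] = points[rng.integers(n)]
    min_dist = np.linalg.norm(points - centers[0], axis=1)
    for j in range(1, k):
        idx = int(np.argmax(min_dist))
        centers[j] = points[idx]
        np.minimum(min_dist, np.linalg.norm(points - centers[j], axis=1), out=min_dist)
    return centers


def _assign(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # argmin breaks ties toward the lowest center index
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def kmeans_segment(
    cloud: PointCloud,
    k: int,
    rng_seed: int = 0,
    max_iter: int = 100,
    z_weight: float = 0.25,
) -> SegmentationResult:
    """Lloyd's k-means from Max-Min initialization.

    Iterates until an assignment pass moves no point (or ``max_iter``).
    An emptied cluster is re-seeded at the point farthest from its assigned
    center, which keeps every instance non-empty.

    ``z_weight`` scales the z coordinate before clustering: row-crop plants
    are taller than their in-row spacing, so an isotropic metric lets the
    farthest-point initialization place two seeds inside one plant (its top
    and bottom are farther apart than two neighboring plants).  Individual
    plants separate horizontally, never vertically, so z is down-weighted
    by default; ``z_weight=1`` restores the isotropic metric.
    """
    if len(cloud) == 0:
        raise ValueError("cannot segment an empty cloud")
    points = cloud.coords * np.array([1.0, 1.0, z_weight])
    centers = maxmin_init(points, k, rng_seed)
    labels = _assign(points, centers)
    for _ in range(max_iter):
        for j in range(k):
            members = points[labels == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:
                # re-seed at the point farthest from its current center
                far = np.linalg.norm(points - centers[labels], axis=1)
                centers[j] = points[int(np.argmax(far))]
        new_labels = _assign(points, centers)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return SegmentationResult.from_labels(cloud.coords, labels)


# ---------------------------------------------------------------------------
# watershed

def rasterize(cloud: PointCloud, resolution: float) -> RasterGrid:
    """Bin the cloud's XY footprint onto a grid padded by one empty cell."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if len(cloud) == 0:
        raise ValueError("cannot rasterize an empty cloud")
    x, y = cloud.coords[:, 0], cloud.coords[:, 1]
    # one-cell padding so the occupancy never touches the image border;
    # binning is anchored at the minima (exact) rather than at the shifted
    # origin (whose float representation can misplace boundary points)
    x0 = x.min() - resolution
    y0 = y.min() - resolution
    cols = np.floor((x - x.min()) / resolution).astype(np.int64) + 1
    rows = np.floor((y - y.min()) / resolution).astype(np.int64) + 1
    shape = (int(rows.max()) + 2, int(cols.max()) + 2)
    occupancy = np.zeros(shape, dtype=bool)
    occupancy[rows, cols] = True
    return RasterGrid(
        origin=(float(x0), float(y0)),
        resolution=resolution,
        shape=shape,
        occupancy=occupancy,
        cell_of_point=np.column_stack([rows, cols]),
    )


def watershed_markers(
    distance: np.ndarray,
    occupancy: np.ndarray,
    resolution: float,
    marker_min_distance: float,
    h_depth: float,
) -> np.ndarray:
    """Marker image for the watershed: regional maxima of the distance map.

    Maxima of prominence below ``h_depth`` are suppressed (h-maxima
    transform); each surviving connected maximum region yields one marker.
    Regions whose centroids are closer than ``marker_min_distance`` are
    merged into the one with the higher peak, so a single plant's ragged
    footprint cannot seed two basins.
    """
    if h_depth > 0:
        maxima = h_maxima(distance, h_depth)
    else:
        maxima = local_maxima(distance)
    maxima &= occupancy
    region_labels, n_regions = ndimage.label(maxima)
    if n_regions == 0:
        return np.zeros(distance.shape, dtype=np.int32)
    ids = np.arange(1, n_regions + 1)
    centroids = np.array(ndimage.center_of_mass(maxima, region_labels, ids))
    peaks = ndimage.maximum(distance, region_labels, ids)
    min_cells = marker_min_distance / resolution
    # greedy suppression: highest peak first, drop regions too close to a keeper
    order = np.argsort(-peaks, kind="stable")
    kept: list[int] = []
    for idx in order:
        c = centroids[idx]
        if all(np.linalg.norm(c - centroids[j]) >= min_cells for j in kept):
            kept.append(idx)
    markers = np.zeros(distance.shape, dtype=np.int32)
    for new_id, idx in enumerate(sorted(kept), start=1):
        markers[region_labels == ids[idx]] = new_id
    return markers


def watershed_segment(
    cloud: PointCloud,
    resolution: float = 0.01,
    marker_min_distance: float = 0.08,
    h_depth: float = 0.02,
) -> SegmentationResult:
    """Watershed instance segmentation of a plant-only cloud.

    Pipeline: rasterize -> Euclidean distance transform of the occupancy
    (in meters) -> markers from its filtered local maxima -> watershed of the
    negative distance map restricted to occupied cells -> cell labels indexed
    back to the points.  Points whose cells end up unlabeled (watershed
    ridges, occupied islands with no marker) take the label of the nearest
    labeled cell, so every point is assigned on non-empty input.
    """
    if len(cloud) == 0:
        raise ValueError("cannot segment an empty cloud")
    grid = rasterize(cloud, resolution)
    occ = grid.occupancy
    if not occ.any():
        return SegmentationResult.from_labels(
            cloud.coords, -np.ones(len(cloud), dtype=np.int64)
        )
    distance = ndimage.distance_transform_edt(occ) * resolution
    markers = watershed_markers(
        distance, occ, resolution, marker_min_distance, h_depth
    )
    if markers.max() == 0:
        # no marker survived (tiny blob): single instance
        cell_labels = occ.astype(np.int32)
    else:
        cell_labels = watershed(-distance, markers=markers, mask=occ)
        unlabeled = occ & (cell_labels == 0)
        if unlabeled.any():
            lab_cells = np.argwhere(cell_labels > 0)
            tree = cKDTree(lab_cells)
            need = np.argwhere(unlabeled)
            _, nearest = tree.query(need)
            cell_labels[need[:, 0], need[:, 1]] = cell_labels[
                lab_cells[nearest, 0], lab_cells[nearest, 1]
            ]
    point_labels = cell_labels[grid.cell_of_point[:, 0], grid.cell_of_point[:, 1]]
    return SegmentationResult.from_labels(
        cloud.coords, point_labels.astype(np.int64) - 1
    )
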