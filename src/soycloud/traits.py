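"""Canopy structural traits of a plant or plot cloud.

Six traits feed the LAI model:

``height``
    Mean z of the highest 20% of points minus the ground reference.
``canopy_roughness``
    CR = IQR / median of the per-point *ambiguities* — each point's
    orthogonal distance to the total-least-squares plane of its spherical
    neighborhood.  A dimensionless ratio; 0 for a perfect plane.
``surface_area``
    Summed 3D area of a 2.5D Delaunay triangulation of the XY projection,
    long-edged triangles discarded.
``volume``
    Per XY grid cell, cell_size^2 * (z range in the cell), summed.
``cover``
    Trapezoidal integral over x of the per-bin y-extent of the projection.
``vog``
    Layered voxel-occupancy ratio.  The cloud's bounding box is cut into
    ``P = int((Zmax - Zmin)/VOS)`` z-layers of ``n1`` voxels each
    (``n1 = ceil(dx/VOS) * ceil(dy/VOS)``); ``nT(p)`` counts occupied voxels
    in layer p.  Because the LiDAR beam does not penetrate the canopy
    interior, an interior-fill term ``pi * k^2 / 2`` (a half-disc of radius
    ``k = max((Xmax - Xmin - 0.59)/VOS, 0)`` voxels, an empirical constant)
    is added per layer before normalizing:

        VOG = (1 / (P * n1)) * sum_p min(nT(p) + pi k^2 / 2, n1)

    With the correction disabled, VOG = sum_p nT(p) / (P * n1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from scipy.stats import pearsonr

from .pointcloud_io import PointCloud

__all__ = [
    "VoxelGrid",
    "TraitVector",
    "TraitConfig",
    "build_voxel_grid",
    "voxel_occupancy_ratio",
    "sweep_voxel_size",
    "point_ambiguity",
    "canopy_roughness",
    "plant_height",
    "canopy_cover",
    "canopy_volume",
    "canopy_surface_area",
    "extract_traits",
]


@dataclass
class VoxelGrid:
    """Layered voxelization of a cloud's bounding box (edge length ``vos``)."""

    vos: float
    P: int                      # z-layers
    n1: int                     # voxels per layer
    nT: np.ndarray              # (P,) occupied-voxel counts per layer
    k: float                    # interior-fill radius, voxel units
    bounds: tuple[float, float, float, float, float, float]


@dataclass
class TraitVector:
    """The six per-plot canopy traits."""

    height: float
    canopy_roughness: float
    surface_area: float
    volume: float
    cover: float
    vog: float

    FIELDS = ("height", "canopy_roughness", "surface_area", "volume", "cover", "vog")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS])


@dataclass
class TraitConfig:
    """Parameters for trait extraction (all lengths in meters)."""

    vos: float = 0.05                 # voxel edge
    interior_fill: bool = True        # apply the pi*k^2/2 correction
    fill_constant: float = 0.59       # empirical constant in k
    cr_radius: float = 0.03           # ambiguity neighborhood radius
    cover_bins: int = 30
    cell_size: float = 0.05           # volume grid cell
    max_edge: float = 0.06            # surface-mesh edge cutoff
    smooth_cell: float | None = 0.02  # surface-mesh vertex averaging cell
    ground_z: float = 0.0             # height reference (e.g. RANSAC plane)
    top_fraction: float = 0.2         # height uses the top 20% of points


# ---------------------------------------------------------------------------
# voxel occupancy

def build_voxel_grid(
    cloud: PointCloud, vos: float, fill_constant: float = 0.59
) -> VoxelGrid:
    """Voxelize the cloud at edge length ``vos``; layers indexed from Zmin."""
    if vos <= 0:
        raise ValueError("vos must be positive")
    if len(cloud) == 0:
        raise ValueError("cannot voxelize an empty cloud")
    c = cloud.coords
    xmin, ymin, zmin = c.min(axis=0)
    xmax, ymax, zmax = c.max(axis=0)
    P = int((zmax - zmin) / vos)
    if P < 1:
        raise ValueError(
            f"vos={vos} exceeds the cloud z-extent {zmax - zmin:.4f}; no layer fits"
        )
    nx = max(1, int(np.ceil((xmax - xmin) / vos)))
    ny = max(1, int(np.ceil((ymax - ymin) / vos)))
    n1 = nx * ny
    ix = np.minimum(np.floor((c[:, 0] - xmin) / vos).astype(np.int64), nx - 1)
    iy = np.minimum(np.floor((c[:, 1] - ymin) / vos).astype(np.int64), ny - 1)
    iz = np.minimum(np.floor((c[:, 2] - zmin) / vos).astype(np.int64), P - 1)
    flat = (iz * ny + iy) * nx + ix
    occupied = np.unique(flat)
    layer_of = occupied // (nx * ny)
    nT = np.bincount(layer_of, minlength=P)
    k = max((xmax - xmin - fill_constant) / vos, 0.0)
    return VoxelGrid(
        vos=vos,
        P=P,
        n1=n1,
        nT=nT,
        k=float(k),
        bounds=(float(xmin), float(xmax), float(ymin), float(ymax),
                float(zmin), float(zmax)),
    )


def voxel_occupancy_ratio(grid: VoxelGrid, interior_fill: bool = True) -> float:
    """Fraction of canopy voxels occupied, optionally interior-filled."""
    per_layer = grid.nT.astype(np.float64)
    if interior_fill:
        per_layer = np.minimum(per_layer + np.pi * grid.k**2 / 2.0, grid.n1)
    return float(per_layer.sum() / (grid.P * grid.n1))


def sweep_voxel_size(
    clouds: list[PointCloud],
    references: np.ndarray,
    vos_min: float = 0.008,
    vos_max: float = 0.14,
    step: float = 0.02,
    interior_fill: bool = True,
) -> list[dict]:
    """Correlate VOG with reference values across a range of voxel sizes.

    Returns one row per voxel size: ``{"vos", "pearson_r", "best"}`` with
    ``pearson_r`` None where VOG is constant across clouds (undefined
    correlation), and ``best`` True on the argmax row.
    """
    references = np.asarray(references, dtype=np.float64)
    if len(clouds) < 3 or len(clouds) != len(references):
        raise ValueError("need >= 3 clouds with paired reference values")
    rows = []
    for vos in np.arange(vos_min, vos_max + 1e-12, step):
        vogs = []
        for cl in clouds:
            try:
                grid = build_voxel_grid(cl, float(vos))
                vogs.append(voxel_occupancy_ratio(grid, interior_fill))
            except ValueError:
                vogs.append(np.nan)
        vogs = np.asarray(vogs)
        ok = np.isfinite(vogs)
        if ok.sum() >= 3 and np.std(vogs[ok]) > 1e-15 and np.std(references[ok]) > 1e-15:
            r = float(pearsonr(vogs[ok], references[ok])[0])
        else:
            r = None
        rows.append({"vos": float(vos), "pearson_r": r, "best": False})
    valid = [i for i, row in enumerate(rows) if row["pearson_r"] is not None]
    if valid:
        best = max(valid, key=lambda i: rows[i]["pearson_r"])
        rows[best]["best"] = True
    return rows


# ---------------------------------------------------------------------------
# canopy roughness

def point_ambiguity(cloud: PointCloud, radius: float = 0.03) -> np.ndarray:
    """Per-point distance to the best-fit (TLS) plane of its neighborhood.

    The neighborhood is all points within ``radius`` (the point included);
    neighborhoods with fewer than 3 points get ambiguity 0.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = cloud.coords
    n = len(coords)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    # accumulate neighborhood first and second moments per point (bincount
    # per moment component: much faster than np.add.at on pair lists)
    counts = np.ones(n)
    sums = coords.copy()
    outer = np.einsum("ij,ik->ijk", coords, coords)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        both = np.concatenate([i, j])
        other = np.concatenate([j, i])
        counts += np.bincount(both, minlength=n)
        for ax in range(3):
            sums[:, ax] += np.bincount(both, weights=coords[other, ax], minlength=n)
        for ax in range(3):
            for bx in range(ax, 3):
                acc = np.bincount(
                    both, weights=coords[other, ax] * coords[other, bx], minlength=n
                )
                outer[:, ax, bx] += acc
                if bx != ax:
                    outer[:, bx, ax] += acc
    mean = sums / counts[:, None]
    cov = outer / counts[:, None, None] - np.einsum("ij,ik->ijk", mean, mean)
    # smallest-eigenvalue eigenvector of each 3x3 covariance = plane normal
    w, v = np.linalg.eigh(cov)
    normals = v[:, :, 0]
    amb = np.abs(np.einsum("ij,ij->i", coords - mean, normals))
    amb[counts < 3] = 0.0
    return amb


def canopy_roughness(cloud: PointCloud, radius: float = 0.03) -> float:
    """CR = IQR / median of the point ambiguities (0 when the median ~ 0)."""
    amb = point_ambiguity(cloud, radius)
    med = float(np.median(amb))
    if med < 1e-9:
        return 0.0
    q1, q3 = np.percentile(amb, [25, 75])  # linear-interpolation quartiles
    return float((q3 - q1) / med)


# ---------------------------------------------------------------------------
# height, cover, volume, surface area

def plant_height(cloud: PointCloud, ground_z: float = 0.0, top_fraction: float = 0.2) -> float:
    """Mean z of the highest ``top_fraction`` of points above ``ground_z``."""
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    z = np.sort(cloud.coords[:, 2])
    m = max(1, int(np.ceil(top_fraction * len(z))))
    return max(float(z[-m:].mean() - ground_z), 0.0)


def canopy_cover(cloud: PointCloud, n_bins: int = 30) -> float:
    """Projected canopy area: trapezoidal integral of per-x-bin y-extent."""
    if len(cloud) < 3:
        raise ValueError("need at least 3 points")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x, y = cloud.coords[:, 0], cloud.coords[:, 1]
    x0, x1 = float(x.min()), float(x.max())
    if x1 - x0 < 1e-12:
        return 0.0
    edges = np.linspace(x0, x1, n_bins + 1)
    which = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    widths = np.zeros(n_bins)
    for b in range(n_bins):
        yy = y[which == b]
        if len(yy):
            widths[b] = yy.max() - yy.min()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(np.trapezoid(widths, centers))


def canopy_volume(cloud: PointCloud, cell_size: float = 0.05) -> float:
    """Sum over occupied XY cells of cell_size^2 * per-cell z-range."""
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    c = cloud.coords
    ix = np.floor((c[:, 0] - c[:, 0].min()) / cell_size).astype(np.int64)
    iy = np.floor((c[:, 1] - c[:, 1].min()) / cell_size).astype(np.int64)
    flat = ix * (iy.max() + 1) + iy
    order = np.argsort(flat, kind="stable")
    flat_s, z_s = flat[order], c[order, 2]
    boundaries = np.flatnonzero(np.diff(flat_s)) + 1
    zmax = np.maximum.reduceat(z_s, np.r_[0, boundaries])
    zmin = np.minimum.reduceat(z_s, np.r_[0, boundaries])
    return float(cell_size**2 * np.sum(zmax - zmin))


def canopy_surface_area(
    cloud: PointCloud, max_edge: float = 0.06, smooth_cell: float | None = 0.02
) -> float:
    """3D area of a 2.5D Delaunay mesh of the canopy surface.

    With ``smooth_cell`` set (the default), mesh vertices are per-XY-cell
    centroids of the cloud — a surface-model reduction that averages
    ranging noise out of the reconstructed surface; with dense multi-return
    clouds the raw point set is not a surface and its mesh area measures
    noise texture instead of canopy geometry.  Pass ``None`` to mesh the
    raw points.  Triangles with any 3D edge longer than ``max_edge`` are
    discarded to avoid bridging separate canopy parts.
    """
    if len(cloud) < 3:
        raise ValueError("need at least 3 points")
    verts = cloud.coords
    if smooth_cell is not None:
        if smooth_cell <= 0:
            raise ValueError("smooth_cell must be positive")
        c = cloud.coords
        ix = np.floor((c[:, 0] - c[:, 0].min()) / smooth_cell).astype(np.int64)
        iy = np.floor((c[:, 1] - c[:, 1].min()) / smooth_cell).astype(np.int64)
        flat = ix * (iy.max() + 1) + iy
        order = np.argsort(flat, kind="stable")
        flat_s = flat[order]
        starts = np.r_[0, np.flatnonzero(np.diff(flat_s)) + 1]
        if len(starts) >= 3:
            sums = np.add.reduceat(c[order], starts, axis=0)
            counts = np.diff(np.r_[starts, len(c)])
            verts = sums / counts[:, None]
    xy = verts[:, :2]
    try:
        tri = Delaunay(xy)
    except Exception as exc:  # qhull raises on degenerate input
        raise ValueError(f"cannot triangulate projection: {exc}") from None
    p = verts[tri.simplices]  # (n_tri, 3, 3)
    e0 = p[:, 1] - p[:, 0]
    e1 = p[:, 2] - p[:, 0]
    e2 = p[:, 2] - p[:, 1]
    lengths = np.stack(
        [np.linalg.norm(e0, axis=1), np.linalg.norm(e1, axis=1),
         np.linalg.norm(e2, axis=1)]
    )
    keep = lengths.max(axis=0) <= max_edge
    areas = 0.5 * np.linalg.norm(np.cross(e0[keep], e1[keep]), axis=1)
    return float(areas.sum())


def extract_traits(cloud: PointCloud, config: TraitConfig | None = None) -> TraitVector:
    """Compose the six trait extractors with ``config`` parameters."""
    if len(cloud) == 0:
        raise ValueError("cannot extract traits from an empty cloud")
    cfg = config or TraitConfig()
    grid = build_voxel_grid(cloud, cfg.vos, cfg.fill_constant)
    vog = voxel_occupancy_ratio(grid, cfg.interior_fill)
    return TraitVector(
        height=plant_height(cloud, cfg.ground_z, cfg.top_fraction),
        canopy_roughness=canopy_roughness(cloud, cfg.cr_radius),
        surface_area=canopy_surface_area(cloud, cfg.max_edge, cfg.smooth_cell),
        volume=canopy_volume(cloud, cfg.cell_size),
        cover=canopy_cover(cloud, cfg.cover_bins),
        vog=min(max(vog, 0.0), 1.0),
    )
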