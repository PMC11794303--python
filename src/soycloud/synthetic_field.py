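"""Synthetic soybean field scenes with per-point ground truth.

The generator emulates the row-planted soybean plots the pipeline targets:
plants on ridges 0.8 m apart with 0.15 m in-row spacing, 10,000-20,000 LiDAR
returns per plant, ~3 cm ranging noise, sparse outliers and a gently rough
ground surface.  Each plant is a parametric model — a vertical stem carrying
planar elliptical leaves — so the true one-sided leaf area (and hence the
plot's true LAI) is known analytically: ``sum(pi * a * b)`` over the leaf
semi-axes.

Canopy *adhesion* — how much neighboring canopies interpenetrate — is the
axis along which instance segmentation gets hard, and is controlled by three
categories:

``simple``
    Max canopy diameter < in-row plant spacing; adjacent point sets are
    separated by a guaranteed XY gap.
``ordinary``
    Adjacent canopies overlap pairwise by at most 25% of the canopy radius.
``complex``
    Chains of three or more consecutive canopies overlap strongly
    (radius ~0.9x the in-row spacing).

Every sampled point carries a class label (0 ground, 1 plant, -1 outlier)
and an instance label (plant ID, -1 for non-plant points), so denoising,
ground removal and segmentation can all be scored without external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pointcloud_io import PointCloud

__all__ = [
    "PlantModel",
    "FieldScene",
    "generate_plant",
    "generate_scene",
    "scene_true_lai",
    "ADHESION_CATEGORIES",
]

ADHESION_CATEGORIES = ("simple", "ordinary", "complex")

# Geometry defaults for a size_scale of 1 (soybean, 35-46 days after sowing).
_STEM_HEIGHT = 0.30          # m, nominal stem height
_LEAF_SEMI_A = (0.048, 0.062)  # m, radial leaf semi-axis range
_LEAF_B_RATIO = 0.62           # tangential semi-axis as fraction of a
_LEAF_INCL = (0.35, 1.05)      # rad, leaf inclination from horizontal
_ATTACH_FRAC = (0.35, 1.0)     # leaf attachment along the stem
_STEM_POINT_FRAC = 0.04        # share of returns from the (visible) stem
_STEM_VISIBLE_FROM = 0.30      # stem occluded by canopy below this fraction
_GROUND_DENSITY = 50000.0      # returns per m^2 of bare soil
_GROUND_MARGIN = 0.15          # m, ground extends past the plot on each side

# Per-category plant size_scale ranges and canopy-radius caps (fractions of
# the in-row plant spacing).
_CATEGORY_SCALE = {
    "simple": (0.50, 0.65),
    "ordinary": (0.70, 0.80),
    "complex": (1.05, 1.25),
}
_CATEGORY_RADIUS_CAP = {
    "simple": 0.45,    # diameter 0.9x spacing -> guaranteed gap
    "ordinary": 0.571,  # overlap 2r - d <= 0.25 r  <=>  r <= d / 1.75
    "complex": 0.92,   # chains of >=3 overlapping canopies
}


@dataclass
class PlantModel:
    """Parametric soybean plant: stem plus planar elliptical leaves.

    ``leaves`` rows are ``(attach_height m, azimuth rad, inclination rad,
    a m, b m, center_offset m)`` where ``center_offset`` is the horizontal
    distance from the stem axis to the leaf-ellipse center.
    ``true_leaf_area`` is exactly ``sum(pi * a * b)``.
    """

    base: tuple[float, float]
    stem_height: float
    n_leaves: int
    leaves: np.ndarray  # (n_leaves, 6)
    canopy_radius: float
    true_leaf_area: float

    def __post_init__(self) -> None:
        if self.stem_height <= 0:
            raise ValueError("stem_height must be positive")
        if np.any(self.leaves[:, 3:5] <= 0):
            raise ValueError("leaf semi-axes must be positive")


@dataclass
class FieldScene:
    """A generated plot: labeled cloud, plant models and ground-truth LAI."""

    cloud: PointCloud
    plants: list[PlantModel]
    plot_extent: tuple[float, float]  # (length m along rows, width m across)
    true_lai: float
    adhesion_category: str

    def metadata(self) -> dict:
        """JSON-serializable scene metadata (plants, extent, true LAI)."""
        return {
            "adhesion_category": self.adhesion_category,
            "plot_extent": list(self.plot_extent),
            "true_lai": self.true_lai,
            "plants": [
                {
                    "base": list(p.base),
                    "stem_height": p.stem_height,
                    "n_leaves": p.n_leaves,
                    "canopy_radius": p.canopy_radius,
                    "true_leaf_area": p.true_leaf_area,
                }
                for p in self.plants
            ],
        }

    def save_metadata(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.metadata(), indent=1))


# ---------------------------------------------------------------------------
# plant generation

def _build_plant(
    rng: np.random.Generator,
    size_scale: float,
    n_leaves_range: tuple[int, int],
    max_radius: float | None,
    base: tuple[float, float] = (0.0, 0.0),
) -> PlantModel:
    if size_scale <= 0:
        raise ValueError("size_scale must be positive")
    lo, hi = n_leaves_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid n_leaves_range")
    n_leaves = int(rng.integers(lo, hi + 1))
    stem_height = _STEM_HEIGHT * size_scale * rng.uniform(0.92, 1.08)
    attach = stem_height * rng.uniform(*_ATTACH_FRAC, size=n_leaves)
    azimuth = rng.uniform(0.0, 2.0 * math.pi, size=n_leaves)
    incl = rng.uniform(*_LEAF_INCL, size=n_leaves)
    a = rng.uniform(*_LEAF_SEMI_A, size=n_leaves) * size_scale
    b = _LEAF_B_RATIO * a
    offset = a.copy()  # leaf center one semi-axis out from the stem
    reach = offset + a * np.cos(incl)
    radius = float(reach.max())
    if max_radius is not None and radius > max_radius:
        # shrink leaves (and their placement) so the canopy fits the cap;
        # true leaf area is recomputed from the shrunken semi-axes
        f = max_radius / radius
        a *= f
        b *= f
        offset *= f
        radius = float((offset + a * np.cos(incl)).max())
    leaves = np.column_stack([attach, azimuth, incl, a, b, offset])
    return PlantModel(
        base=base,
        stem_height=float(stem_height),
        n_leaves=n_leaves,
        leaves=leaves,
        canopy_radius=radius,
        true_leaf_area=float(np.sum(np.pi * a * b)),
    )


def generate_plant(
    rng_seed: int,
    size_scale: float = 1.0,
    n_leaves_range: tuple[int, int] = (40, 55),
    max_radius: float | None = None,
) -> PlantModel:
    """Generate one plant model, deterministic in ``rng_seed``.

    ``size_scale`` multiplies stem height and leaf semi-axes; leaf area (and
    so LAI) therefore grows quadratically with it.  ``max_radius`` optionally
    caps the horizontal canopy reach by shrinking the leaves.
    """
    rng = np.random.default_rng(rng_seed)
    return _build_plant(rng, size_scale, n_leaves_range, max_radius)


def _sample_plant_points(
    rng: np.random.Generator, plant: PlantModel, n_points: int
) -> np.ndarray:
    """Sample ``n_points`` on the plant surface, uniform per unit leaf area,
    plus a small fixed fraction on the canopy-visible part of the stem."""
    n_stem = int(round(_STEM_POINT_FRAC * n_points))
    n_leaf = n_points - n_stem
    areas = np.pi * plant.leaves[:, 3] * plant.leaves[:, 4]
    counts = rng.multinomial(n_leaf, areas / areas.sum())
    pts = np.empty((n_points, 3))
    pos = 0
    bx, by = plant.base
    for (attach, az, incl, a, b, off), m in zip(plant.leaves, counts):
        if m == 0:
            continue
        # uniform-by-area on the ellipse via polar inversion
        r = np.sqrt(rng.uniform(0.0, 1.0, m))
        t = rng.uniform(0.0, 2.0 * math.pi, m)
        u = a * r * np.cos(t)
        v = b * r * np.sin(t)
        ca, sa = math.cos(az), math.sin(az)
        radial = off + u * math.cos(incl)
        pts[pos : pos + m, 0] = bx + ca * radial - sa * v
        pts[pos : pos + m, 1] = by + sa * radial + ca * v
        pts[pos : pos + m, 2] = attach + u * math.sin(incl)
        pos += m
    if n_stem:
        z = rng.uniform(
            _STEM_VISIBLE_FROM * plant.stem_height, plant.stem_height, n_stem
        )
        ang = rng.uniform(0.0, 2.0 * math.pi, n_stem)
        r_st = 0.004  # stem radius, m
        pts[pos:, 0] = bx + r_st * np.cos(ang)
        pts[pos:, 1] = by + r_st * np.sin(ang)
        pts[pos:, 2] = z
    return pts


# ---------------------------------------------------------------------------
# scene generation

def _ground_height(x: np.ndarray, y: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Smooth random ground surface, amplitude <= 1 cm."""
    return (
        0.004 * np.sin(2 * np.pi * x / 1.3 + phases[0])
        + 0.003 * np.sin(2 * np.pi * y / 1.7 + phases[1])
        + 0.003 * np.sin(2 * np.pi * (x + y) / 0.9 + phases[2])
    )


def generate_scene(
    n_rows: int = 2,
    plants_per_row: int = 4,
    plant_spacing: float = 0.15,
    ridge_spacing: float = 0.8,
    adhesion: str = "ordinary",
    points_per_plant: tuple[int, int] = (10000, 20000),
    noise_sd: float = 0.03,
    outlier_frac: float = 0.01,
    rng_seed: int = 0,
    n_leaves_range: tuple[int, int] = (40, 55),
    size_scale_range: tuple[float, float] | None = None,
    ground_density: float = _GROUND_DENSITY,
) -> FieldScene:
    """Generate a labeled plot scene.

    Plants sit on ``n_rows`` ridges ``ridge_spacing`` apart, ``plants_per_row``
    per ridge at ``plant_spacing``.  ``adhesion`` picks the canopy-overlap
    regime (see module docstring); ``size_scale_range``, when given, overrides
    the category's default plant-size range (the category radius cap is then
    not enforced).  Ranging noise of sd ``noise_sd`` is applied along z with a
    0.15x horizontal component; ``outlier_frac`` of the surface returns are
    replaced-free uniform outliers in the scene bounding box (class -1).
    """
    if n_rows < 1 or plants_per_row < 1:
        raise ValueError("scene must contain at least one plant")
    if plant_spacing <= 0 or ridge_spacing <= 0:
        raise ValueError("spacings must be positive")
    if not (0 <= outlier_frac < 0.2):
        raise ValueError("outlier_frac must be in [0, 0.2)")
    if adhesion not in ADHESION_CATEGORIES:
        raise ValueError(f"adhesion must be one of {ADHESION_CATEGORIES}")
    rng = np.random.default_rng(rng_seed)

    if size_scale_range is None:
        scale_lo, scale_hi = _CATEGORY_SCALE[adhesion]
        radius_cap = _CATEGORY_RADIUS_CAP[adhesion] * plant_spacing
    else:
        scale_lo, scale_hi = size_scale_range
        radius_cap = None

    plants: list[PlantModel] = []
    coords_parts: list[np.ndarray] = []
    inst_parts: list[np.ndarray] = []
    pid = 0
    for row in range(n_rows):
        y0 = (row + 0.5) * ridge_spacing
        for i in range(plants_per_row):
            x0 = (i + 0.5) * plant_spacing
            scale = rng.uniform(scale_lo, scale_hi)
            plant = _build_plant(
                rng, scale, n_leaves_range, radius_cap, base=(x0, y0)
            )
            plants.append(plant)
            n_pts = int(rng.integers(points_per_plant[0], points_per_plant[1] + 1))
            coords_parts.append(_sample_plant_points(rng, plant, n_pts))
            inst_parts.append(np.full(n_pts, pid, dtype=np.int64))
            pid += 1

    length = plants_per_row * plant_spacing
    width = n_rows * ridge_spacing
    phases = rng.uniform(0.0, 2.0 * np.pi, 3)

    # ground returns over the plot plus a margin
    gx0, gx1 = -_GROUND_MARGIN, length + _GROUND_MARGIN
    gy0, gy1 = -_GROUND_MARGIN, width + _GROUND_MARGIN
    n_ground = int(round(ground_density * (gx1 - gx0) * (gy1 - gy0)))
    gx = rng.uniform(gx0, gx1, n_ground)
    gy = rng.uniform(gy0, gy1, n_ground)
    gz = _ground_height(gx, gy, phases)
    ground = np.column_stack([gx, gy, gz])

    plant_pts = np.vstack(coords_parts)
    n_plant = len(plant_pts)
    n_outlier = int(round(outlier_frac * (n_plant + n_ground)))
    zmax = max(p.stem_height for p in plants) + 0.25
    outliers = np.column_stack(
        [
            rng.uniform(gx0, gx1, n_outlier),
            rng.uniform(gy0, gy1, n_outlier),
            rng.uniform(0.0, zmax, n_outlier),
        ]
    )

    coords = np.vstack([plant_pts, ground, outliers])
    class_label = np.concatenate(
        [
            np.ones(n_plant, dtype=np.int64),
            np.zeros(n_ground, dtype=np.int64),
            -np.ones(n_outlier, dtype=np.int64),
        ]
    )
    instance_label = np.concatenate(
        [
            np.concatenate(inst_parts),
            -np.ones(n_ground + n_outlier, dtype=np.int64),
        ]
    )

    if noise_sd > 0:
        # nadir flight: ranging error is mostly vertical
        noise = rng.normal(0.0, noise_sd, size=(len(coords), 3))
        noise[:, :2] *= 0.15
        surface = class_label >= 0  # outliers are already positionless noise
        coords[surface] += noise[surface]

    cloud = PointCloud(
        coords=coords, class_label=class_label, instance_label=instance_label
    )
    scene = FieldScene(
        cloud=cloud,
        plants=plants,
        plot_extent=(length, width),
        true_lai=0.0,
        adhesion_category=adhesion,
    )
    scene.true_lai = scene_true_lai(scene)
    return scene


def scene_true_lai(scene: FieldScene) -> float:
    """Ground-truth LAI: total analytic leaf area over the plot ground area."""
    if not scene.plants:
        raise ValueError("scene has no plants")
    area = scene.plot_extent[0] * scene.plot_extent[1]
    return float(sum(p.true_leaf_area for p in scene.plants) / area)
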