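"""End-to-end orchestration and the synthetic benchmark harness.

``run_pipeline`` executes the full chain on one scene — generate (or load)
-> denoise -> ground removal -> individual segmentation -> per-instance
traits -> evaluation against ground truth — and writes every intermediate
artifact (labeled clouds, trait CSV, JSON reports) to an output directory.

``run_benchmark`` reproduces the simulated experimental design: scenes in
the three adhesion categories (default 15 simple / 18 ordinary / 9 complex),
both segmenters scored per plant with paired t-tests between methods, plus a
trait-based LAI regression study on independently generated single-plant
plots.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .eval_segmentation import compare_methods, match_instances, plot_accuracy, point_prf
from .lai_model import make_trait_table, run_lai_study
from .pointcloud_io import PointCloud, read_cloud, write_cloud
from .preprocess import ransac_ground_removal, statistical_outlier_removal
from .segment import kmeans_segment, watershed_segment
from .synthetic_field import FieldScene, generate_scene
from .traits import TraitConfig, extract_traits

logger = logging.getLogger("soycloud")

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "run_benchmark",
    "score_scene",
    "build_lai_table",
]


def _from_dict(cls, data: dict):
    import typing

    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    hints = typing.get_type_hints(cls)
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        ftype = hints.get(f.name, f.type)
        if dataclasses.is_dataclass(ftype) and isinstance(val, dict):
            val = _from_dict(ftype, val)
        kwargs[f.name] = val
    return cls(**kwargs)


@dataclass
class SceneConfig:
    n_rows: int = 2
    plants_per_row: int = 4
    plant_spacing: float = 0.15
    ridge_spacing: float = 0.8
    adhesion: str = "simple"
    points_per_plant: tuple[int, int] = (10000, 20000)
    noise_sd: float = 0.03
    outlier_frac: float = 0.01


@dataclass
class DenoiseConfig:
    n_neighbors: int = 10
    std_ratio: float = 1.0


@dataclass
class GroundConfig:
    dist_threshold: float = 0.05
    n_iterations: int = 500


@dataclass
class SegmentConfig:
    method: str = "watershed"  # watershed | kmeans
    resolution: float = 0.01
    marker_min_distance: float = 0.08
    h_depth: float = 0.02
    k: int | None = None  # k-means cluster count; None = true plant count
    max_iter: int = 100


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed and output directory."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    ground: GroundConfig = field(default_factory=GroundConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    traits: TraitConfig = field(default_factory=TraitConfig)
    input_cloud: str | None = None  # load instead of generating when set
    seed: int = 0
    outdir: str = "soycloud_out"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _from_dict(cls, data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".toml", ".tml"):
            import tomllib

            data = tomllib.loads(text)
        else:
            import yaml

            data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def validate(self) -> None:
        """Reject invalid parameter combinations before any stage runs."""
        sc, dn, gd, sg, tr = self.scene, self.denoise, self.ground, self.segment, self.traits
        checks = [
            (sc.n_rows >= 1 and sc.plants_per_row >= 1, "scene must have >= 1 plant"),
            (sc.plant_spacing > 0 and sc.ridge_spacing > 0, "spacings must be positive"),
            (0 <= sc.outlier_frac < 0.2, "outlier_frac must be in [0, 0.2)"),
            (sc.noise_sd >= 0, "noise_sd must be non-negative"),
            (dn.n_neighbors >= 1, "n_neighbors must be >= 1"),
            (dn.std_ratio > 0, "std_ratio must be positive"),
            (gd.dist_threshold > 0, "dist_threshold must be positive"),
            (gd.n_iterations >= 1, "n_iterations must be >= 1"),
            (sg.method in ("watershed", "kmeans"), f"unknown method {sg.method!r}"),
            (sg.resolution > 0, "resolution must be positive"),
            (sg.marker_min_distance >= 0, "marker_min_distance must be >= 0"),
            (sg.h_depth >= 0, "h_depth must be >= 0"),
            (sg.k is None or sg.k >= 1, "k must be >= 1"),
            (tr.vos > 0, "vos must be positive"),
            (tr.cr_radius > 0, "cr_radius must be positive"),
            (tr.cell_size > 0, "cell_size must be positive"),
            (tr.cover_bins >= 2, "cover_bins must be >= 2"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def prepare_plants(
    cloud: PointCloud,
    denoise: DenoiseConfig | None = None,
    ground: GroundConfig | None = None,
    rng_seed: int = 0,
):
    """Denoise, remove the ground, then denoise the plant cloud again.

    The second statistical pass targets ground residue: soil returns more
    than ``dist_threshold`` above the fitted plane survive ground removal,
    but once the dense soil layer beneath them is gone they are isolated
    and fall to the same neighbor-distance criterion as sensor outliers.

    Returns ``(plants, ground_cloud, plane)``.
    """
    dn = denoise or DenoiseConfig()
    gd = ground or GroundConfig()
    cloud, _ = statistical_outlier_removal(cloud, dn.n_neighbors, dn.std_ratio)
    plants, ground_cloud, plane = ransac_ground_removal(
        cloud, gd.dist_threshold, gd.n_iterations, rng_seed
    )
    if len(plants) > dn.n_neighbors:
        plants, _ = statistical_outlier_removal(plants, dn.n_neighbors, dn.std_ratio)
    return plants, ground_cloud, plane


def score_scene(
    scene: FieldScene,
    method: str = "watershed",
    denoise: DenoiseConfig | None = None,
    ground: GroundConfig | None = None,
    segment: SegmentConfig | None = None,
    rng_seed: int = 0,
    plants: PointCloud | None = None,
) -> dict:
    """Run denoise -> ground removal -> segmentation on one scene and score
    it against the per-point ground truth.

    ``plants`` may carry a precomputed plant cloud (from
    :func:`prepare_plants`) to share preprocessing between methods.
    Returns per-plant precision/recall/F1 (truly segmented plants only),
    plot accuracy, and the segmented plant cloud.
    """
    sg = segment or SegmentConfig(method=method)
    if plants is None:
        plants, _, plane = prepare_plants(scene.cloud, denoise, ground, rng_seed)
    else:
        plane = None
    if method == "watershed":
        seg = watershed_segment(
            plants, sg.resolution, sg.marker_min_distance, sg.h_depth
        )
    elif method == "kmeans":
        k = sg.k if sg.k is not None else len(scene.plants)
        seg = kmeans_segment(plants, k, rng_seed, sg.max_iter)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    match = match_instances(seg, plants.instance_label)
    per_plant, means = point_prf(match)
    arr = (
        np.array(list(per_plant.values()))
        if per_plant
        else np.empty((0, 3))
    )
    return {
        "method": method,
        "accuracy": plot_accuracy(match),
        "per_plant": per_plant,
        "precision": arr[:, 0] if len(arr) else np.array([]),
        "recall": arr[:, 1] if len(arr) else np.array([]),
        "f1": arr[:, 2] if len(arr) else np.array([]),
        "mean_prf": means,
        "n_true": match.n_true,
        "n_pred": match.n_pred,
        "segmented_cloud": plants.with_instances(seg.instance_label),
        "plane": plane,
        "match": match,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline per ``config`` and write the report bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
    timings: dict[str, float] = {}

    t0 = _stage("input")
    scene = None
    if config.input_cloud:
        cloud = read_cloud(config.input_cloud)
    else:
        scene = generate_scene(
            n_rows=config.scene.n_rows,
            plants_per_row=config.scene.plants_per_row,
            plant_spacing=config.scene.plant_spacing,
            ridge_spacing=config.scene.ridge_spacing,
            adhesion=config.scene.adhesion,
            points_per_plant=tuple(config.scene.points_per_plant),
            noise_sd=config.scene.noise_sd,
            outlier_frac=config.scene.outlier_frac,
            rng_seed=config.seed,
        )
        cloud = scene.cloud
        scene.save_metadata(outdir / "scene_meta.json")
        write_cloud(cloud, outdir / "scene.xyz")
    timings["input"] = time.perf_counter() - t0

    t0 = _stage("denoise")
    cloud, removed = statistical_outlier_removal(
        cloud, config.denoise.n_neighbors, config.denoise.std_ratio
    )
    timings["denoise"] = time.perf_counter() - t0

    t0 = _stage("ground_removal")
    plants, ground_cloud, plane = ransac_ground_removal(
        cloud, config.ground.dist_threshold, config.ground.n_iterations, config.seed
    )
    if len(plants) > config.denoise.n_neighbors:
        plants, _ = statistical_outlier_removal(
            plants, config.denoise.n_neighbors, config.denoise.std_ratio
        )
    timings["ground_removal"] = time.perf_counter() - t0

    t0 = _stage("segment")
    sg = config.segment
    if sg.method == "watershed":
        seg = watershed_segment(plants, sg.resolution, sg.marker_min_distance, sg.h_depth)
    elif sg.method == "kmeans":
        k = sg.k if sg.k is not None else (len(scene.plants) if scene else 1)
        seg = kmeans_segment(plants, k, config.seed, sg.max_iter)
    else:
        raise ValueError(f"unknown segmentation method {sg.method!r}")
    labeled = plants.with_instances(seg.instance_label)
    write_cloud(labeled, outdir / "segmented.xyz")
    timings["segment"] = time.perf_counter() - t0

    t0 = _stage("traits")
    tcfg = dataclasses.replace(config.traits, ground_z=float(plane.offset))
    rows = []
    for inst in range(seg.n_instances):
        sub = labeled.select(labeled.instance_label == inst)
        tv = extract_traits(sub, tcfg)
        rows.append({"instance": inst, "n_points": len(sub), **asdict(tv)})
    trait_df = pd.DataFrame(rows)
    trait_df.to_csv(outdir / "traits.csv", index=False)
    timings["traits"] = time.perf_counter() - t0

    report: dict = {
        "n_input": int(len(cloud) + len(removed)),
        "n_denoised": int(len(cloud)),
        "n_plants_points": int(len(plants)),
        "n_ground_points": int(len(ground_cloud)),
        "n_instances": int(seg.n_instances),
        "timings_s": timings,
    }
    if scene is not None:
        match = match_instances(seg, plants.instance_label)
        per_plant, means = point_prf(match)
        report["evaluation"] = {
            "accuracy": plot_accuracy(match),
            "mean_precision": means[0],
            "mean_recall": means[1],
            "mean_f1": means[2],
            "true_lai": scene.true_lai,
        }
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report


# ---------------------------------------------------------------------------
# benchmark harness

def build_lai_table(
    n_plots: int = 140,
    seed_offset: int = 0,
    size_scale_range: tuple[float, float] = (0.7, 1.4),
    noise_sd: float = 0.03,
    trait_config: TraitConfig | None = None,
) -> pd.DataFrame:
    """Generate single-plant plots, extract traits, pair with true LAI.

    Plot ``i`` uses scene seed ``seed_offset + i + 1`` and a plant size
    scale drawn uniformly from ``size_scale_range``; observed LAI is the
    scene's analytic ground truth.
    """
    ids, traits, lais = [], [], []
    for i in range(n_plots):
        seed = seed_offset + i + 1
        rng = np.random.default_rng(seed)
        scale = float(rng.uniform(*size_scale_range))
        scene = generate_scene(
            n_rows=1,
            plants_per_row=1,
            adhesion="ordinary",
            size_scale_range=(scale, scale),
            noise_sd=noise_sd,
            rng_seed=seed,
        )
        plants, _, plane = prepare_plants(scene.cloud, rng_seed=seed)
        tcfg = dataclasses.replace(
            trait_config or TraitConfig(), ground_z=float(plane.offset)
        )
        traits.append(extract_traits(plants, tcfg))
        ids.append(seed)
        lais.append(scene.true_lai)
    return make_trait_table(ids, traits, lais)


def run_benchmark(
    n_simple: int = 15,
    n_ordinary: int = 18,
    n_complex: int = 9,
    seed_offset: int = 0,
    n_lai_plots: int = 140,
    split_seed: int = 7,
    outdir: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full synthetic study: both segmenters on a three-category
    scene benchmark, then the trait-based LAI regression.

    Scene ``j`` (1-based across categories) uses seed ``seed_offset + j``.
    Returns a dict with per-category method tables, paired t-tests, pooled
    metrics and LAI fit reports; writes CSV/JSON mirrors when ``outdir``.
    """
    cfg = config or PipelineConfig()
    categories = (
        ["simple"] * n_simple + ["ordinary"] * n_ordinary + ["complex"] * n_complex
    )
    if not categories:
        raise ValueError("need at least one scene")
    per_scene_rows = []
    pooled: dict[str, dict[str, list]] = {
        m: {"precision": [], "recall": [], "f1": [], "accuracy": []}
        for m in ("watershed", "kmeans")
    }
    percat: dict[tuple[str, str], dict[str, list]] = {}
    scene_means: dict[str, list[tuple[float, float, float]]] = {
        "watershed": [], "kmeans": []
    }
    for j, cat in enumerate(categories, start=1):
        seed = seed_offset + j
        scene = generate_scene(
            n_rows=cfg.scene.n_rows,
            plants_per_row=cfg.scene.plants_per_row,
            plant_spacing=cfg.scene.plant_spacing,
            ridge_spacing=cfg.scene.ridge_spacing,
            adhesion=cat,
            points_per_plant=tuple(cfg.scene.points_per_plant),
            noise_sd=cfg.scene.noise_sd,
            outlier_frac=cfg.scene.outlier_frac,
            rng_seed=seed,
        )
        plants_cloud, _, _ = prepare_plants(
            scene.cloud, cfg.denoise, cfg.ground, rng_seed=seed
        )
        for method in ("watershed", "kmeans"):
            res = score_scene(
                scene, method, cfg.denoise, cfg.ground,
                dataclasses.replace(cfg.segment, method=method), rng_seed=seed,
                plants=plants_cloud,
            )
            pooled[method]["precision"].extend(res["precision"])
            pooled[method]["recall"].extend(res["recall"])
            pooled[method]["f1"].extend(res["f1"])
            pooled[method]["accuracy"].append(res["accuracy"])
            bucket = percat.setdefault(
                (cat, method), {"precision": [], "recall": [], "f1": []}
            )
            bucket["precision"].extend(res["precision"])
            bucket["recall"].extend(res["recall"])
            bucket["f1"].extend(res["f1"])
            scene_means[method].append(res["mean_prf"])
            per_scene_rows.append(
                {
                    "scene": seed,
                    "category": cat,
                    "method": method,
                    "accuracy": res["accuracy"],
                    "mean_precision": res["mean_prf"][0],
                    "mean_recall": res["mean_prf"][1],
                    "mean_f1": res["mean_prf"][2],
                    "n_instances": res["n_pred"],
                }
            )
        logger.info("benchmark scene %d/%d (%s) done", j, len(categories), cat)

    category_table = []
    for cat in ("simple", "ordinary", "complex"):
        for method in ("watershed", "kmeans"):
            b = percat.get((cat, method))
            if not b:
                continue
            row = {"category": cat, "method": method}
            for metric in ("precision", "recall", "f1"):
                v = np.asarray(b[metric])
                row[f"{metric}_mean"] = float(v.mean()) if len(v) else float("nan")
                row[f"{metric}_std"] = float(v.std(ddof=1)) if len(v) > 1 else 0.0
            category_table.append(row)

    # paired per-scene t-tests between methods (scene mean metrics)
    ws = np.array(scene_means["watershed"], dtype=np.float64)
    km = np.array(scene_means["kmeans"], dtype=np.float64)
    ok = np.all(np.isfinite(ws), axis=1) & np.all(np.isfinite(km), axis=1)
    ttests = {}
    if ok.sum() >= 2:
        for i, metric in enumerate(("precision", "recall", "f1")):
            ttests[metric] = compare_methods(ws[ok, i], km[ok, i])

    pooled_summary = {
        m: {
            "mean_precision": float(np.mean(v["precision"])) if v["precision"] else None,
            "mean_recall": float(np.mean(v["recall"])) if v["recall"] else None,
            "mean_f1": float(np.mean(v["f1"])) if v["f1"] else None,
            "mean_accuracy": float(np.mean(v["accuracy"])),
            "n_plants_scored": len(v["f1"]),
        }
        for m, v in pooled.items()
    }

    if n_lai_plots > 0:
        lai_table = build_lai_table(
            n_plots=n_lai_plots,
            seed_offset=seed_offset,
            noise_sd=cfg.scene.noise_sd,
            trait_config=cfg.traits,
        )
        lai_reports = run_lai_study(lai_table, train_frac=0.3, rng_seed=split_seed)
    else:
        lai_table = pd.DataFrame()
        lai_reports = {}

    result = {
        "per_scene": per_scene_rows,
        "category_table": category_table,
        "ttests": ttests,
        "pooled": pooled_summary,
        "lai_table": lai_table,
        "lai_reports": {m: r.to_dict() for m, r in lai_reports.items()},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(per_scene_rows).to_csv(outdir / "per_scene.csv", index=False)
        pd.DataFrame(category_table).to_csv(outdir / "category_table.csv", index=False)
        lai_table.to_csv(outdir / "lai_table.csv", index=False)
        (outdir / "benchmark.json").write_text(
            json.dumps(
                {
                    "pooled": pooled_summary,
                    "ttests": ttests,
                    "lai_reports": result["lai_reports"],
                },
                indent=1,
            )
        )
    return result
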