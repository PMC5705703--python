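"""End-to-end orchestration: segment -> density + coherency + fibers -> compare.

A single TOML config drives the run: an image table (path, animal, group,
optional hemisphere, pixel scale), segmentation parameters, orientation
sigmas, the spur-prune length, and a comparison plan.  Per-image metrics
are averaged per animal (field averaging precedes any statistics: one
value per animal), then the plan's group comparisons are computed.
Outputs are ``per_image.csv``, ``per_animal.csv``, ``comparisons.csv``,
overlay PNGs and ``run.log``; every output is stamped with the config
hash and software version, and a rerun with an identical config is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
import tomllib
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import __version__
from .io import Micrograph, RegionOfInterest, read_micrograph, write_overlay
from .segmentation import SegmentationParams, segment
from .density import positive_area_fraction, darkest_fraction_roi, immunodensity
from .orientation import structure_tensor, coherency
from .skeleton import analyze_fibers
from .stats import compare_two

__all__ = ["ImageEntry", "RunConfig", "run_pipeline", "load_config", "measure_image"]

#: metrics compared by default when the plan names none
DEFAULT_METRICS = (
    "positive_area_pct",
    "immunodensity_raw",
    "coherency",
    "total_fiber_length",
    "fiber_length_density",
    "n_intersections",
    "intersection_density",
    "mean_fiber_diameter",
    "porosity",
)


@dataclass
class ImageEntry:
    path: str
    animal_id: str
    group: str
    pixel_size: float
    hemisphere: str = ""


@dataclass
class RunConfig:
    images: list[ImageEntry]
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)
    sigma_gradient: float = 1.0
    sigma_window: float = 4.0
    prune_um: float = 3.0
    comparisons: list[tuple[str, str]] = dc_field(default_factory=list)
    metrics: list[str] = dc_field(default_factory=lambda: list(DEFAULT_METRICS))
    out_dir: str = "results"
    seed: int = 0
    write_overlays: bool = True

    def validate(self) -> None:
        if not self.images:
            raise ValueError("config lists no images")
        for e in self.images:
            if not os.path.exists(e.path):
                raise FileNotFoundError(f"image not found: {e.path}")
            if e.pixel_size <= 0:
                raise ValueError(f"non-positive pixel_size for {e.path}")
        groups = {e.group for e in self.images}
        for a, b in self.comparisons:
            for g in (a, b):
                if g not in groups:
                    raise ValueError(f"comparison group {g!r} not in image table")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "images": [vars(e) for e in self.images],
                "segmentation": vars(self.segmentation),
                "sigma_gradient": self.sigma_gradient,
                "sigma_window": self.sigma_window,
                "prune_um": self.prune_um,
                "comparisons": self.comparisons,
                "metrics": self.metrics,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | os.PathLike) -> RunConfig:
    """Parse a TOML run config; see the README for the schema."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    images = [
        ImageEntry(
            path=i["path"],
            animal_id=str(i["animal_id"]),
            group=str(i["group"]),
            pixel_size=float(i["pixel_size"]),
            hemisphere=str(i.get("hemisphere", "")),
        )
        for i in raw.get("images", [])
    ]
    seg = SegmentationParams(**raw.get("segmentation", {}))
    opts = raw.get("pipeline", {})
    comparisons = [tuple(c) for c in raw.get("comparisons", [])]
    return RunConfig(
        images=images,
        segmentation=seg,
        sigma_gradient=float(opts.get("sigma_gradient", 1.0)),
        sigma_window=float(opts.get("sigma_window", 4.0)),
        prune_um=float(opts.get("prune_um", 3.0)),
        comparisons=comparisons,
        metrics=list(opts.get("metrics", DEFAULT_METRICS)),
        out_dir=str(opts.get("out_dir", "results")),
        seed=int(opts.get("seed", 0)),
        write_overlays=bool(opts.get("write_overlays", True)),
    )


def measure_image(
    image: Micrograph,
    seg_params: SegmentationParams,
    sigma_gradient: float = 1.0,
    sigma_window: float = 4.0,
    prune_um: float = 3.0,
) -> tuple[dict[str, float], "np.ndarray", "np.ndarray"]:
    """All per-image metrics; returns (metrics, mask, skeleton raster)."""
    mask = segment(image, seg_params)
    background = darkest_fraction_roi(image)
    # signal region: the whole field, matching fixed-field acquisition
    signal = RegionOfInterest(np.ones(image.shape, dtype=bool), "signal")
    dens = immunodensity(image, signal, background)
    coh = coherency(structure_tensor(image, sigma_gradient, sigma_window))
    fib, g = analyze_fibers(mask, prune_um, return_graph=True)
    metrics = {
        "positive_area_pct": positive_area_fraction(mask),
        "immunodensity_raw": dens,
        "coherency": coh.coherency,
        "orientation_deg": coh.orientation_deg,
        "total_fiber_length": fib.total_fiber_length,
        "fiber_length_density": fib.fiber_length_density,
        "mean_segment_length": fib.mean_segment_length,
        "n_intersections": float(fib.n_intersections),
        "intersection_density": fib.intersection_density,
        "mean_fiber_diameter": fib.mean_fiber_diameter,
        "porosity": fib.porosity,
    }
    return metrics, mask.mask, g.skeleton_mask


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full workflow; returns the three result tables.

    Writes ``per_image.csv``, ``per_animal.csv``, ``comparisons.csv``,
    overlay PNGs and ``run.log`` under ``config.out_dir``.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    chash = config.config_hash()
    log_lines = [
        f"myeliq {__version__} run, config hash {chash}",
        f"segmentation: {vars(config.segmentation)}",
        f"sigma_gradient={config.sigma_gradient} sigma_window={config.sigma_window}",
        f"prune_um={config.prune_um} seed={config.seed}",
        f"n_images={len(config.images)}",
    ]

    per_image_rows = []
    for entry in config.images:
        try:
            img = read_micrograph(entry.path, entry.pixel_size)
            metrics, mask, skel = measure_image(
                img,
                config.segmentation,
                config.sigma_gradient,
                config.sigma_window,
                config.prune_um,
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline failed on image {entry.path!r}: {exc}") from exc
        if config.write_overlays:
            stem = os.path.splitext(os.path.basename(entry.path))[0]
            write_overlay(img, mask, os.path.join(config.out_dir, f"{stem}_mask.png"))
            write_overlay(
                img, skel, os.path.join(config.out_dir, f"{stem}_thinning.png")
            )
        for name, value in metrics.items():
            per_image_rows.append(
                {
                    "path": entry.path,
                    "animal_id": entry.animal_id,
                    "group": entry.group,
                    "hemisphere": entry.hemisphere,
                    "metric": name,
                    "value": value,
                }
            )
        log_lines.append(f"measured {entry.path}")

    per_image = pd.DataFrame(per_image_rows)
    # field averaging: one value per animal per metric, before any statistics
    per_animal = (
        per_image.groupby(["animal_id", "group", "metric"], as_index=False)["value"]
        .mean()
        .sort_values(["metric", "group", "animal_id"], kind="mergesort")
        .reset_index(drop=True)
    )

    comp_rows = []
    for (ga, gb) in config.comparisons:
        for metric in config.metrics:
            sub = per_animal[per_animal["metric"] == metric]
            va = sub[sub["group"] == ga]["value"].to_numpy()
            vb = sub[sub["group"] == gb]["value"].to_numpy()
            if va.size < 2 or vb.size < 2:
                continue
            res = compare_two(va, vb)
            comp_rows.append(
                {
                    "metric": metric,
                    "group_a": ga,
                    "group_b": gb,
                    "test": res.test,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "mean_a": res.group_means[0],
                    "mean_b": res.group_means[1],
                    "sem_a": res.group_sems[0],
                    "sem_b": res.group_sems[1],
                    "n_a": res.group_ns[0],
                    "n_b": res.group_ns[1],
                }
            )
    comparisons = pd.DataFrame(comp_rows)

    stamp = f"# myeliq {__version__} config {chash}\n"
    for name, df in (
        ("per_image", per_image),
        ("per_animal", per_animal),
        ("comparisons", comparisons),
    ):
        out_path = os.path.join(config.out_dir, f"{name}.csv")
        with open(out_path, "w") as fh:
            fh.write(stamp)
            df.to_csv(fh, index=False)
    with open(os.path.join(config.out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return {"per_image": per_image, "per_animal": per_animal, "comparisons": comparisons}
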