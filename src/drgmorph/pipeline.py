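"""End-to-end orchestration: simulate → preprocess → profile → metrics → stats.

The pipeline consumes either a synthetic cohort (generated on the fly)
or a directory of TIFF images with a manifest CSV giving, per neuron,
the image path, soma seed point in pixels, pixel size and group label.
It writes per-neuron Sholl profiles, per-neuron morphometric and
branching metrics, group-comparison tables, and a run log.  Per-neuron
analysis failures are recorded and skipped — real cultures contain
unanalyzable cells — but an empty cohort is fatal.  All outputs are
deterministic given the configuration and master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .branching import compute_metrics
from .errors import DrgMorphError, InvalidParameterError
from .image_prep import clean_mask, segment_soma, threshold_image
from .morphometry import (MIN_NEURITE_EXTENSION_UM, SIZE_CUTOFF_UM,
                          classify_neurite_bearing, classify_size)
from .sholl import ShollGrid, compute_profile, summarize_profile
from .synthetic import GrowthParams, RasterConfig, auto_raster_config, make_cohort

logger = logging.getLogger("drgmorph")

#: endpoints compared between treatment groups
ENDPOINTS = ["Bmax", "Bmin", "Bsmax", "Bsmin",
             "enclosing_radius_um", "max_intersections", "radius_of_max_um"]


@dataclass
class GroupSpec:
    label: str
    n_neurons: int
    growth: GrowthParams


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible run."""

    mode: str = "synthetic"            # synthetic | images
    outdir: str = "results/run"
    seed: int = 0
    day: int = 1
    # Sholl grid
    start_radius: float = 50.0
    step: float = 10.0
    n_radii: int | None = None         # None: cover the frame
    # preprocessing
    threshold_method: str = "otsu"
    threshold_level: int | None = None
    min_component_px: int = 20
    line_width_px: int = 3
    # morphometry
    size_cutoff_um: float = SIZE_CUTOFF_UM
    min_extension_um: float = MIN_NEURITE_EXTENSION_UM
    # statistics
    adjust: str = "bonferroni"
    # synthetic mode
    groups: list[GroupSpec] = field(default_factory=list)
    raster: RasterConfig = field(default_factory=RasterConfig)
    # images mode
    image_dir: str | None = None
    manifest: str | None = None
    write_qc_masks: bool = False

    @property
    def opening_radius_px(self) -> int:
        # disk strictly wider than the neurite line width
        return int(np.ceil(1.5 * self.line_width_px))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        groups = [GroupSpec(label=g["label"], n_neurons=int(g["n_neurons"]),
                            growth=GrowthParams(**g.get("growth", {})))
                  for g in raw.pop("groups", [])]
        raster = RasterConfig(**raw.pop("raster", {}))
        return cls(groups=groups, raster=raster, **raw)


def analyze_neuron(image: np.ndarray, soma_center_px: tuple[float, float],
                   pixel_size: float, grid: ShollGrid,
                   config: PipelineConfig) -> dict:
    """Run preprocessing, Sholl profiling and morphometry on one image.

    Returns a flat record dict; raises a DrgMorphError subclass when the
    neuron cannot be analyzed.
    """
    mask = threshold_image(image, method=config.threshold_method,
                           level=config.threshold_level)
    clean = clean_mask(mask, soma_center_px, pixel_size,
                       min_component_px=config.min_component_px)
    soma = segment_soma(clean, opening_radius_px=config.opening_radius_px)
    profile = compute_profile(clean, soma, grid)
    summary = summarize_profile(profile)
    metrics = compute_metrics(profile, grid)
    return {
        "soma_diameter_um": soma.soma_diameter,
        "size_class": classify_size(soma.soma_diameter, cutoff=config.size_cutoff_um),
        "neurite_bearing": classify_neurite_bearing(
            clean, soma, min_extension_um=config.min_extension_um),
        "enclosing_radius_um": summary.enclosing_radius,
        "max_intersections": summary.max_intersections,
        "radius_of_max_um": summary.radius_of_max,
        "Bmax": metrics.Bmax, "Bmin": metrics.Bmin,
        "Bsmax": metrics.Bsmax, "Bsmin": metrics.Bsmin,
        "profile_counts": profile.counts.tolist(),
    }


def _grid_for_frame(config: PipelineConfig, shape: tuple[int, int],
                    center_px: tuple[float, float], pixel_size: float) -> ShollGrid:
    if config.n_radii is not None:
        return ShollGrid(config.start_radius, config.step, config.n_radii)
    h, w = shape
    x, y = center_px
    room_px = min(x, y, (w - 1) - x, (h - 1) - y) - 1.0
    max_radius = room_px * pixel_size
    n = int(np.floor((max_radius - config.start_radius) / config.step)) + 1
    if n < 1:
        raise InvalidParameterError("frame too small for even one Sholl radius")
    return ShollGrid(config.start_radius, config.step, n)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns paths of the written outputs."""
    from .stats import compare_groups  # local import keeps module load light

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.mode == "synthetic":
        if not config.groups:
            raise InvalidParameterError("synthetic mode needs at least one group")
        raster = config.raster
        # frame must hold the largest possible arbor of any group
        worst = max((g.growth for g in config.groups),
                    key=lambda p: p.soma_diameter / 2 + p.max_steps * p.step_len)
        raster = auto_raster_config(worst, base=raster)
        image_dir = outdir / "images"
        manifest = make_cohort(
            [(g.label, g.growth, g.n_neurons) for g in config.groups],
            raster, seed=config.seed, outdir=image_dir, day=config.day)
    elif config.mode == "images":
        if not (config.image_dir and config.manifest):
            raise InvalidParameterError("images mode needs image_dir and manifest")
        image_dir = Path(config.image_dir)
        manifest = pd.read_csv(config.manifest)
    else:
        raise InvalidParameterError(f"unknown mode {config.mode!r}")

    records, profile_rows, failures = [], [], []
    grid: ShollGrid | None = None
    for row in manifest.itertuples(index=False):
        try:
            image = tifffile.imread(image_dir / row.tiff_path)
            center = (float(row.soma_x_px), float(row.soma_y_px))
            px = float(row.pixel_size_um)
            if grid is None:
                grid = _grid_for_frame(config, image.shape, center, px)
            rec = analyze_neuron(image, center, px, grid, config)
        except (DrgMorphError, OSError, ValueError) as exc:
            logger.warning("neuron %s excluded: %s", row.neuron_id, exc)
            failures.append({"neuron_id": row.neuron_id, "error": str(exc)})
            continue
        counts = rec.pop("profile_counts")
        for r, n in zip(grid.radii, counts):
            profile_rows.append({"neuron_id": row.neuron_id,
                                 "radius_um": float(r), "n_intersections": int(n)})
        rec.update({"neuron_id": row.neuron_id, "group": row.group, "day": row.day})
        records.append(rec)

    if not records:
        raise DrgMorphError("empty cohort: no neuron could be analyzed")

    metrics_df = pd.DataFrame(records)
    front = ["neuron_id", "group", "day"]
    metrics_df = metrics_df[front + [c for c in metrics_df.columns if c not in front]]
    profiles_df = pd.DataFrame(profile_rows)

    comparison_rows = []
    if metrics_df["group"].nunique() >= 2:
        for var in ENDPOINTS:
            sub = metrics_df.dropna(subset=[var])
            if sub.groupby("group").size().min() < 1 or sub["group"].nunique() < 2:
                continue
            comp = compare_groups(sub, var, adjust=config.adjust)
            for pw in comp.pairwise.itertuples(index=False):
                comparison_rows.append({
                    "variable": var, "day": config.day,
                    "group_a": pw.group_a, "group_b": pw.group_b,
                    "n_a": pw.n_a, "n_b": pw.n_b,
                    "kw_H": comp.statistic, "kw_p": comp.p_value,
                    "z": pw.z, "p_raw": pw.p_raw, "p_adj": pw.p_adj,
                    "tier": pw.tier})
    comparisons_df = pd.DataFrame(comparison_rows)

    paths = {"metrics": outdir / "metrics.csv",
             "profiles": outdir / "profiles.csv",
             "comparisons": outdir / "comparisons.csv",
             "log": outdir / "run_log.json"}
    metrics_df.to_csv(paths["metrics"], index=False, float_format="%.6g")
    profiles_df.to_csv(paths["profiles"], index=False)
    comparisons_df.to_csv(paths["comparisons"], index=False, float_format="%.6g")

    log = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if k not in ("groups", "raster")},
        "grid": {"start_radius": grid.start_radius, "step": grid.step,
                 "n_radii": grid.n_radii},
        "n_analyzed": len(records),
        "n_excluded": len(failures),
        "failures": failures,
    }
    paths["log"].write_text(json.dumps(log, indent=2, default=str))
    logger.info("pipeline done: %d neurons analyzed, %d excluded",
                len(records), len(failures))
    return {k: str(v) for k, v in paths.items()}
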