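"""Shared fixtures: phantom neurons and small analyzed cohorts.

Everything is generated programmatically; no image files ship with the
test suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import drgmorph as dm


def grow_centered(params: dm.GrowthParams, cfg: dm.RasterConfig):
    """Grow an arbor centred in the frame; returns (tree, center_px)."""
    px = cfg.pixel_size
    center_um = ((cfg.width - 1) / 2.0 * px, (cfg.height - 1) / 2.0 * px)
    tree = dm.grow_arbor(params, soma_center=center_um)
    center_px = (center_um[0] / px, center_um[1] / px)
    return tree, center_px


def analyze_mask(image: np.ndarray, center_px, pixel_size: float,
                 opening_radius_px: int = 5):
    """threshold → clean → soma for one image; returns (clean, soma)."""
    mask = dm.threshold_image(image)
    clean = dm.clean_mask(mask, center_px, pixel_size)
    soma = dm.segment_soma(clean, opening_radius_px=opening_radius_px)
    return clean, soma


def frame_grid(cfg: dm.RasterConfig, center_px, start=50.0, step=10.0,
               rmax: float | None = None) -> dm.ShollGrid:
    """Largest 50/10 grid that fits the frame (optionally capped at rmax)."""
    room = (min(center_px[0], center_px[1],
                cfg.width - 1 - center_px[0],
                cfg.height - 1 - center_px[1]) - 1) * cfg.pixel_size
    top = min(room, rmax) if rmax is not None else room
    n = int(np.floor((top - start) / step)) + 1
    return dm.ShollGrid(start, step, max(1, n))


#: straight 4-ray neuron: 20 µm soma, rays of 110 µm, tips at 120 µm radius
PHANTOM_PARAMS = dm.GrowthParams(n_primary=4, branch_prob=0.0, term_prob=0.0,
                                 angle_sd=0.0, step_len=10.0, max_steps=11,
                                 soma_diameter=20.0, seed=1)


@pytest.fixture(scope="session")
def phantom():
    """Noiseless rendered 4-ray phantom with its analysis chain."""
    cfg = dm.RasterConfig(noise_sd=0.0, debris_count=0, pixel_size=1.0,
                          width=301, height=301)
    tree, center_px = grow_centered(PHANTOM_PARAMS, cfg)
    image = dm.rasterize(tree, cfg, seed=0)
    clean, soma = analyze_mask(image, center_px, cfg.pixel_size)
    return {"params": PHANTOM_PARAMS, "cfg": cfg, "tree": tree,
            "center_px": center_px, "image": image, "clean": clean,
            "soma": soma, "grid": dm.ShollGrid(50.0, 10.0, 10)}


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """Two groups x three neurons, written to disk with a manifest."""
    outdir = tmp_path_factory.mktemp("cohort")
    params = dm.GrowthParams(max_steps=10, soma_diameter=40.0)
    cfg = dm.auto_raster_config(params, dm.RasterConfig())
    manifest = dm.make_cohort(
        [("ctrl", params, 3),
         ("gf", dm.GrowthParams(max_steps=10, soma_diameter=40.0,
                                branch_prob=0.08), 3)],
        cfg, seed=11, outdir=outdir)
    return outdir, manifest, cfg
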