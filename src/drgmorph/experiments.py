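"""Cohort-level simulation experiments on the branching statistics.

These routines run the generator → oracle-profile → branching-metrics
chain at cohort scale to characterise the statistical behaviour of the
endpoints: the power of the Kruskal–Wallis comparison to separate
growth conditions that differ in branching probability, its type-I
error under identically distributed groups, and the correlation
structure between minimum and maximum branching rates.  They work on
ground-truth geometry (the exact Sholl oracle) rather than rendered
images, which makes thousand-replicate experiments cheap while
exercising exactly the same downstream mathematics as the image
pipeline.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .branching import compute_metrics
from .sholl import ShollGrid, summarize_profile
from .stats import ALPHA, kruskal_wallis, pearson_corr
from .synthetic import GrowthParams, grow_arbor, oracle_sholl


def _grid_for(params: GrowthParams) -> ShollGrid:
    worst = params.soma_diameter / 2.0 + params.max_steps * params.step_len
    return ShollGrid.covering(worst + params.step_len)


def sample_metrics(params: GrowthParams, n: int, seed: int,
                   grid: ShollGrid | None = None) -> pd.DataFrame:
    """Per-neuron endpoint table for ``n`` neurons grown with ``params``.

    Neuron seeds derive deterministically from ``seed``; profiles come
    from the exact geometric oracle on a grid wide enough for the
    largest possible arbor.
    """
    grid = grid or _grid_for(params)
    rows = []
    for j in range(n):
        sub = int(np.random.SeedSequence([seed, j]).generate_state(1)[0] % (2 ** 31))
        tree = grow_arbor(dataclasses.replace(params, seed=sub))
        profile = oracle_sholl(tree, grid)
        m = compute_metrics(profile, grid)
        s = summarize_profile(profile)
        rows.append({"neuron_id": j, "Bmax": m.Bmax, "Bmin": m.Bmin,
                     "Bsmax": m.Bsmax, "Bsmin": m.Bsmin,
                     "enclosing_radius_um": s.enclosing_radius,
                     "max_intersections": s.max_intersections,
                     "radius_of_max_um": s.radius_of_max})
    return pd.DataFrame(rows)


def oracle_image_agreement(n_neurons: int, seed: int,
                           params: GrowthParams | None = None,
                           raster=None) -> dict:
    """Image-pipeline Sholl profiles versus the exact geometric oracle.

    Renders ``n_neurons`` random neurons, runs the full image chain
    (threshold → clean → soma → profile) and compares each count with
    the segment–circle oracle on the generating tree.  Returns the
    fraction of (neuron, radius) pairs in exact agreement and the
    fraction within one intersection.
    """
    from .image_prep import clean_mask, segment_soma, threshold_image
    from .sholl import compute_profile
    from .synthetic import RasterConfig, auto_raster_config, rasterize

    params = params or GrowthParams()
    cfg = auto_raster_config(params, raster or RasterConfig())
    px = cfg.pixel_size
    center_um = ((cfg.width - 1) / 2.0 * px, (cfg.height - 1) / 2.0 * px)
    center_px = (center_um[0] / px, center_um[1] / px)
    room = (min(center_px) - 1) * px

    n_equal = n_within_one = n_pairs = 0
    for j in range(n_neurons):
        sub = int(np.random.SeedSequence([seed, j]).generate_state(1)[0] % (2 ** 31))
        tree = grow_arbor(dataclasses.replace(params, seed=sub),
                          soma_center=center_um)
        image = rasterize(tree, cfg, seed=sub)
        clean = clean_mask(threshold_image(image), center_px, px)
        soma = segment_soma(clean, opening_radius_px=int(np.ceil(1.5 * cfg.line_width)))
        top = min(tree.max_extent() + 10.0, room)
        n_r = max(1, int(np.floor((top - 50.0) / 10.0)) + 1)
        grid = ShollGrid(50.0, 10.0, n_r)
        delta = np.abs(oracle_sholl(tree, grid).counts
                       - compute_profile(clean, soma, grid).counts)
        n_equal += int((delta == 0).sum())
        n_within_one += int((delta <= 1).sum())
        n_pairs += delta.size
    return {"fraction_equal": n_equal / n_pairs,
            "fraction_within_one": n_within_one / n_pairs,
            "n_pairs": n_pairs, "n_neurons": n_neurons}


def kw_power(params_low: GrowthParams, params_high: GrowthParams,
             n_per_group: int, n_replicates: int, seed: int,
             variable: str = "Bmax") -> dict:
    """Rejection rate of Kruskal–Wallis between two growth conditions.

    Returns the fraction of replicates with p < 0.05 and the fraction in
    which the group means are ordered as the branching probabilities are.
    """
    grid = ShollGrid.covering(max(
        params_low.soma_diameter / 2 + params_low.max_steps * params_low.step_len,
        params_high.soma_diameter / 2 + params_high.max_steps * params_high.step_len) + 10)
    rejections = 0
    ordered = 0
    for rep in range(n_replicates):
        a = sample_metrics(params_low, n_per_group, seed=seed * 1_000_003 + 2 * rep,
                           grid=grid)[variable].to_numpy()
        b = sample_metrics(params_high, n_per_group, seed=seed * 1_000_003 + 2 * rep + 1,
                           grid=grid)[variable].to_numpy()
        _h, p = kruskal_wallis([a, b])
        rejections += int(p < ALPHA)
        ordered += int(b.mean() > a.mean())
    return {"power": rejections / n_replicates,
            "ordered_fraction": ordered / n_replicates,
            "n_replicates": n_replicates}


def kw_type1_error(params: GrowthParams, n_pool: int, n_per_group: int,
                   n_groups: int, n_replicates: int, seed: int,
                   variable: str = "Bmax") -> dict:
    """Type-I error of Kruskal–Wallis under identically distributed groups.

    One pool of ``n_pool`` generator-derived endpoint values is drawn
    once; every replicate resamples all groups (with replacement) from
    that single pool, so the groups share one distribution exactly and
    any rejection is a false positive.
    """
    pool = sample_metrics(params, n_pool, seed=seed)[variable].to_numpy()
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        groups = [rng.choice(pool, size=n_per_group, replace=True)
                  for _ in range(n_groups)]
        _h, p = kruskal_wallis(groups)
        rejections += int(p < ALPHA)
    return {"type1_rate": rejections / n_replicates, "n_replicates": n_replicates}


def heterogeneous_cohort(n: int, seed: int) -> pd.DataFrame:
    """Cohort with neuron-to-neuron variation in branch and termination rates.

    Branching probabilities are drawn uniformly from [0.0, 0.08] and
    termination probabilities from [0.0, 0.05] per neuron, mimicking the
    biological spread of arborisation vigour within a culture.
    """
    rng = np.random.default_rng(seed)
    base = GrowthParams()
    grid = _grid_for(base)
    rows = []
    for j in range(n):
        p = dataclasses.replace(
            base,
            branch_prob=float(rng.uniform(0.0, 0.08)),
            term_prob=float(rng.uniform(0.0, 0.05)),
            seed=int(rng.integers(2 ** 31)))
        tree = grow_arbor(p)
        m = compute_metrics(oracle_sholl(tree, grid), grid)
        rows.append({"neuron_id": j, "branch_prob": p.branch_prob,
                     "term_prob": p.term_prob, "Bmax": m.Bmax, "Bmin": m.Bmin})
    return pd.DataFrame(rows)


def bmin_bmax_correlation(n: int, seed: int) -> dict:
    """Pearson correlation between per-neuron Bmin and Bmax in a mixed cohort.

    Vigorous arbors branch strongly (high Bmax) and, all those neurites
    having to terminate eventually, also show the strongest net
    termination (very negative Bmin) — so the correlation is negative.
    """
    cohort = heterogeneous_cohort(n, seed)
    r, p = pearson_corr(cohort["Bmin"], cohort["Bmax"])
    return {"r": r, "p": p, "n": n}


def mean_bmax_by_branch_prob(branch_probs: list[float], n_per_level: int,
                             n_replicates: int, seed: int) -> pd.DataFrame:
    """Replicate-averaged mean Bmax at each branching probability level."""
    base = GrowthParams()
    grid = ShollGrid.covering(
        base.soma_diameter / 2 + base.max_steps * base.step_len + 10)
    rows = []
    for level, bp in enumerate(branch_probs):
        params = dataclasses.replace(base, branch_prob=bp)
        means = []
        for rep in range(n_replicates):
            df = sample_metrics(params, n_per_level,
                                seed=seed * 7919 + 100 * level + rep, grid=grid)
            means.append(df["Bmax"].mean())
        rows.append({"branch_prob": bp, "mean_Bmax": float(np.mean(means)),
                     "sd_over_replicates": float(np.std(means)),
                     "n_replicates": n_replicates})
    return pd.DataFrame(rows)
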