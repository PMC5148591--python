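"""Image-based Sholl profiles and profile summaries."""

import dataclasses

import numpy as np
import pytest

import drgmorph as dm
from drgmorph.errors import GridExceedsFrameError, InvalidParameterError
from drgmorph.image_prep import CleanMask

from conftest import analyze_mask, frame_grid, grow_centered


class TestComputeProfile:
    def test_four_ray_phantom_counts(self, phantom):
        """Rays reaching 120 µm give exactly four intersections on the
        50–120 µm circles and none beyond."""
        profile = dm.compute_profile(phantom["clean"], phantom["soma"],
                                     phantom["grid"])
        assert profile.counts.tolist() == [4] * 8 + [0, 0]

    def test_soma_only_mask_gives_all_zeros(self):
        params = dm.GrowthParams(n_primary=0, soma_diameter=60.0)
        cfg = dm.RasterConfig(noise_sd=0.0, debris_count=0, width=400,
                              height=400, pixel_size=1.0)
        tree, center = grow_centered(params, cfg)
        image = dm.rasterize(tree, cfg, seed=0)
        clean, soma = analyze_mask(image, center, cfg.pixel_size)
        profile = dm.compute_profile(clean, soma, dm.ShollGrid(50, 10, 10))
        assert not profile.counts.any()

    def test_large_soma_excluded_from_counting(self):
        """A 120 µm soma swallows the 50 µm circle; excluding soma pixels
        keeps the inner radii at the true neurite count instead of a
        spurious full-circle hit."""
        params = dm.GrowthParams(n_primary=3, branch_prob=0, term_prob=0,
                                 angle_sd=0, max_steps=10, soma_diameter=120.0,
                                 seed=0)
        cfg = dm.auto_raster_config(params, dm.RasterConfig(noise_sd=0.0,
                                                            debris_count=0))
        tree, center = grow_centered(params, cfg)
        clean, soma = analyze_mask(dm.rasterize(tree, cfg, seed=0), center,
                                   cfg.pixel_size)
        profile = dm.compute_profile(clean, soma, dm.ShollGrid(50, 10, 8))
        # the 50 µm circle lies inside the (excluded) soma: no spurious
        # full-circle count; past the soma the three rays are seen
        assert profile.counts[0] == 0
        assert profile.counts[2:].tolist() == [3] * 6

    def test_rotating_image_by_90_degrees_preserves_profile(self):
        """The concentric grid is isotropic: rotating the mask and centre by
        90° leaves every count unchanged."""
        params = dm.GrowthParams(seed=8, max_steps=12)
        cfg = dm.auto_raster_config(params, dm.RasterConfig())
        tree, center = grow_centered(params, cfg)
        clean, soma = analyze_mask(dm.rasterize(tree, cfg, seed=8), center,
                                   cfg.pixel_size)
        grid = frame_grid(cfg, center, rmax=tree.max_extent() + 10)
        base = dm.compute_profile(clean, soma, grid)

        h = clean.mask.shape[0]
        rot = np.rot90(clean.mask)
        rot_soma = np.rot90(soma.mask)
        # np.rot90 maps (row, col) -> (h-1-col, row): x' = y, y' = h-1-x
        rot_center = (center[1], h - 1 - center[0])
        rot_clean = CleanMask(mask=rot, soma_center=rot_center,
                              pixel_size=clean.pixel_size)
        rot_profile = dm.compute_profile(
            rot_clean, dataclasses.replace(soma, mask=rot_soma), grid)
        assert base.counts.tolist() == rot_profile.counts.tolist()

    def test_disjoint_arbor_union_is_superadditive(self):
        """Adding a second, well-separated arbor to the mask can only add
        intersections at each radius."""
        params = dm.GrowthParams(n_primary=2, branch_prob=0, term_prob=0,
                                 angle_sd=0, max_steps=10, soma_diameter=30.0,
                                 seed=0)
        cfg = dm.RasterConfig(noise_sd=0.0, debris_count=0, width=600,
                              height=600, pixel_size=1.0)
        tree, center = grow_centered(params, cfg)
        clean, soma = analyze_mask(dm.rasterize(tree, cfg, seed=0), center,
                                   cfg.pixel_size)
        grid = dm.ShollGrid(50, 10, 12)
        alone = dm.compute_profile(clean, soma, grid)

        # second arbor: same shape rotated 45°, same soma centre region,
        # so its rays interleave with the first's
        other = dm.grow_arbor(
            dataclasses.replace(params, n_primary=3, seed=1),
            soma_center=tree.soma_center)
        other_mask = dm.rasterize(other, cfg, seed=0) == cfg.foreground_level
        union = CleanMask(mask=clean.mask | other_mask,
                          soma_center=clean.soma_center,
                          pixel_size=clean.pixel_size)
        combined = dm.compute_profile(union, soma, grid)
        assert np.all(combined.counts >= alone.counts)

    def test_grid_leaving_frame_is_an_error(self, phantom):
        huge = dm.ShollGrid(50, 10, 40)
        with pytest.raises(GridExceedsFrameError):
            dm.compute_profile(phantom["clean"], phantom["soma"], huge)


class TestShollGrid:
    def test_radii_are_arithmetic(self):
        grid = dm.ShollGrid(50.0, 10.0, 4)
        assert grid.radii.tolist() == [50.0, 60.0, 70.0, 80.0]

    @pytest.mark.parametrize("bad", [dict(start_radius=0), dict(step=-1),
                                     dict(n_radii=0)])
    def test_invalid_grids_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            dm.ShollGrid(**{"start_radius": 50, "step": 10, "n_radii": 3, **bad})

    def test_covering_reaches_requested_radius(self):
        grid = dm.ShollGrid.covering(123.0)
        assert grid.radii[-1] >= 123.0
        assert grid.radii[-2] < 123.0 if grid.n_radii > 1 else True


class TestSummarizeProfile:
    def test_tie_break_takes_smallest_radius(self):
        p = dm.ShollProfile(radii=[50, 60, 70, 80], counts=[2, 5, 5, 1])
        s = dm.summarize_profile(p)
        assert (s.enclosing_radius, s.max_intersections, s.radius_of_max) == \
            (80.0, 5, 60.0)

    def test_all_zero_profile_has_missing_radii(self):
        s = dm.summarize_profile(dm.ShollProfile(radii=[50, 60], counts=[0, 0]))
        assert s.enclosing_radius is None
        assert s.max_intersections == 0
        assert s.radius_of_max is None

    def test_single_radius_profile(self):
        s = dm.summarize_profile(dm.ShollProfile(radii=[50], counts=[7]))
        assert (s.enclosing_radius, s.max_intersections, s.radius_of_max) == \
            (50.0, 7, 50.0)

    def test_summary_internal_consistency(self, phantom):
        """max_intersections equals the count at radius_of_max, and the
        enclosing radius never exceeds the grid."""
        profile = dm.compute_profile(phantom["clean"], phantom["soma"],
                                     phantom["grid"])
        s = dm.summarize_profile(profile)
        idx = list(profile.radii).index(s.radius_of_max)
        assert profile.counts[idx] == s.max_intersections
        assert s.enclosing_radius <= profile.radii[-1]

    def test_empty_profile_rejected(self):
        with pytest.raises(InvalidParameterError):
            dm.ShollProfile(radii=[], counts=[])
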