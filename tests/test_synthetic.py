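"""Generator, geometric oracle, rasterization and cohort writing."""

import dataclasses

import numpy as np
import pytest

import drgmorph as dm
from drgmorph.errors import FrameTooSmallError, InvalidParameterError

from conftest import PHANTOM_PARAMS, grow_centered


def brute_force_sholl(tree: dm.ArborTree, grid: dm.ShollGrid,
                      n_samples: int = 4000) -> np.ndarray:
    """Independent crossing count: densely sample each segment and count
    sign changes of (distance to soma centre − r)."""
    cx, cy = tree.soma_center
    counts = np.zeros(grid.n_radii, dtype=int)
    ts = np.linspace(0.0, 1.0, n_samples)
    for seg in tree.segments:
        xs = seg.start[0] + ts * (seg.end[0] - seg.start[0])
        ys = seg.start[1] + ts * (seg.end[1] - seg.start[1])
        d = np.hypot(xs - cx, ys - cy)
        for i, r in enumerate(grid.radii):
            sgn = np.sign(d - r)
            sgn = sgn[sgn != 0]
            counts[i] += int(np.count_nonzero(np.diff(sgn) != 0))
    return counts


class TestGrowArbor:
    def test_degenerate_growth_gives_straight_radial_rays(self):
        """No branching, no jitter: n_primary straight rays of max_steps*step_len."""
        p = dataclasses.replace(PHANTOM_PARAMS, max_steps=12)
        tree = dm.grow_arbor(p)
        assert tree.n_segments == 4 * 12
        # each ray is radial: every segment endpoint lies on its primary's axis
        for seg in tree.segments:
            ang = np.arctan2(seg.end[1], seg.end[0]) % (2 * np.pi)
            assert np.isclose(ang % (np.pi / 2), 0.0, atol=1e-9) or \
                np.isclose(ang % (np.pi / 2), np.pi / 2, atol=1e-9)
        assert np.isclose(tree.max_extent(), 10.0 + 120.0)

    def test_no_primaries_gives_soma_only_tree(self):
        tree = dm.grow_arbor(dataclasses.replace(PHANTOM_PARAMS, n_primary=0))
        assert tree.n_segments == 0

    def test_same_seed_reproduces_identical_segments(self):
        p = dm.GrowthParams(seed=42)
        assert dm.grow_arbor(p).segments == dm.grow_arbor(p).segments

    def test_invalid_probability_sum_rejected(self):
        with pytest.raises(InvalidParameterError):
            dm.GrowthParams(branch_prob=0.7, term_prob=0.5)

    def test_soma_diameter_range_enforced_unless_overridden(self):
        with pytest.raises(InvalidParameterError):
            dm.GrowthParams(soma_diameter=10.0)
        dm.GrowthParams(soma_diameter=10.0, allow_soma_override=True)

    def test_branching_doubles_tips(self):
        """branch_prob=1 with no termination: segment count doubles per step."""
        p = dm.GrowthParams(n_primary=1, branch_prob=1.0, term_prob=0.0,
                            angle_sd=0.0, max_steps=4, soma_diameter=30.0, seed=0)
        tree = dm.grow_arbor(p)
        assert tree.n_segments == 2 + 4 + 8 + 16


class TestOracleSholl:
    def test_four_ray_tree_counts_four_until_tip(self):
        """Rays spanning radii 10–130 µm cross circles 50–120; a tip ending
        exactly on the 130 µm circle is a pure tangency and counts zero."""
        tree = dm.grow_arbor(dataclasses.replace(PHANTOM_PARAMS, max_steps=12))
        profile = dm.oracle_sholl(tree, dm.ShollGrid(50, 10, 10))
        assert profile.counts.tolist() == [4] * 8 + [0, 0]

    def test_soma_only_tree_gives_all_zero_profile(self):
        tree = dm.grow_arbor(dataclasses.replace(PHANTOM_PARAMS, n_primary=0))
        profile = dm.oracle_sholl(tree, dm.ShollGrid(50, 10, 5))
        assert not profile.counts.any()

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_sampling_oracle(self, seed):
        """Exact crossing counts equal dense-sampling sign-change counts on
        random trees (50 seeds)."""
        params = dm.GrowthParams(seed=seed, max_steps=15)
        tree = dm.grow_arbor(params)
        grid = dm.ShollGrid.covering(tree.max_extent() + 7.0)
        profile = dm.oracle_sholl(tree, grid)
        assert profile.counts.tolist() == brute_force_sholl(tree, grid).tolist()

    def test_no_branching_profiles_non_increasing_without_jitter(self):
        """Without branching, neurites can only terminate, so straight-growing
        (jitter-free) trees have non-increasing profiles.  (Heading jitter can
        transiently raise a count by crossing a circle twice.)"""
        for seed in range(20):
            p = dm.GrowthParams(branch_prob=0.0, term_prob=0.05, angle_sd=0.0,
                                seed=seed)
            tree = dm.grow_arbor(p)
            grid = dm.ShollGrid.covering(tree.max_extent() + 7.0)
            counts = dm.oracle_sholl(tree, grid).counts
            assert np.all(np.diff(counts) <= 0)


class TestRasterize:
    def test_noiseless_image_is_exactly_two_valued(self):
        cfg = dm.RasterConfig(noise_sd=0.0, debris_count=0, width=301,
                              height=301, pixel_size=1.0)
        tree, _ = grow_centered(PHANTOM_PARAMS, cfg)
        image = dm.rasterize(tree, cfg, seed=0)
        assert set(np.unique(image)) == {cfg.background_level, cfg.foreground_level}

    def test_foreground_pixels_are_within_halfwidth_of_the_tree(self):
        """Noiseless drawing has foreground exactly where a pixel centre lies
        within line_width/2 of a segment or inside the soma disk."""
        cfg = dm.RasterConfig(noise_sd=0.0, debris_count=0, width=301,
                              height=301, pixel_size=1.0)
        tree, _ = grow_centered(PHANTOM_PARAMS, cfg)
        image = dm.rasterize(tree, cfg, seed=0)
        fg = image == cfg.foreground_level
        half_w = cfg.line_width / 2.0
        cx, cy = tree.soma_center
        ys, xs = np.nonzero(fg)
        dist = np.full(ys.size, np.inf)
        for seg in tree.segments:
            ax, ay = seg.start
            vx, vy = seg.end[0] - ax, seg.end[1] - ay
            t = np.clip(((xs - ax) * vx + (ys - ay) * vy) / (vx * vx + vy * vy), 0, 1)
            dist = np.minimum(dist, np.hypot(xs - (ax + t * vx), ys - (ay + t * vy)))
        in_soma = np.hypot(xs - cx, ys - cy) <= tree.soma_radius
        assert np.all((dist <= half_w) | in_soma)

    def test_same_seed_gives_byte_identical_images(self):
        cfg = dm.RasterConfig(width=400, height=400)
        params = dm.GrowthParams(max_steps=8, soma_diameter=30.0, seed=5)
        tree, _ = grow_centered(params, cfg)
        a = dm.rasterize(tree, cfg, seed=9)
        b = dm.rasterize(tree, cfg, seed=9)
        assert np.array_equal(a, b)

    def test_arbor_exceeding_frame_is_an_error(self):
        cfg = dm.RasterConfig(width=80, height=80, pixel_size=1.0)
        tree, _ = grow_centered(PHANTOM_PARAMS, cfg)
        with pytest.raises(FrameTooSmallError):
            dm.rasterize(tree, cfg, seed=0)


class TestSwcRoundTrip:
    def test_tree_survives_swc_write_read(self, tmp_path):
        tree = dm.grow_arbor(dm.GrowthParams(seed=3, max_steps=12))
        path = tmp_path / "neuron.swc"
        dm.write_swc(tree, path)
        back = dm.read_swc(path)
        assert back.soma_radius == pytest.approx(tree.soma_radius, abs=1e-3)
        assert back.n_segments == tree.n_segments
        for a, b in zip(tree.segments, back.segments):
            assert a.parent == b.parent
            assert np.allclose(a.start, b.start, atol=1e-3)
            assert np.allclose(a.end, b.end, atol=1e-3)


class TestMakeCohort:
    def test_writes_one_tiff_swc_manifest_row_per_neuron(self, small_cohort_dir):
        outdir, manifest, _cfg = small_cohort_dir
        assert len(manifest) == 6
        assert sorted(manifest["group"].unique()) == ["ctrl", "gf"]
        for row in manifest.itertuples():
            assert (outdir / row.tiff_path).exists()
            assert (outdir / row.swc_path).exists()

    def test_duplicate_group_labels_rejected(self, tmp_path):
        params = dm.GrowthParams(max_steps=3, soma_diameter=30.0)
        cfg = dm.auto_raster_config(params)
        with pytest.raises(InvalidParameterError):
            dm.make_cohort([("a", params, 1), ("a", params, 1)], cfg, 0, tmp_path)

    def test_same_master_seed_reproduces_manifest_and_files(self, tmp_path):
        params = dm.GrowthParams(max_steps=6, soma_diameter=30.0)
        cfg = dm.auto_raster_config(params)
        m1 = dm.make_cohort([("g", params, 2)], cfg, seed=5, outdir=tmp_path / "a")
        m2 = dm.make_cohort([("g", params, 2)], cfg, seed=5, outdir=tmp_path / "b")
        assert m1.drop(columns=[]).equals(m2)
        for row in m1.itertuples():
            a = (tmp_path / "a" / row.tiff_path).read_bytes()
            b = (tmp_path / "b" / row.tiff_path).read_bytes()
            assert a == b
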