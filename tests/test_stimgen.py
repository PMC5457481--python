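"""Stimulus generators: stereograms, step edges, rendering, patches."""

import numpy as np
import pytest

from binodepth.stimgen import (
    RDSConfig,
    SceneSpec,
    StepEdgeConfig,
    StereoPair,
    extract_patches,
    make_davinci,
    make_rds,
    make_step_edge,
    make_wallpaper,
    polarity_controls,
    render_stereo_from_depth,
    synth_scene,
)


def _windowed_xcorr_peak(pair: StereoPair, max_lag: int = 12) -> int:
    """Lag of the peak cross-correlation between the eyes (whole image)."""
    lags = np.arange(-max_lag, max_lag + 1)
    vals = []
    left = pair.left - pair.left.mean()
    right = pair.right - pair.right.mean()
    for d in lags:
        vals.append(np.sum(left * np.roll(right, -d, axis=1)))
    return int(lags[int(np.argmax(vals))])


class TestRDS:
    def test_zero_disparity_correlated_is_identical(self):
        p = make_rds(RDSConfig(disparity=0, seed=0))
        assert np.array_equal(p.left, p.right)

    def test_anticorrelated_inverts_dots_only(self):
        p = make_rds(RDSConfig(disparity=0, correlated=False, seed=0))
        dots = p.left != 0
        assert np.array_equal(p.left[dots], -p.right[dots])
        assert np.array_equal(p.left[~dots], p.right[~dots])

    def test_dot_density_matches_configuration(self):
        fractions = [
            (make_rds(RDSConfig(size=(100, 100), density=0.5, seed=s)).left != 0).mean()
            for s in range(100)
        ]
        # mean over 100 seeds within 3 binomial standard errors
        se = np.sqrt(0.25 / (100 * 100 * 100))
        assert abs(np.mean(fractions) - 0.5) < 3 * se

    def test_intensity_values_are_ternary(self):
        p = make_rds(RDSConfig(seed=3))
        assert set(np.unique(p.left)) <= {-1.0, 0.0, 1.0}

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            RDSConfig(density=1.5)

    @pytest.mark.parametrize("disparity", [-8, -4, -1, 1, 4, 8])
    def test_xcorr_peaks_at_imposed_disparity(self, disparity):
        p = make_rds(RDSConfig(size=(60, 60), disparity=disparity, seed=1))
        assert _windowed_xcorr_peak(p) == disparity

    def test_anticorrelation_flips_xcorr_sign(self):
        c = make_rds(RDSConfig(size=(80, 80), disparity=4, seed=5))
        a = make_rds(RDSConfig(size=(80, 80), disparity=4, correlated=False, seed=5))

        def xc(pair, d):
            return float(np.sum(pair.left * np.roll(pair.right, -d, axis=1)))

        assert xc(c, 4) > 0 > xc(a, 4)

    def test_deterministic_under_seed(self):
        a = make_rds(RDSConfig(seed=11))
        b = make_rds(RDSConfig(seed=11))
        assert np.array_equal(a.left, b.left) and np.array_equal(a.right, b.right)


class TestStepEdge:
    def test_noise_free_step_gives_two_pixel_difference(self):
        cfg = StepEdgeConfig(noise_sd=0.0, seed=0)
        pair = make_step_edge(cfg)
        d = pair.disparity
        w = d.shape[1]
        left_half = d[:, : w // 2]
        right_half = d[:, w // 2 :]
        mean_diff = right_half[right_half != 0].mean() - left_half[left_half != 0].mean()
        assert mean_diff == pytest.approx(2.0, abs=0.3)

    def test_mixed_polarity_has_both_dot_signs(self):
        pair = make_step_edge(StepEdgeConfig(seed=1))
        n_bright = (pair.left == 1).sum()
        n_dark = (pair.left == -1).sum()
        assert n_bright > 0 and n_dark > 0
        assert 0.5 < n_bright / n_dark < 2.0

    def test_disparity_noise_sd_matches_configuration(self):
        sds = []
        for s in range(40):
            pair = make_step_edge(StepEdgeConfig(seed=s))
            d = pair.disparity[pair.disparity != 0]
            sds.append(d.std())
        assert np.mean(sds) == pytest.approx(8.0, rel=0.1)

    def test_dots_do_not_overlap(self):
        pair = make_step_edge(StepEdgeConfig(seed=2))
        # dot pixels exactly tile: count must be a multiple of dot area
        assert (pair.left != 0).sum() % (8 * 8) == 0

    def test_density_approximate(self):
        pair = make_step_edge(StepEdgeConfig(seed=3))
        assert (pair.left != 0).mean() == pytest.approx(0.15, abs=0.02)


class TestPolarityControls:
    def test_dc_removed_zero_mean(self):
        pair = make_step_edge(StepEdgeConfig(polarity="bright", seed=0))
        out = polarity_controls(pair, "dc-removed")
        assert abs(out.left.mean()) < 1e-12
        assert abs(out.right.mean()) < 1e-12

    def test_range_matched_spans_two(self):
        pair = make_step_edge(StepEdgeConfig(polarity="bright", seed=0))
        out = polarity_controls(pair, "range-matched")
        assert out.left.min() == pytest.approx(-1.0)
        assert out.left.max() == pytest.approx(1.0)

    def test_dc_then_range_match_equalizes_ranges(self):
        mixed = make_step_edge(StepEdgeConfig(polarity="mixed", seed=0))
        bright = make_step_edge(StepEdgeConfig(polarity="bright", seed=0))
        m = polarity_controls(mixed, "range-matched-after-dc")
        b = polarity_controls(bright, "range-matched-after-dc")
        assert np.ptp(m.left) == pytest.approx(np.ptp(b.left))


class TestRenderFromDepth:
    def test_flat_scene_renders_identical_eyes(self):
        rng = np.random.default_rng(0)
        tex = rng.uniform(-1, 1, (40, 60))
        pair = render_stereo_from_depth(tex, np.zeros((40, 60)))
        assert np.array_equal(pair.left, pair.right)

    def test_constant_depth_shifts_uniformly(self):
        rng = np.random.default_rng(1)
        tex = rng.uniform(-1, 1, (40, 80))
        pair = render_stereo_from_depth(tex, np.ones((40, 80)), max_shift=10)
        assert _windowed_xcorr_peak(pair) == 10

    def test_square_region_carries_its_own_shift(self):
        rng = np.random.default_rng(2)
        tex = rng.uniform(-1, 1, (80, 80))
        depth = np.zeros((80, 80))
        depth[20:60, 20:60] = 1.0  # fronto-parallel square at max depth
        pair = render_stereo_from_depth(tex, depth, max_shift=6)
        sq = StereoPair(pair.left[28:52, 28:52], pair.right[28:52, 28:52])
        assert _windowed_xcorr_peak(sq, max_lag=8) == 6

    def test_non_finite_depth_rejected(self):
        with pytest.raises(ValueError):
            render_stereo_from_depth(np.zeros((5, 5)), np.full((5, 5), np.nan))

    def test_interp_mask_marks_disocclusions(self):
        rng = np.random.default_rng(3)
        tex = rng.uniform(-1, 1, (40, 80))
        depth = np.zeros((40, 80))
        depth[:, 40:] = -1.0  # near surface on the right half
        pair = render_stereo_from_depth(tex, depth, max_shift=8)
        assert pair.interp_mask is not None and pair.interp_mask.any()


class TestSyntheticScenes:
    def test_deterministic_under_seed(self):
        t1, d1 = synth_scene(SceneSpec(seed=9))
        t2, d2 = synth_scene(SceneSpec(seed=9))
        assert np.array_equal(t1, t2) and np.array_equal(d1, d2)

    def test_spectral_slope(self):
        t, _ = synth_scene(SceneSpec(size=(256, 256), spectral_slope=-1.0, seed=0))
        spec = np.abs(np.fft.fft2(t))
        fy = np.fft.fftfreq(256)[:, None]
        fx = np.fft.fftfreq(256)[None, :]
        f = np.hypot(fy, fx).ravel()
        s = spec.ravel()
        sel = (f > 0.01) & (f < 0.4)
        slope = np.polyfit(np.log(f[sel]), np.log(s[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_two_surface_scene_is_bimodal(self):
        spec = SceneSpec(n_surfaces=2, depth_levels=(-0.6, 0.6), seed=4)
        _, depth = synth_scene(spec)
        vals = np.unique(depth)
        assert set(vals) <= {-0.6, 0.6}
        assert len(vals) >= 1  # two seeds may draw the same level


class TestPatchPipeline:
    def _render_pairs(self, n, seed):
        rng = np.random.default_rng(seed)
        pairs = []
        for _ in range(n):
            tex, depth = synth_scene(SceneSpec(), rng=rng)
            pairs.append(render_stereo_from_depth(tex, depth))
        return pairs

    def test_constant_patch_excluded_and_sets_disjoint(self):
        pairs = self._render_pairs(30, 0)
        # flatten one pair to constant: all its patches must be excluded
        pairs[0].left[:] = 0.5
        pairs[0].right[:] = 0.5
        tr, va, te = extract_patches(pairs, seed=0)
        assert len(tr) > len(va) > 0 and len(te) > 0
        for ps in (tr, va, te):
            assert ps.left.min() >= -1 and ps.left.max() <= 1
            assert ps.left.std(axis=(1, 2)).min() >= 20 / 127.5

    def test_split_proportions(self):
        pairs = self._render_pairs(40, 1)
        tr, va, te = extract_patches(pairs, split=(70, 15, 15), seed=1)
        n = len(tr) + len(va) + len(te)
        assert len(tr) == int(round(n * 0.70))
        assert len(va) == int(round(n * 0.15))

    def test_over_interpolated_patches_excluded(self):
        pairs = self._render_pairs(20, 2)
        # force heavy interpolation flags on one pair
        pairs[0].interp_mask[:] = True
        tr0, va0, te0 = extract_patches(pairs, seed=3)
        n_with = len(tr0) + len(va0) + len(te0)
        tr1, va1, te1 = extract_patches(pairs[1:], seed=3)
        n_without = len(tr1) + len(va1) + len(te1)
        assert n_with == n_without

    def test_too_few_patches_raises(self):
        pairs = self._render_pairs(1, 3)
        pairs[0].left[:] = 0.0
        with pytest.raises(RuntimeError):
            extract_patches(pairs, seed=0)


class TestWallpaperAndDaVinci:
    def test_wallpaper_periodicity(self):
        pair = make_wallpaper(period=8)
        y0, x0, hh, ww = pair.meta["center"]
        center = pair.left[y0 : y0 + hh, x0 : x0 + ww]
        assert np.array_equal(center[:, 8:], center[:, :-8])
        assert np.array_equal(pair.left, pair.right)

    def test_bias_variants_differ_only_in_background(self):
        a = make_wallpaper(bg_luminance=-0.5)
        b = make_wallpaper(bg_luminance=0.5)
        y0, x0, hh, ww = a.meta["center"]
        center = (slice(y0, y0 + hh), slice(x0, x0 + ww))
        assert np.array_equal(a.left[center], b.left[center])
        outside = np.ones_like(a.left, dtype=bool)
        outside[center] = False
        assert np.all(a.left[outside] == -0.5) and np.all(b.left[outside] == 0.5)

    def test_wallpaper_minimum_period(self):
        with pytest.raises(ValueError):
            make_wallpaper(period=1)

    def test_davinci_target_binocular_flanks_monocular(self):
        pair = make_davinci(seed=0)
        y0, x0, hh, ww = pair.meta["target"]
        target = (slice(y0, y0 + hh), slice(x0, x0 + ww))
        assert np.array_equal(pair.left[target], pair.right[target])
        occl = pair.occlusion_mask
        assert occl.any()
        # the eyes differ only at masked (monocular) pixels
        differs = pair.left != pair.right
        assert not (differs & ~occl).any()
        # each flank is visible in exactly one eye
        left_flank = occl & (pair.left != 0)
        right_flank = occl & (pair.right != 0)
        assert left_flank.any() and right_flank.any()
        assert not (left_flank & right_flank).any()
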