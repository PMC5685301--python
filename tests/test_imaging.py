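"""Unit and property tests for the confocal quantification operations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import zfquant as zq
from zfquant.imaging import DegenerateInputError, UndefinedCoefficientError


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_kapur(hist):
    """Exhaustive 256-candidate evaluation of the entropy sum."""
    p = np.asarray(hist, float) / np.sum(hist)
    best_t, best_h = -1, -math.inf
    for t in range(256):
        bg, fg = p[: t + 1], p[t + 1 :]
        pb, pf = bg.sum(), fg.sum()
        if pb <= 0 or pf <= 0:
            continue
        hb = -sum(q / pb * math.log(q / pb) for q in bg if q > 0)
        hf = -sum(q / pf * math.log(q / pf) for q in fg if q > 0)
        if hb + hf > best_h + 1e-12:
            best_t, best_h = t, hb + hf
    return best_t


def flood_fill_particles(mask):
    """BFS 8-connected component count and per-component areas."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    areas = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        stack, area = [start], 0
        seen[start] = True
        while stack:
            r, c = stack.pop()
            area += 1
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                            and mask[rr, cc] and not seen[rr, cc]):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
        areas.append(area)
    return len(areas), sorted(areas)


# ---------------------------------------------------------------------------
# projection


class TestMaxZProjection:
    def test_single_slice_identity(self, rng):
        vox = rng.integers(0, 256, (4, 8, 8)).astype(np.uint8)
        stack = zq.ImageStack(vox)
        proj = zq.max_z_projection(stack, (2, 3))
        assert np.array_equal(proj.pixels, vox[2])

    def test_pixelwise_max_of_two(self):
        vox = np.array([[[3]], [[7]]], dtype=np.uint8)
        proj = zq.max_z_projection(zq.ImageStack(vox), (0, 2))
        assert proj.pixels[0, 0] == 7

    def test_matches_brute_force_loop(self, rng):
        vox = rng.integers(0, 256, (5, 6, 7)).astype(np.uint8)
        proj = zq.max_z_projection(zq.ImageStack(vox), (0, 5))
        for r in range(6):
            for c in range(7):
                assert proj.pixels[r, c] == max(vox[s, r, c] for s in range(5))

    def test_dominates_every_slice_and_preserves_calibration(self, rng):
        vox = rng.integers(0, 256, (6, 5, 5)).astype(np.uint8)
        stack = zq.ImageStack(vox, pixel_size_xy=0.3, z_step=1.0)
        proj = zq.max_z_projection(stack, (1, 5))
        for s in range(1, 5):
            assert (proj.pixels >= vox[s]).all()
        assert proj.pixel_size_xy == 0.3

    @pytest.mark.parametrize("bad_range", [(3, 3), (-1, 2), (0, 99), (4, 2)])
    def test_bad_slice_range(self, rng, bad_range):
        stack = zq.ImageStack(rng.integers(0, 256, (4, 4, 4)).astype(np.uint8))
        with pytest.raises(IndexError):
            zq.max_z_projection(stack, bad_range)


# ---------------------------------------------------------------------------
# thresholding


class TestKapurThreshold:
    def test_two_spike_histogram_tie_breaks_low(self):
        hist = np.zeros(256, int)
        hist[10], hist[200] = 50, 70
        # any t in [10, 199] attains the maximum; smallest wins
        assert zq.kapur_max_entropy_threshold(hist) == 10

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(hst.lists(hst.integers(0, 1000), min_size=256, max_size=256))
    def test_matches_exhaustive_oracle(self, hist):
        if np.count_nonzero(hist) < 2:
            return
        assert zq.kapur_max_entropy_threshold(hist) == brute_force_kapur(hist)

    def test_uniform_image_is_degenerate(self):
        hist = np.zeros(256, int)
        hist[42] = 1000
        with pytest.raises(DegenerateInputError):
            zq.kapur_max_entropy_threshold(hist)

    def test_16bit_threshold_mapped_to_native_scale(self, rng):
        pixels = rng.integers(0, 2**16, (32, 32)).astype(np.uint16)
        proj = zq.Projection(pixels, bit_depth=16)
        t = zq.threshold_projection(proj)
        assert 0 <= t <= 2**16 - 1
        assert t > 255  # back on the native scale for a full-range image


class TestApplyThresholdMask:
    def test_worked_example(self):
        proj = zq.Projection(np.array([[5, 10], [20, 0]], dtype=np.uint8))
        mask, masked = zq.apply_threshold_mask(proj, 9)
        assert np.array_equal(mask.pixels, [[False, True], [True, False]])
        assert np.array_equal(masked.pixels, [[0, 10], [20, 0]])

    def test_threshold_at_max_gives_empty_mask(self, rng):
        pixels = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        mask, _ = zq.apply_threshold_mask(zq.Projection(pixels), int(pixels.max()))
        assert not mask.pixels.any()

    def test_minimum_threshold_keeps_all_positive(self, rng):
        pixels = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        mask, _ = zq.apply_threshold_mask(zq.Projection(pixels), 0)
        assert np.array_equal(mask.pixels, pixels > 0)
        with pytest.raises(ValueError):
            zq.apply_threshold_mask(zq.Projection(pixels), -1)


# ---------------------------------------------------------------------------
# ROI cropping


class TestCropROI:
    def test_retain_whole_image_is_identity(self, rng):
        proj = zq.Projection(rng.integers(0, 256, (10, 10)).astype(np.uint8))
        out = zq.crop_roi(proj, zq.RectROI(0, 10, 0, 10, mode="retain"))
        assert out.domain.all()
        assert np.array_equal(out.pixels, proj.pixels)

    def test_excluding_half_of_uniform_image_keeps_percentages(self):
        pixels = np.full((10, 10), 7, dtype=np.uint8)
        proj = zq.Projection(pixels)
        mask_full, _ = zq.apply_threshold_mask(proj, 3)
        pct_full = zq.analyze_particles(mask_full).percent_positive_pixels
        cropped = zq.crop_roi(proj, zq.RectROI(0, 5, 0, 10, mode="exclude"))
        mask_half = zq.BinaryMask(pixels > 3, 3, domain=cropped.domain)
        pct_half = zq.analyze_particles(mask_half).percent_positive_pixels
        assert pct_full == pct_half == 100.0

    def test_excluding_all_signal_zeroes_percent(self):
        pixels = np.zeros((10, 10), dtype=np.uint8)
        pixels[0:2, :] = 200  # all signal in one stripe
        proj = zq.Projection(pixels)
        cropped = zq.crop_roi(proj, zq.RectROI(0, 2, 0, 10, mode="exclude"))
        mask = zq.BinaryMask(pixels > 50, 50, domain=cropped.domain)
        assert zq.analyze_particles(mask).percent_positive_pixels == 0.0

    def test_empty_domain_is_degenerate(self):
        proj = zq.Projection(np.ones((4, 4), dtype=np.uint8))
        with pytest.raises(DegenerateInputError):
            zq.crop_roi(proj, zq.RectROI(0, 4, 0, 4, mode="exclude"))


# ---------------------------------------------------------------------------
# colocalization


def _proj(arr):
    return zq.Projection(np.asarray(arr, dtype=np.uint8))


class TestManders:
    def test_four_pixel_worked_example(self):
        m1, m2 = zq.manders_coefficients(_proj([[10, 0, 10, 0]]), _proj([[5, 5, 0, 0]]))
        assert m1 == pytest.approx(0.5)
        assert m2 == pytest.approx(0.5)

    def test_identical_channels_fully_colocalized(self, rng):
        img = rng.integers(1, 256, (6, 6)).astype(np.uint8)
        m1, m2 = zq.manders_coefficients(_proj(img), _proj(img))
        assert m1 == m2 == 1.0

    def test_disjoint_supports(self):
        red = np.array([[10, 20, 0, 0]])
        green = np.array([[0, 0, 5, 9]])
        assert zq.manders_coefficients(_proj(red), _proj(green)) == (0.0, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.integers(0, 2**32 - 1))
    def test_swap_symmetry_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        red = rng.integers(0, 40, (8, 8)).astype(np.uint8)
        green = rng.integers(0, 40, (8, 8)).astype(np.uint8)
        if red.sum() == 0 or green.sum() == 0:
            return
        m1, m2 = zq.manders_coefficients(_proj(red), _proj(green))
        m1s, m2s = zq.manders_coefficients(_proj(green), _proj(red))
        assert m1 == pytest.approx(m2s) and m2 == pytest.approx(m1s)
        m1x, m2x = zq.manders_coefficients(_proj(red * 3), _proj(green * 3))
        assert m1x == pytest.approx(m1) and m2x == pytest.approx(m2)

    def test_empty_channel_raises_not_zero(self):
        with pytest.raises(UndefinedCoefficientError):
            zq.manders_coefficients(_proj([[0, 0]]), _proj([[1, 2]]))
        with pytest.raises(UndefinedCoefficientError):
            zq.manders_coefficients(_proj([[1, 2]]), _proj([[0, 0]]))


class TestPearson:
    def test_perfect_linear_relation(self):
        red = np.arange(1, 17, dtype=np.uint8).reshape(4, 4)
        assert zq.pearson_coefficient(_proj(red), _proj(red * 2)) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        red = np.arange(16, dtype=np.uint8).reshape(4, 4)
        assert zq.pearson_coefficient(_proj(red), _proj(15 - red)) == pytest.approx(-1.0)

    def test_matches_two_pass_formula(self, rng):
        red = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        green = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        expected = np.corrcoef(red.ravel().astype(float), green.ravel().astype(float))[0, 1]
        assert zq.pearson_coefficient(_proj(red), _proj(green)) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedCoefficientError):
            zq.pearson_coefficient(_proj([[3, 3], [3, 3]]), _proj([[1, 2], [3, 4]]))


# ---------------------------------------------------------------------------
# particles


class TestAnalyzeParticles:
    def test_three_squares(self):
        mask = np.zeros((10, 10), dtype=bool)
        for r, c in [(0, 0), (4, 4), (8, 8)]:
            mask[r:r + 2, c:c + 2] = True
        ps = zq.analyze_particles(zq.BinaryMask(mask, 0))
        assert ps.n_particles == 3
        assert ps.percent_positive_pixels == pytest.approx(12.0)
        assert ps.total_area_pixels == 12

    def test_area_calibration(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:3, 1:3] = True
        ps = zq.analyze_particles(zq.BinaryMask(mask, 0), pixel_size_xy=0.5)
        assert ps.particles[0].area_um2 == pytest.approx(4 * 0.25)

    def test_insensitive_to_intensity_rescaling(self, rng):
        img = rng.integers(0, 128, (16, 16)).astype(np.uint8)
        m1, _ = zq.apply_threshold_mask(zq.Projection(img), 60)
        # doubling intensities with the correspondingly scaled threshold
        m2, _ = zq.apply_threshold_mask(zq.Projection((img.astype(int) * 2).clip(0, 255).astype(np.uint8)), 121)
        p1 = zq.analyze_particles(m1)
        p2 = zq.analyze_particles(m2)
        assert p1.n_particles == p2.n_particles
        assert p1.percent_positive_pixels == p2.percent_positive_pixels

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = ndi_blobs(rng)
        ps = zq.analyze_particles(zq.BinaryMask(mask, 0))
        n, areas = flood_fill_particles(mask)
        assert ps.n_particles == n
        assert sorted(p.area_pixels for p in ps.particles) == areas
        assert ps.percent_positive_pixels == pytest.approx(100.0 * mask.sum() / mask.size)

    def test_min_area_filter(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, 0] = True  # singleton
        mask[3:6, 3:6] = True  # 9-pixel block
        ps = zq.analyze_particles(zq.BinaryMask(mask, 0), min_area_pixels=2)
        assert ps.n_particles == 1
        assert ps.particles[0].area_pixels == 9


def ndi_blobs(rng, shape=(24, 24), p=0.35):
    return rng.random(shape) < p


# ---------------------------------------------------------------------------
# axon length


class TestAxonLength:
    def test_two_vertices(self):
        assert zq.measure_axon_length([(0, 0), (0, 10)], 0.5) == pytest.approx(5.0)

    def test_closed_square(self):
        path = [(0, 0), (0, 3), (3, 3), (3, 0), (0, 0)]
        assert zq.measure_axon_length(path, 1.0) == pytest.approx(12.0)

    def test_matches_segment_sum_oracle(self, rng):
        pts = rng.random((10, 2)) * 100
        expected = sum(
            math.dist(pts[i], pts[i + 1]) for i in range(9)
        ) * 0.25
        assert zq.measure_axon_length(pts, 0.25) == pytest.approx(expected)

    def test_single_vertex_rejected(self):
        with pytest.raises(ValueError):
            zq.measure_axon_length([(0, 0)], 1.0)


# ---------------------------------------------------------------------------
# full pipeline


class TestQuantifyNMJ:
    def test_fully_colocalized_synthetic_stack(self):
        params = zq.SyntheticNMJParams(
            coloc_fraction=1.0, poisson_noise=False, read_noise_sd=0.0,
            background=0.0, seed=11)
        pair, _ = zq.generate_nmj_stack(params)
        m = zq.quantify_nmj(pair)
        assert m.M1 >= 0.99
        assert m.pearson > 0.5

    def test_disjoint_synthetic_stack(self):
        params = zq.SyntheticNMJParams(
            coloc_fraction=0.0, poisson_noise=False, read_noise_sd=0.0,
            background=0.0, seed=12)
        pair, _ = zq.generate_nmj_stack(params)
        m = zq.quantify_nmj(pair)
        assert m.M1 == 0.0 and m.M2 == 0.0

    def test_deterministic_for_fixed_input(self):
        pair, _ = zq.generate_nmj_stack(zq.SyntheticNMJParams(seed=13))
        a = zq.quantify_nmj(pair, larva_id="x")
        b = zq.quantify_nmj(pair, larva_id="x")
        assert a == b

    def test_roi_exclusion_changes_denominator(self):
        pair, _ = zq.generate_nmj_stack(zq.SyntheticNMJParams(seed=14))
        full = zq.quantify_nmj(pair)
        roi = zq.RectROI(0, 20, 0, 96, mode="exclude")
        cropped = zq.quantify_nmj(pair, roi=roi)
        assert cropped.pct_red != full.pct_red or cropped.pct_green != full.pct_green

    def test_error_carries_stage_context(self):
        pair, _ = zq.generate_nmj_stack(zq.SyntheticNMJParams(seed=15))
        with pytest.raises(IndexError, match=r"\[projection\]"):
            zq.quantify_nmj(pair, slice_range=(0, 99))
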