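import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cropdepth import synthetic, thresholding as th
from cropdepth.errors import (
    DegenerateHistogramError,
    NoEdgesError,
    NoGradientError,
    ParameterError,
)
from conftest import random_histogram


# ---------------------------------------------------------------------------
# Independent oracles, coded straight from the definitions
# ---------------------------------------------------------------------------

def otsu_brute(counts):
    """Exhaustive between-class-variance scan over all 256 splits."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    x = np.arange(256)
    best_v, best_t = -np.inf, None
    for t in range(256):
        w0 = counts[: t + 1].sum()
        w1 = counts[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        u0 = (x[: t + 1] * counts[: t + 1]).sum() / w0
        u1 = (x[t + 1 :] * counts[t + 1 :]).sum() / w1
        v = (w0 / total) * (w1 / total) * (u0 - u1) ** 2
        if v > best_v * (1 + 1e-12) + 1e-12:
            best_v, best_t = v, t
    return best_t


def ght_brute(counts, nu, tau, kappa, omega):
    """Per-split GHT objective computed term by term with explicit loops."""
    counts = np.asarray(counts, dtype=float)
    x = np.arange(256, dtype=float)
    eps = 1e-30
    obj = np.empty(255)
    for t in range(255):
        n0, x0 = counts[: t + 1], x[: t + 1]
        n1, x1 = counts[t + 1 :], x[t + 1 :]
        w0 = max(n0.sum(), eps)
        w1 = max(n1.sum(), eps)
        p0, p1 = w0 / (w0 + w1), w1 / (w0 + w1)
        mu0 = (n0 * x0).sum() / w0
        mu1 = (n1 * x1).sum() / w1
        d0 = (n0 * (x0 - mu0) ** 2).sum()
        d1 = (n1 * (x1 - mu1) ** 2).sum()
        v0 = max((nu * p0 * tau**2 + d0) / (nu * p0 + w0), eps)
        v1 = max((nu * p1 * tau**2 + d1) / (nu * p1 + w1), eps)
        f0 = -d0 / v0 - w0 * np.log(v0) + 2 * (w0 + kappa * omega) * np.log(w0)
        f1 = -d1 / v1 - w1 * np.log(v1) + 2 * (w1 + kappa * (1 - omega)) * np.log(w1)
        obj[t] = f0 + f1
    return obj


# ---------------------------------------------------------------------------
# Histogram
# ---------------------------------------------------------------------------

class TestHistogram:
    def test_direct_count(self):
        h = th.histogram(np.array([[0.0, 0.0, 1.0], [255.0, 255.0, 1.0], [3.0] * 3]))
        assert h[0] == 2 and h[255] == 2 and h[1] == 2 and h[3] == 3
        assert h.sum() == 9

    def test_rounding_half_away_from_zero(self):
        h = th.histogram(np.full((3, 3), 10.4))
        assert h[10] == 9
        h = th.histogram(np.full((3, 3), 10.6))
        assert h[11] == 9
        h = th.histogram(np.full((3, 3), 10.5))
        assert h[11] == 9


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------

class TestOtsu:
    def test_two_point_histogram_smallest_tie(self):
        h = np.zeros(256)
        h[10], h[200] = 60, 40
        # every split in [10, 199] yields the same partition; smallest wins
        assert th.otsu_threshold(h) == 10

    def test_degenerate_histogram_raises(self):
        with pytest.raises(DegenerateHistogramError):
            th.otsu_threshold(th.histogram(np.full((5, 5), 42.0)))

    def test_matches_bruteforce_on_200_random_histograms(self, rng):
        for _ in range(200):
            h = random_histogram(rng)
            assert th.otsu_threshold(h) == otsu_brute(h)


# ---------------------------------------------------------------------------
# GHT
# ---------------------------------------------------------------------------

class TestGHT:
    def test_bimodal_threshold_lies_between_modes(self, rng):
        h = np.zeros(256)
        x = np.arange(256)
        h += 500 * np.exp(-0.5 * ((x - 40) / 5.0) ** 2)
        h += 500 * np.exp(-0.5 * ((x - 210) / 5.0) ** 2)
        t = th.ght_threshold(h)
        assert 40 < t < 210

    def test_objective_matches_bruteforce(self, rng):
        params = th.GHTParams(nu=10.0, tau=5.0, kappa=2.0, omega=0.3)
        for _ in range(25):
            h = random_histogram(rng, bimodal=True)
            mine = th.ght_objective(h, params)
            ref = ght_brute(h, 10.0, 5.0, 2.0, 0.3)
            np.testing.assert_allclose(mine, ref, rtol=1e-8)
            assert th.ght_threshold(h, params) == int(np.argmax(ref))

    def test_mirror_symmetry_of_objective(self, rng):
        params = th.GHTParams(nu=4.0, tau=8.0, kappa=0.0, omega=0.5)
        for _ in range(10):
            h = random_histogram(rng, bimodal=True)
            obj = th.ght_objective(h, params)
            obj_m = th.ght_objective(h[::-1].copy(), params)
            np.testing.assert_allclose(obj[::-1], obj_m, rtol=1e-7)

    def test_otsu_limit_recovers_otsu_on_50_histograms(self, rng):
        params = th.GHTParams.otsu_limit()
        for _ in range(50):
            h = random_histogram(rng, bimodal=True)
            assert th.ght_threshold(h, params) == th.otsu_threshold(h)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            th.GHTParams(nu=-1).validate()
        with pytest.raises(ParameterError):
            th.GHTParams(omega=1.5).validate()


# ---------------------------------------------------------------------------
# apply_threshold / normalize_depth
# ---------------------------------------------------------------------------

class TestApplyThreshold:
    def test_strictly_greater_semantics(self):
        np.testing.assert_array_equal(
            th.apply_threshold(np.array([[10.0, 200.0, 10.0]] * 3), 10),
            np.array([[0, 1, 0]] * 3),
        )

    def test_extreme_thresholds(self):
        d = np.full((3, 3), 100.0)
        assert th.apply_threshold(d, 255).sum() == 0
        assert th.apply_threshold(d, 0).sum() == 9


class TestNormalizeDepth:
    def test_constant_map_to_zero(self):
        assert th.normalize_depth(np.full((4, 4), 9.0)).max() == 0.0

    def test_separable_worked_example_vanishes(self):
        # f(i) + g(j) grid: rows -> [[0,1,2]]*3, then column minima remove all
        d = np.array([[1, 2, 3], [3, 4, 5], [5, 6, 7]], dtype=float)
        np.testing.assert_array_equal(th.normalize_depth(d), np.zeros((3, 3)))

    def test_non_separable_bump_survives(self):
        d = np.zeros((3, 3))
        d[1, 1] = 5.0
        np.testing.assert_array_equal(th.normalize_depth(d), d)

    @given(
        a=st.floats(0, 0.5), b=st.floats(0, 0.5), c=st.floats(0, 100),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_separable_ramp_removed_exactly(self, a, b, c):
        ii, jj = np.mgrid[0:20, 0:20]
        d = np.clip(c + a * ii + b * jj, 0, 255)
        np.testing.assert_allclose(th.normalize_depth(d), 0.0, atol=1e-9)

    def test_idempotent(self, unbiased_scene):
        once = th.normalize_depth(unbiased_scene.depth)
        np.testing.assert_allclose(th.normalize_depth(once), once, atol=1e-9)


# ---------------------------------------------------------------------------
# Gradient / edges / target mask
# ---------------------------------------------------------------------------

class TestGradientStages:
    def test_constant_map_zero_gradient(self):
        assert th.compute_gradient(np.full((6, 6), 5.0)).max() == 0.0

    def test_step_column_magnitude_is_4h(self):
        h = 30.0
        d = np.zeros((9, 9))
        d[:, 5:] = h
        g = th.compute_gradient(d, 3)
        # interior rows, columns adjacent to the step: |Sx| = 4h
        assert g[4, 4] == pytest.approx(4 * h)
        assert g[4, 0] == 0.0

    def test_even_kernel_rejected(self):
        with pytest.raises(ParameterError):
            th.compute_gradient(np.zeros((5, 5)), 4)

    def test_canny_constant_map_no_edges(self):
        assert th.compute_edges(np.full((8, 8), 7.0)).sum() == 0

    def test_canny_strong_step_fires_thin_line(self):
        d = np.zeros((24, 24))
        d[:, 12:] = 120.0
        e = th.compute_edges(d)
        cols = np.unique(np.nonzero(e)[1])
        assert e.sum() > 0
        assert cols.size <= 2 and np.all(np.abs(cols - 11.5) <= 1.5)

    def test_canny_subthreshold_step_silent(self):
        d = np.zeros((24, 24))
        d[:, 12:] = 2.0  # gradient 8 on the 4h scale, below low=50
        assert th.compute_edges(d).sum() == 0

    def test_canny_invalid_thresholds(self):
        with pytest.raises(ParameterError):
            th.compute_edges(np.zeros((5, 5)), low=100, high=50)

    def test_target_mask_empty_edges(self):
        assert th.build_target_mask(np.zeros((10, 10), dtype=int)).sum() == 0

    def test_target_mask_fills_closed_ring(self):
        e = np.zeros((40, 40), dtype=int)
        e[10, 10:30] = e[29, 10:30] = 1
        e[10:30, 10] = e[10:30, 29] = 1
        m = th.build_target_mask(e, dilation=3)
        assert m[20, 20] == 1  # interior filled
        dilated_superset = m.astype(bool)
        assert dilated_superset[10, 10] and dilated_superset[29, 29]

    def test_dilation_bridges_subwindow_gaps(self):
        e = np.zeros((60, 80), dtype=int)
        e[20, 10:70] = 1
        e[40, 10:70] = 1  # two parallel segments 20 px apart
        m = th.build_target_mask(e, dilation=30)
        from scipy import ndimage

        _, n_components = ndimage.label(m)
        assert n_components == 1
        assert np.all(m[20:41, 30] == 1)


class TestGradientLevels:
    def test_extremes_and_midpoint(self):
        g = np.array([[0.0, 10.0], [5.0, 10.0]])
        lv = th.gradient_levels(g, p=3)
        assert lv[0, 0] == 0 and lv[0, 1] == 2 and lv[1, 0] == 1

    def test_uniform_positive_gradient_is_top_level(self):
        lv = th.gradient_levels(np.full((4, 4), 3.3), p=3)
        assert np.all(lv == 2)

    def test_zero_gradient_raises(self):
        with pytest.raises(NoGradientError):
            th.gradient_levels(np.zeros((4, 4)), p=3)


class TestLevelWeights:
    def test_degenerate_single_level(self):
        lv = np.full((4, 4), 2)
        e = np.zeros((4, 4), dtype=int)
        e[1, 1] = e[2, 2] = 1
        np.testing.assert_allclose(th.level_weights(lv, e, p=3), [0, 0, 1])

    def test_three_to_one_split(self):
        lv = np.array([[2, 2, 2, 1]])
        e = np.ones((1, 4), dtype=int)
        np.testing.assert_allclose(th.level_weights(lv, e, p=3), [0, 0.25, 0.75])

    def test_no_edges_raises(self):
        with pytest.raises(NoEdgesError):
            th.level_weights(np.zeros((3, 3), dtype=int), np.zeros((3, 3)), p=3)


class TestWeightedHistogram:
    def test_single_spike(self):
        d = np.full((4, 4), 50.0)
        e = np.zeros((4, 4), dtype=int)
        e[2, 2] = 1
        lv = np.full((4, 4), 1)
        r, s = th.weighted_histogram(d, lv, e, np.array([0.0, 1.0]))
        assert r[50] == 1.0 and r.sum() == 1.0
        assert np.all(s[:50] == 0.0) and np.all(s[50:] == 255.0)

    def test_two_equal_plateaus(self):
        d = np.full((4, 4), 50.0)
        d[0, 0] = 150.0
        e = np.zeros((4, 4), dtype=int)
        e[0, 0] = e[2, 2] = 1
        lv = np.zeros((4, 4), dtype=int)
        r, s = th.weighted_histogram(d, lv, e, np.array([1.0]))
        np.testing.assert_allclose(s[:50], 0.0)
        np.testing.assert_allclose(s[50:150], 127.5)
        np.testing.assert_allclose(s[150:], 255.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_s_monotone_ending_at_255(self, seed):
        scene = synthetic.generate_scene(synthetic.SceneSpec(seed=seed % 1000))
        dn = th.normalize_depth(scene.depth)
        e = th.compute_edges(dn)
        if e.sum() == 0:
            return
        g = th.compute_gradient(dn)
        lv = th.gradient_levels(g, 3)
        gamma = th.level_weights(lv, e, 3)
        assert gamma.sum() == pytest.approx(1.0)
        _, s = th.weighted_histogram(dn, lv, e, gamma)
        assert np.all(np.diff(s) >= -1e-12)
        assert s[-1] == pytest.approx(255.0)


# ---------------------------------------------------------------------------
# Sigmoid fit
# ---------------------------------------------------------------------------

class TestSigmoidFit:
    @staticmethod
    def _sigmoid(t, a, b):
        return 255.0 / (1.0 + np.exp(-a * (t - b)))

    def test_self_fit_recovers_parameters(self):
        t = np.arange(256)
        fit = th.fit_sigmoid(self._sigmoid(t, 0.1, 100.0))
        assert fit.a == pytest.approx(0.1, abs=1e-3)
        assert abs(fit.b - 100.0) <= 0.5

    @pytest.mark.parametrize("a", [0.05, 0.5, 2.0])
    @pytest.mark.parametrize("b", [40.0, 128.0, 200.0])
    def test_noiseless_recovery_grid(self, a, b):
        fit = th.fit_sigmoid(self._sigmoid(np.arange(256), a, b))
        assert abs(fit.b - b) <= 1.0

    @pytest.mark.parametrize("a", [0.05, 0.5, 2.0])
    @pytest.mark.parametrize("b", [40.0, 128.0, 200.0])
    def test_noisy_recovery_grid(self, a, b, rng):
        s = self._sigmoid(np.arange(256), a, b) + rng.uniform(-5, 5, size=256)
        fit = th.fit_sigmoid(s)
        assert abs(fit.b - b) <= 3.0

    def test_threshold_from_fit_midpoint_and_clamp(self):
        assert th.threshold_from_fit(th.SigmoidFit(a=1.0, b=100.0)) == 100
        assert th.threshold_from_fit(th.SigmoidFit(a=1.0, b=255.4)) == 255
        assert th.threshold_from_fit(th.SigmoidFit(a=1.0, b=0.0)) == 0


# ---------------------------------------------------------------------------
# Full pseudo-mask pipeline
# ---------------------------------------------------------------------------

class TestGeneratePseudoMask:
    def test_ggt_on_clean_scene_recovers_crops(self):
        from cropdepth.metrics import iou

        spec = synthetic.SceneSpec(noise_sigma=0.0, seed=21)
        scene = synthetic.generate_scene(spec)
        mask, diag = th.generate_pseudo_mask(scene.depth, "ggt")
        assert diag.fallback is None
        assert iou(mask, scene.mask) >= 0.9

    def test_constant_map_raises_degenerate_error(self):
        with pytest.raises(DegenerateHistogramError):
            th.generate_pseudo_mask(np.full((32, 32), 80.0), "ggt")

    def test_no_edges_falls_back_to_otsu(self):
        # bimodal but ultra-smooth: no Canny response after normalization
        ii = np.mgrid[0:64, 0:64][0]
        d = 40.0 + 80.0 / (1.0 + np.exp(-(ii - 32) / 12.0))
        mask, diag = th.generate_pseudo_mask(d, "ggt", th.GGTConfig(apply_normalization=False))
        assert diag.fallback == "NoEdgesError"
        t = th.otsu_threshold(th.histogram(d))
        np.testing.assert_array_equal(mask, th.apply_threshold(d, t))

    def test_deterministic(self, biased_scene):
        a, _ = th.generate_pseudo_mask(biased_scene.depth, "ggt")
        b, _ = th.generate_pseudo_mask(biased_scene.depth, "ggt")
        np.testing.assert_array_equal(a, b)

    def test_unknown_method_rejected(self, unbiased_scene):
        with pytest.raises(ParameterError):
            th.generate_pseudo_mask(unbiased_scene.depth, "watershed")

    def test_ggt_beats_otsu_on_biased_batch(self):
        from cropdepth.metrics import iou

        scenes, _ = synthetic.generate_batch(synthetic.SceneSpec.biased(), 8, 300)
        gap = []
        for sc in scenes:
            mg, _ = th.generate_pseudo_mask(sc.depth, "ggt")
            mo, _ = th.generate_pseudo_mask(sc.depth, "otsu")
            gap.append(iou(mg, sc.mask) - iou(mo, sc.mask))
        assert np.mean(gap) >= 0.2
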