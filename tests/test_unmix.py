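"""Matched-filter and NNLS estimators, scalar summaries, response curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glowsplit.colorspace import LinearRGBImage, TristimulusImage, DEFAULT_CAMERA_MATRIX
from glowsplit.spectra import DEFAULT_BASIS
from glowsplit.synthkit import StripSpec, render_scene, render_test_strip, synth_scene
from glowsplit.unmix import (
    blue_channel_proxy,
    contrast_gain_percent,
    integrate_fluorescence,
    matched_filter,
    matched_filter_alpha,
    nnls_batch,
    nnls_decompose,
    nnls_pixel,
    response_curve,
    rms_contrast,
)

from conftest import nnls_support_oracle

finite3 = st.lists(
    st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=3, max_size=3
)


class TestMatchedFilter:
    def test_x_unit_vector_returns_fluor_x_weight(self):
        assert matched_filter(np.array([[[1.0, 0.0, 0.0]]]))[0, 0] == 0.2149

    def test_zero_pixel_returns_zero(self):
        assert matched_filter(np.zeros((1, 1, 3)))[0, 0] == 0.0

    def test_linearity(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=(4, 4, 3))
        assert np.allclose(matched_filter(2 * c), 2 * matched_filter(c), atol=1e-12)

    def test_weights_match_fluorescence_column(self):
        eye = np.eye(3).reshape(3, 1, 3)
        assert np.array_equal(matched_filter(eye).ravel(), DEFAULT_BASIS.fluor_col)


class TestMatchedFilterAlpha:
    def test_pure_fluorescence_recovers_power_exactly(self):
        c = 3.7 * DEFAULT_BASIS.fluor_col
        assert abs(matched_filter_alpha(c.reshape(1, 1, 3))[0, 0] - 3.7) < 1e-10

    def test_pure_skin_gives_positive_confusion_bias(self):
        c = DEFAULT_BASIS.skin_col.reshape(1, 1, 3)
        f, s = DEFAULT_BASIS.fluor_col, DEFAULT_BASIS.skin_col
        expected = (f @ s) / (f @ f)  # independent arithmetic on the constants
        got = matched_filter_alpha(c)[0, 0]
        assert got > 0
        assert abs(got - expected) < 1e-12
        assert abs(expected - 0.309) < 1e-3

    def test_nonnegative_for_nonnegative_xyz(self):
        rng = np.random.default_rng(1)
        c = rng.uniform(0, 2, (5, 5, 3))
        assert np.all(matched_filter_alpha(c) >= 0)


class TestNNLSPixel:
    def test_zero_input_zero_output(self):
        beta, resid = nnls_pixel(np.zeros(3))
        assert np.array_equal(beta, np.zeros(3))
        assert np.array_equal(resid, np.zeros(3))

    def test_pure_fluorescence_exact(self):
        beta, resid = nnls_pixel(2.5 * DEFAULT_BASIS.fluor_col)
        assert np.allclose(beta, [0, 0, 2.5], atol=1e-10)
        assert np.linalg.norm(resid) < 1e-10

    def test_mixture_recovered_exactly(self):
        # independent forward product of the printed basis with (1, 2, 3)
        c = np.array(
            [
                1 * 1.000 + 2 * 0.0914 + 3 * 0.2149,
                1 * 1.000 + 2 * 0.0702 + 3 * 0.1614,
                1 * 1.000 + 2 * 0.3381 + 3 * 1.1198,
            ]
        )
        assert np.allclose(c, [1.8275, 1.6246, 5.0356])
        beta, resid = nnls_pixel(c)
        assert np.allclose(beta, [1, 2, 3], atol=1e-8)
        assert np.linalg.norm(resid) < 1e-8

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            nnls_pixel([np.nan, 0, 0])

    @given(finite3)
    @settings(max_examples=200, deadline=None)
    def test_kkt_conditions_hold(self, c):
        c = np.array(c)
        beta, resid = nnls_pixel(c)
        grad = -DEFAULT_BASIS.matrix.T @ resid  # gradient of 0.5||A b - c||^2
        assert np.all(beta >= 0)
        for i in range(3):
            if beta[i] > 1e-10:
                assert abs(grad[i]) < 1e-8
            else:
                assert grad[i] >= -1e-8

    @given(finite3)
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_support_enumeration_oracle(self, c):
        c = np.array(c)
        beta, resid = nnls_pixel(c)
        beta_o, rnorm_o = nnls_support_oracle(DEFAULT_BASIS.matrix, c)
        assert np.allclose(beta, beta_o, atol=1e-8)
        assert abs(np.linalg.norm(resid) - rnorm_o) < 1e-8

    def test_unconstrained_solution_returned_when_feasible(self):
        rng = np.random.default_rng(2)
        A = DEFAULT_BASIS.matrix
        for _ in range(50):
            beta_true = rng.uniform(0.1, 3, 3)
            beta, _ = nnls_pixel(A @ beta_true)
            unconstrained = np.linalg.solve(A, A @ beta_true)
            assert np.allclose(beta, unconstrained, atol=1e-9)


class TestNNLSBatch:
    def test_matches_per_pixel_solver(self):
        rng = np.random.default_rng(3)
        c = rng.normal(scale=2, size=(500, 3))
        beta, resid = nnls_batch(c)
        for i in range(0, 500, 37):
            b_i, r_i = nnls_pixel(c[i])
            assert np.allclose(beta[i], b_i, atol=1e-9)
            assert np.allclose(resid[i], r_i, atol=1e-9)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(4)
        c = rng.normal(size=(200, 3))
        beta, resid = nnls_batch(c)
        assert np.allclose(beta @ DEFAULT_BASIS.matrix.T + resid, c, atol=1e-8)

    def test_residual_beats_random_feasible_competitors(self):
        rng = np.random.default_rng(5)
        c = rng.normal(size=(20, 3))
        beta, resid = nnls_batch(c)
        rnorm = np.linalg.norm(resid, axis=1)
        A = DEFAULT_BASIS.matrix
        for i in range(20):
            probes = np.abs(beta[i] + rng.normal(scale=0.3, size=(1000, 3)))
            competitor = np.linalg.norm(probes @ A.T - c[i], axis=1)
            assert np.all(rnorm[i] <= competitor + 1e-9)

    def test_positive_homogeneity(self):
        rng = np.random.default_rng(6)
        c = rng.normal(size=(100, 3))
        beta1, _ = nnls_batch(c)
        beta3, _ = nnls_batch(3.0 * c)
        assert np.allclose(beta3, 3.0 * beta1, atol=1e-8)


class TestNNLSDecompose:
    def test_pure_fluorescence_blobs_recovered(self):
        rng = np.random.default_rng(7)
        beta_f = np.zeros((16, 16))
        beta_f[4:8, 4:8] = rng.uniform(0.5, 2, (4, 4))
        xyz = beta_f[..., None] * DEFAULT_BASIS.fluor_col
        maps = nnls_decompose(TristimulusImage(xyz))
        assert np.allclose(maps.beta_f, beta_f, atol=1e-8)
        assert np.allclose(maps.beta_w, 0, atol=1e-8)
        assert np.allclose(maps.beta_s, 0, atol=1e-8)

    def test_white_region_assigned_to_white(self):
        xyz = np.tile(0.8 * DEFAULT_BASIS.white_col, (4, 4, 1))
        maps = nnls_decompose(TristimulusImage(xyz))
        assert np.all(maps.beta_w > 0.7)
        assert np.allclose(maps.beta_f, 0, atol=1e-8)

    def test_scene_fixture_round_trip(self):
        truth = synth_scene((40, 40), seed=9)
        img = render_scene(truth, seed=9)
        maps = nnls_decompose(img)
        assert np.allclose(maps.beta_w, truth.beta_w_map, atol=1e-8)
        assert np.allclose(maps.beta_s, truth.beta_s_map, atol=1e-8)
        assert np.allclose(maps.beta_f, truth.beta_f_map, atol=1e-8)

    def test_unmasked_pixels_zeroed(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        xyz = np.tile(DEFAULT_BASIS.fluor_col, (4, 4, 1))
        maps = nnls_decompose(TristimulusImage(xyz, mask=mask))
        assert maps.beta_f[0, 0] == pytest.approx(1.0, abs=1e-10)
        assert np.all(maps.beta_f[~mask] == 0)


class TestScalarSummaries:
    def test_uniform_map_integral(self):
        truth = synth_scene((10, 10), seed=0)
        maps = nnls_decompose(render_scene(truth, seed=0))
        maps.beta_f[:] = 0.5
        assert integrate_fluorescence(maps) == pytest.approx(0.5 * 100)

    def test_integral_linearity_and_fixture_bookkeeping(self):
        truth = synth_scene((32, 32), seed=12)
        maps = nnls_decompose(render_scene(truth, seed=12))
        total = integrate_fluorescence(maps)
        assert total == pytest.approx(truth.beta_f_map.sum(), abs=1e-6)
        maps.beta_f *= 2
        assert integrate_fluorescence(maps) == pytest.approx(2 * total, rel=1e-12)

    def test_saturated_pixels_excluded_by_default(self):
        maps = nnls_decompose(
            TristimulusImage(
                np.tile(DEFAULT_BASIS.fluor_col, (2, 2, 1)),
                saturated=np.array([[True, False], [False, False]]),
            )
        )
        assert integrate_fluorescence(maps) == pytest.approx(3.0, abs=1e-9)
        assert integrate_fluorescence(maps, include_saturated=True) == pytest.approx(4.0, abs=1e-9)

    def test_empty_mask_rejected(self):
        maps = nnls_decompose(TristimulusImage(np.zeros((2, 2, 3))))
        maps.mask[:] = False
        with pytest.raises(ValueError, match="empty mask"):
            integrate_fluorescence(maps)

    def test_rms_contrast_constant_map_is_zero(self):
        assert rms_contrast(np.full((4, 4), 2.0)) == 0.0

    def test_rms_contrast_half_zeros_half_ones(self):
        m = np.zeros((2, 4))
        m[:, :2] = 1.0
        assert rms_contrast(m) == pytest.approx(1.0)

    def test_rms_contrast_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            rms_contrast(np.zeros((3, 3)))

    def test_reference_contrast_gain_arithmetic(self):
        assert contrast_gain_percent(1.5, 1.0) == pytest.approx(50.0)


class TestBlueChannelProxy:
    def test_returns_blue_channel(self):
        img = LinearRGBImage(np.array([[[0.2, 0.4, 0.9]]]))
        assert blue_channel_proxy(img)[0, 0] == 0.9

    def test_pure_red_image_gives_zero_map(self):
        px = np.zeros((3, 3, 3))
        px[..., 0] = 0.5
        assert np.all(blue_channel_proxy(LinearRGBImage(px)) == 0)

    def test_blue_channel_is_linear_functional_of_xyz(self):
        # B = (third row of the inverse camera matrix) . XYZ, so the proxy and
        # the matched filter differ only by their weight vectors.
        rng = np.random.default_rng(10)
        px = rng.uniform(0, 0.8, (6, 6, 3))
        img = LinearRGBImage(px)
        from glowsplit.colorspace import rgb_to_xyz

        xyz = rgb_to_xyz(img).pixels
        weights = np.linalg.inv(DEFAULT_CAMERA_MATRIX)[2]
        assert np.allclose(xyz @ weights, blue_channel_proxy(img), atol=1e-10)


class TestResponseCurve:
    def test_noiseless_proportional_strip_is_linear(self):
        spec = StripSpec(n_swatches=8)
        img, boxes, conc, _ = render_test_strip(
            spec, response_model=lambda c: np.asarray(c, float)
        )
        table = response_curve(img, boxes, conc.tolist())
        r = np.corrcoef(table["concentration"], table["nnls_beta_f"])[0, 1]
        assert r**2 == pytest.approx(1.0, abs=1e-12)

    def test_clipping_breaks_nnls_monotonicity_but_mf_plateaus(self):
        spec = StripSpec(n_swatches=8, exposure_scale=6.0)
        img, boxes, conc, truth = render_test_strip(spec, clip_level=1.0)
        assert truth.clip_mask.any()  # generator bookkeeping confirms clipping
        table = response_curve(img, boxes, conc.tolist())
        d_nnls = np.diff(table["nnls_beta_f"].to_numpy())
        d_mf = np.diff(table["matched_filter"].to_numpy())
        assert (d_nnls < 0).any()  # non-monotone at the top end
        assert np.all(d_mf >= -1e-9)  # matched filter saturates, never drops

    def test_box_outside_image_rejected(self):
        img, boxes, conc, _ = render_test_strip(StripSpec(n_swatches=3))
        bad = [(0, 10_000, 0, 4)] + boxes[1:]
        with pytest.raises(ValueError, match="outside"):
            response_curve(img, bad, conc.tolist())

    def test_duplicate_concentrations_rejected(self):
        img, boxes, conc, _ = render_test_strip(StripSpec(n_swatches=3))
        with pytest.raises(ValueError, match="duplicate"):
            response_curve(img, boxes, [0.5, 0.5, 0.1])
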