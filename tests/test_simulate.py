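"""Transport scaling and the synthetic-scan generator."""

import math

import numpy as np
import pytest

from sc2wb import (
    ArrayLayout,
    ConfigError,
    TargetSpec,
    band_sigma,
    diffusion_time,
    diffusive_loss,
    lane_rois,
    simulate_array,
    simulate_timecourse,
)


class TestTransportScaling:
    @pytest.mark.parametrize(
        "x, D, expected",
        [
            (10.0, 88.0, 0.5682),  # GFP reaching the open microwell top: ~0.6 s
            (10.0, 80.0, 0.625),  # detergent micelle over the same length
            (0.0, 88.0, 0.0),
        ],
    )
    def test_diffusion_time(self, x, D, expected):
        assert diffusion_time(x, D) == pytest.approx(expected, abs=5e-4)

    def test_diffusion_time_domain(self):
        with pytest.raises(ValueError):
            diffusion_time(-1.0, 88.0)
        with pytest.raises(ValueError):
            diffusion_time(10.0, 0.0)

    @pytest.mark.parametrize(
        "sigma0, D, t, expected",
        [
            (8.0, 88.0, 10.0, math.sqrt(64 + 1760)),  # 42.71 um
            (8.0, 88.0, 0.0, 8.0),
            (8.0, 0.0, 10.0, 8.0),
        ],
    )
    def test_band_sigma(self, sigma0, D, t, expected):
        assert band_sigma(sigma0, D, t) == pytest.approx(expected, rel=1e-12)

    def test_band_sigma_domain(self):
        with pytest.raises(ValueError):
            band_sigma(-1.0, 88.0, 10.0)

    def test_diffusive_loss(self):
        assert diffusive_loss(0.0, 10.0) == 0.0
        assert diffusive_loss(10.0, 10.0) == pytest.approx(1 - math.exp(-1), rel=1e-12)
        assert diffusive_loss(1e9, 10.0) < 1.0  # clamped below 1
        with pytest.raises(ValueError):
            diffusive_loss(10.0, 0.0)


class TestSimulateArray:
    def test_identical_seed_bit_identical(self, layout_2x2, cyt_target):
        a_img, a_truth = simulate_array(layout_2x2, [cyt_target], seed=11)
        b_img, b_truth = simulate_array(layout_2x2, [cyt_target], seed=11)
        np.testing.assert_array_equal(a_img["AF647"], b_img["AF647"])
        assert a_truth.equals(b_truth)
        c_img, _ = simulate_array(layout_2x2, [cyt_target], seed=12)
        assert not np.array_equal(a_img["AF647"], c_img["AF647"])

    def test_rendered_band_conserves_true_auc(self, cyt_target):
        # noiseless, lossless: lane pixel sum * pixel size == true total AUC
        lay = ArrayLayout(n_rows=1, n_cols=1)
        images, truth = simulate_array(lay, [cyt_target], noise_sd=0.0, seed=2)
        (roi,) = lane_rois(lay)
        rs, cs = roi.slices()
        rendered = images["AF647"][rs, cs].sum() * lay.pixel_size
        assert rendered == pytest.approx(truth["true_total_auc"].iloc[0], rel=5e-3)

    def test_all_nuclear_leaves_east_empty(self):
        lay = ArrayLayout(n_rows=1, n_cols=1)
        target = TargetSpec(name="laminAC", nuclear_fraction_mean=1.0,
                            nuclear_fraction_sd=0.0, expected_compartment="nuclear")
        images, _ = simulate_array(lay, [target], noise_sd=0.0, seed=0)
        (roi,) = lane_rois(lay)
        rs, cs = roi.slices()
        lane = images["AF647"][rs, cs]
        east_cols = lane[:, lane.shape[1] // 2 + 4 :]  # east of the well
        assert east_cols.sum() == pytest.approx(0.0, abs=1e-6)

    def test_diffusive_loss_scales_rendered_signal(self, cyt_target):
        lay = ArrayLayout(n_rows=1, n_cols=1)
        imgs, truth = simulate_array(lay, [cyt_target], noise_sd=0.0, seed=3, tau_loss=250.0)
        loss = truth["loss_fraction"].iloc[0]
        assert loss == pytest.approx(diffusive_loss(25.0, 250.0))
        (roi,) = lane_rois(lay)
        rs, cs = roi.slices()
        rendered = imgs["AF647"][rs, cs].sum() * lay.pixel_size
        assert rendered == pytest.approx((1 - loss) * truth["true_total_auc"].iloc[0], rel=5e-3)

    def test_expression_cv_converges(self):
        lay = ArrayLayout(n_rows=10, n_cols=20)
        target = TargetSpec(name="t", expression_cv=0.4)
        _, truth = simulate_array(lay, [target], n_cells=200, noise_sd=0.0, seed=4)
        auc = truth["true_total_auc"]
        cv = auc.std(ddof=1) / auc.mean()
        assert cv == pytest.approx(0.4, rel=0.20)

    def test_too_many_cells_is_config_error(self, layout_2x2, cyt_target):
        with pytest.raises(ConfigError, match="exceeds"):
            simulate_array(layout_2x2, [cyt_target], n_cells=5)

    def test_beta_fraction_model_matches_moments(self):
        lay = ArrayLayout(n_rows=10, n_cols=20)
        target = TargetSpec(name="t", nuclear_fraction_mean=0.3, nuclear_fraction_sd=0.1)
        _, truth = simulate_array(lay, [target], n_cells=200, noise_sd=0.0, seed=5,
                                  fraction_model="beta")
        f = truth["true_nuclear_fraction"]
        assert f.between(0, 1).all()
        assert f.mean() == pytest.approx(0.3, abs=0.03)


class TestSimulateTimecourse:
    def test_constant_curve_statistically_identical(self, cyt_target):
        lay = ArrayLayout(n_rows=2, n_cols=5)
        sims = simulate_timecourse(lay, [cyt_target], [0, 30, 60], lambda t: 0.5, 10, seed=6)
        means = [truth["true_nuclear_fraction"].mean() for _, truth in sims.values()]
        assert np.ptp(means) < 0.15

    def test_truth_medians_peak_at_curve_peak(self):
        from sc2wb import nfkb_pulse

        lay = ArrayLayout(n_rows=10, n_cols=10)
        target = TargetSpec(name="NFkB", nuclear_fraction_sd=0.11)
        sims = simulate_timecourse(
            lay, [target], list(range(0, 121, 15)), nfkb_pulse(), 100, seed=7
        )
        medians = {tp: truth["true_nuclear_fraction"].median() for tp, (_, truth) in sims.items()}
        assert max(medians, key=medians.get) == 60

    def test_zero_cells_degenerate(self, layout_2x2, cyt_target):
        sims = simulate_timecourse(layout_2x2, [cyt_target], [0, 15], lambda t: 0.5, 0, seed=8)
        for images, truth in sims.values():
            assert truth.empty
            assert images["AF647"].shape == layout_2x2.image_shape()

    def test_empty_timepoints_is_config_error(self, layout_2x2, cyt_target):
        with pytest.raises(ConfigError, match="non-empty"):
            simulate_timecourse(layout_2x2, [cyt_target], [], lambda t: 0.5, 1)
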