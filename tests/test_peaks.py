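"""Gaussian band fitting, threshold-based peak calling and 4-sigma AUC."""

import math

import numpy as np
import pytest

from sc2wb import ArrayLayout, PeakFit, TargetSpec, auc_4sigma, call_peaks, fit_gaussian
from sc2wb import extract_profile, lane_rois, simulate_array

GAUSS_MASS = math.erf(2 / math.sqrt(2))  # 0.9545, band mass within +/- 2 sigma


class TestFitGaussian:
    def test_noiseless_identity_fit(self, make_profile):
        prof = make_profile(bands=[(100.0, 50.0, 5.0)], background_sd=1.0)
        pk = fit_gaussian(prof, (30.0, 70.0))
        assert pk.amplitude == pytest.approx(100.0, rel=1e-6)
        assert pk.x == pytest.approx(50.0, abs=1e-6)
        assert pk.sigma == pytest.approx(5.0, rel=1e-6)
        assert pk.r2 == pytest.approx(1.0, abs=1e-9)
        assert pk.called
        assert pk.w == 4 * pk.sigma

    def test_high_snr_recovery_over_seeds(self, make_profile):
        xs, sigmas = [], []
        for seed in range(100):
            prof = make_profile(bands=[(100.0, 50.0, 25.0)], noise_sd=1.0, seed=seed)
            pk = fit_gaussian(prof, (-25.0, 125.0))
            xs.append(pk.x)
            sigmas.append(pk.sigma)
        assert np.all(np.abs(np.array(xs) - 50.0) < 1.0)
        assert np.all(np.abs(np.array(sigmas) / 25.0 - 1.0) < 0.05)

    def test_noise_only_window_stays_uncalled(self, make_profile):
        called = 0
        n = 300
        for seed in range(n):
            prof = make_profile(bands=[], noise_sd=5.0, seed=seed)
            pk = fit_gaussian(prof, (100.0, 400.0))
            called += pk.snr > 3 and pk.r2 > 0.7
        assert called / n <= 0.01

    def test_too_few_samples_is_error(self, make_profile):
        prof = make_profile(bands=[(10.0, 50.0, 5.0)])
        with pytest.raises(ValueError, match="need >= 5"):
            fit_gaussian(prof, (48.0, 52.0))


class TestCallPeaks:
    def test_two_noiseless_east_bands(self, make_profile):
        prof = make_profile(bands=[(100.0, 150.0, 25.0), (80.0, 300.0, 25.0)],
                            background_sd=1.0)
        east = call_peaks(prof, "east")
        west = call_peaks(prof, "west")
        assert len(east) == 2 and len(west) == 0
        assert east[0].x == pytest.approx(150.0, abs=1.0)  # sorted by |x|
        assert east[1].x == pytest.approx(300.0, abs=1.0)

    def test_low_snr_band_not_called(self, make_profile):
        prof = make_profile(bands=[(10.0, 200.0, 25.0)], noise_sd=5.0, seed=1)
        peaks = call_peaks(prof, "east")  # SNR = 2 < 3
        assert peaks == []

    def test_resolved_triplet_called_in_seeded_runs(self, make_profile):
        hits = 0
        for seed in range(50):
            prof = make_profile(
                bands=[(100.0, 100.0, 12.0), (90.0, 250.0, 12.0), (80.0, 400.0, 12.0)],
                noise_sd=2.0, seed=seed,
            )
            hits += len(call_peaks(prof, "east")) == 3
        assert hits >= 48  # >= 95% of runs

    def test_monotone_calling_in_noise(self, make_profile):
        mean_calls = []
        for noise_sd in (2.0, 20.0, 60.0, 150.0):
            counts = [
                len(call_peaks(make_profile(bands=[(100.0, 250.0, 25.0)],
                                            noise_sd=noise_sd, seed=s), "east"))
                for s in range(50)
            ]
            mean_calls.append(np.mean(counts))
        assert all(a >= b - 1e-9 for a, b in zip(mean_calls, mean_calls[1:]))

    def test_well_straddling_band_flagged(self, make_profile):
        prof = make_profile(bands=[(100.0, 30.0, 20.0)], background_sd=1.0)
        peaks = call_peaks(prof, "east")
        assert peaks and peaks[0].compartment == "well-straddling"


class TestAUC:
    def test_windowed_integral_matches_erf_oracle(self, make_profile):
        # fine sampling: trapezoid over [x-2s, x+2s] = 0.9545 * A * s * sqrt(2pi)
        prof = make_profile(bands=[(1.0, 100.0, 10.0)], spacing=0.5, background_sd=1e-6)
        pk = fit_gaussian(prof, (50.0, 150.0))
        auc = auc_4sigma(prof, pk)
        expected = GAUSS_MASS * 1.0 * 10.0 * math.sqrt(2 * math.pi)  # 23.92
        assert auc == pytest.approx(expected, rel=5e-3)
        assert auc == pytest.approx(23.92, abs=0.05)

    def test_fitted_curve_auc_option(self, make_profile):
        prof = make_profile(bands=[(1.0, 100.0, 10.0)], spacing=0.5, background_sd=1e-6)
        pk = fit_gaussian(prof, (50.0, 150.0))
        analytic = auc_4sigma(prof, pk, use_fitted=True)
        assert analytic == pytest.approx(GAUSS_MASS * math.sqrt(2 * math.pi) * 10.0, rel=1e-6)

    def test_zero_profile_gives_zero(self, make_profile):
        prof = make_profile(bands=[])
        pk = PeakFit(cell_id=0, channel="", x=100.0, sigma=10.0, amplitude=0.0,
                     snr=0.0, r2=0.0)
        assert auc_4sigma(prof, pk) == 0.0

    def test_linearity_in_amplitude(self, make_profile):
        pk = PeakFit(cell_id=0, channel="", x=100.0, sigma=10.0, amplitude=1.0,
                     snr=10.0, r2=1.0)
        a1 = auc_4sigma(make_profile(bands=[(1.0, 100.0, 10.0)]), pk)
        a2 = auc_4sigma(make_profile(bands=[(2.0, 100.0, 10.0)]), pk)
        assert a2 == pytest.approx(2 * a1, rel=1e-9)

    def test_window_outside_lane_flagged_zero(self, make_profile):
        prof = make_profile(bands=[])
        pk = PeakFit(cell_id=0, channel="", x=700.0, sigma=10.0, amplitude=1.0,
                     snr=10.0, r2=1.0)
        assert auc_4sigma(prof, pk) == 0.0
        assert "auc_window_outside_lane" in pk.flags


class TestRecoveryOnSimulatedScenes:
    def test_called_auc_tracks_true_side_auc(self):
        lay = ArrayLayout(n_rows=10, n_cols=10)
        target = TargetSpec(name="t", nuclear_fraction_mean=0.0, nuclear_fraction_sd=0.0,
                            expected_compartment="cytoplasmic")
        images, truth = simulate_array(lay, [target], seed=9, tau_loss=250.0)
        ratios = []
        truth = truth.set_index("cell_id")
        for roi in lane_rois(lay):
            prof = extract_profile(images["AF647"], roi, lay)
            peaks = call_peaks(prof, "east")
            if not peaks:
                continue
            t = truth.loc[roi.cell_id]
            expected = (1 - t["loss_fraction"]) * t["true_total_auc"]
            ratios.append(sum(p.auc for p in peaks) / expected)
        assert len(ratios) == 100
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)
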