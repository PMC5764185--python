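"""Localization fractions, separation resolution, peak capacity, migration CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sc2wb import (
    ArrayLayout,
    PeakFit,
    TargetSpec,
    localization,
    migration_cv,
    normalize_expression,
    peak_capacity,
    quantify_images,
    separation_resolution,
    simulate_array,
)


def _peak(x, sigma=25.0, auc=100.0, called=True, compartment=None, cell_id=0):
    comp = compartment or ("east" if x > 0 else "west")
    return PeakFit(cell_id=cell_id, channel="AF647", x=x, sigma=sigma, amplitude=10.0,
                   snr=10.0, r2=0.95, auc=auc, called=called, compartment=comp)


class TestLocalization:
    def test_all_west_is_fully_nuclear(self):
        rec = localization([_peak(-250.0, auc=100.0)])
        assert rec.nuc_fraction == 1.0
        assert rec.cyt_fraction == 0.0

    def test_even_split(self):
        rec = localization([_peak(-250.0, auc=50.0), _peak(250.0, auc=50.0)])
        assert rec.nuc_fraction == 0.5

    def test_fractions_always_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            e, w = rng.uniform(0.1, 100, 2)
            rec = localization([_peak(250.0, auc=e), _peak(-250.0, auc=w)])
            assert rec.nuc_fraction + rec.cyt_fraction == pytest.approx(1.0, rel=1e-12)
            assert 0 <= rec.nuc_fraction <= 1

    def test_orientation_flip_swaps_fractions(self):
        peaks = [_peak(250.0, auc=80.0), _peak(-250.0, auc=20.0)]
        default = localization(peaks, east_is_cytoplasmic=True)
        flipped = localization(peaks, east_is_cytoplasmic=False)
        assert default.nuc_fraction == pytest.approx(0.2)
        assert flipped.nuc_fraction == pytest.approx(0.8)

    def test_no_called_peaks_flagged_not_detected(self):
        rec = localization([_peak(250.0, called=False)], cell_id=3)
        assert not rec.detected
        assert "not_detected" in rec.flags
        assert np.isnan(rec.nuc_fraction)

    def test_well_straddling_excluded(self):
        rec = localization([_peak(250.0, auc=50.0),
                            _peak(10.0, auc=50.0, compartment="well-straddling")])
        assert rec.auc_total == 50.0
        assert "well_straddling_excluded" in rec.flags


class TestSeparationResolution:
    def test_hand_value(self):
        p1, p2 = _peak(300.0, sigma=25.0), _peak(100.0, sigma=25.0)
        assert separation_resolution(p1, p2) == pytest.approx(2.0)  # 200 / 100

    def test_identical_peaks_zero(self):
        p = _peak(150.0)
        assert separation_resolution(p, p) == 0.0

    def test_bidirectional_pair(self):
        # west at -200 vs east at +200, sigma 30 -> Rs = 400/120
        p1, p2 = _peak(-200.0, sigma=30.0), _peak(200.0, sigma=30.0)
        assert separation_resolution(p1, p2) == pytest.approx(400 / 120)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        x1=st.floats(-450, 450), x2=st.floats(-450, 450),
        s1=st.floats(5, 60), s2=st.floats(5, 60),
        shift=st.floats(-100, 100),
    )
    def test_symmetry_and_translation_invariance(self, x1, x2, s1, s2, shift):
        a, b = _peak(x1, sigma=s1), _peak(x2, sigma=s2)
        rs = separation_resolution(a, b)
        assert rs == pytest.approx(separation_resolution(b, a), rel=1e-12)
        a2, b2 = _peak(x1 + shift, sigma=s1), _peak(x2 + shift, sigma=s2)
        assert rs == pytest.approx(separation_resolution(a2, b2), rel=1e-9, abs=1e-12)
        assert rs >= 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(gap=st.floats(1, 200), extra=st.floats(1, 100))
    def test_strictly_increasing_with_center_distance(self, gap, extra):
        s = 25.0
        near = separation_resolution(_peak(100.0, sigma=s), _peak(100.0 + gap, sigma=s))
        far = separation_resolution(_peak(100.0, sigma=s), _peak(100.0 + gap + extra, sigma=s))
        assert far > near


class TestPeakCapacity:
    def test_hand_values(self):
        assert peak_capacity(1000.0, [_peak(250.0, sigma=25.0)]) == pytest.approx(10.0)
        assert peak_capacity(1000.0, [_peak(250.0, sigma=96.4 / 4)]) == pytest.approx(10.37, abs=0.005)

    def test_widest_called_peak_governs(self):
        peaks = [_peak(150.0, sigma=10.0), _peak(300.0, sigma=25.0),
                 _peak(-200.0, sigma=50.0, called=False)]
        assert peak_capacity(1000.0, peaks) == pytest.approx(10.0)

    def test_degenerate_and_empty(self):
        assert peak_capacity(1000.0, [_peak(250.0, sigma=300.0)]) < 1  # valid, degenerate
        assert np.isnan(peak_capacity(1000.0, []))
        with pytest.raises(ValueError):
            peak_capacity(0.0, [_peak(250.0)])


class TestMigrationCV:
    def test_equal_distances_zero(self):
        peaks = [_peak(250.0, cell_id=i) for i in range(5)]
        assert migration_cv(peaks) == 0.0

    def test_hand_value(self):
        peaks = [_peak(float(x), cell_id=i) for i, x in enumerate((95, 100, 105))]
        assert migration_cv(peaks) == pytest.approx(5.0)

    def test_requires_two_cells(self):
        with pytest.raises(ValueError):
            migration_cv([_peak(100.0)])

    def test_recovers_configured_cv_at_n187(self):
        lay = ArrayLayout(n_rows=17, n_cols=11)
        target = TargetSpec(name="TurboGFP", nuclear_fraction_mean=0.0,
                            nuclear_fraction_sd=0.0, expected_compartment="cytoplasmic")
        images, _ = simulate_array(lay, [target], n_cells=187, seed=10, migration_cv=6.4)
        _, _, metrics = quantify_images(images, lay, [target])
        assert metrics["migration_cv"]["TurboGFP"] == pytest.approx(6.4, abs=1.0)


class TestNormalizeExpression:
    def test_mean_and_max_normalization(self):
        df = pd.DataFrame(
            {
                "target": ["a"] * 4,
                "auc_total": [1.0, 2.0, 3.0, 10.0],
                "detected": [True, True, True, True],
            }
        )
        out = normalize_expression(df)
        assert out["norm_expression_mean"].mean() == pytest.approx(1.0)
        assert out["norm_expression_max"].max() == pytest.approx(1.0)
        assert out["norm_expression_max"].iloc[0] == pytest.approx(0.1)

    def test_undetected_cells_excluded(self):
        df = pd.DataFrame(
            {
                "target": ["a", "a", "a"],
                "auc_total": [1.0, 3.0, 100.0],
                "detected": [True, True, False],
            }
        )
        out = normalize_expression(df)
        assert np.isnan(out["norm_expression_mean"].iloc[2])
        assert out["norm_expression_mean"].iloc[1] == pytest.approx(1.5)
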