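"""Hop injection, ilr transforms, calibration regression and inverse estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lowcov import (
    downsample,
    estimate_hop_level,
    fit_level_regression,
    ilr_2part,
    ilr_3part,
    inject_hopping,
    simulate_reads,
    simulate_truth,
    tally_counts,
)
from lowcov.example_data import CALIBRATION_LEVELS, example_calibration, example_observed
from lowcov.hopping import estimate_hopping, ilr_variables


@pytest.fixture(scope="module")
def multiplex():
    truth = simulate_truth(8, 400, seed=31)
    return truth, simulate_reads(truth, 3.0, 0.01, seed=32)


class TestDownsample:
    def test_fraction_one_keeps_everything(self, multiplex):
        _, reads = multiplex
        assert len(downsample(reads, 1.0, seed=1)) == len(reads)

    def test_fraction_zero_empties(self, multiplex):
        _, reads = multiplex
        assert len(downsample(reads, 0.0, seed=1)) == 0

    def test_kept_count_is_binomial(self):
        truth = simulate_truth(10, 1500, seed=33)
        reads = simulate_reads(truth, 10.0, 0.01, seed=34)
        n = len(reads)
        kept = len(downsample(reads, 1 / 15, seed=35))
        sd = np.sqrt(n * (1 / 15) * (14 / 15))
        assert abs(kept - n / 15) < 3 * sd

    def test_fraction_out_of_range(self, multiplex):
        _, reads = multiplex
        with pytest.raises(ValueError):
            downsample(reads, 1.5, seed=0)


class TestInjectHopping:
    def test_zero_rate_changes_nothing(self, multiplex):
        _, reads = multiplex
        out = inject_hopping(reads, 0.0, seed=1)
        assert (out.assigned_sample == out.true_sample).all()

    def test_rate_one_moves_every_fragment(self, multiplex):
        _, reads = multiplex
        out = inject_hopping(reads, 1.0, seed=2)
        assert (out.assigned_sample != out.true_sample).all()

    def test_hopped_fraction_is_binomial(self):
        # ~100 000 fragments at h = 0.05
        truth = simulate_truth(10, 2000, seed=41)
        reads = simulate_reads(truth, 5.0, 0.01, seed=42)
        out = inject_hopping(reads, 0.05, seed=3)
        n = len(reads)
        frac = float((out.assigned_sample != out.true_sample).mean())
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)

    def test_conserves_fragments_and_per_site_totals(self, multiplex):
        truth, reads = multiplex
        out = inject_hopping(reads, 0.10, seed=4)
        assert len(out) == len(reads)
        before = np.bincount(reads.site, minlength=truth.n_sites)
        after = np.bincount(out.site, minlength=truth.n_sites)
        np.testing.assert_array_equal(before, after)
        # per-site allele totals across the whole multiplex are unchanged
        r0, a0 = tally_counts(reads, truth.n_samples, truth.n_sites)
        r1, a1 = tally_counts(out, truth.n_samples, truth.n_sites)
        np.testing.assert_array_equal(r0.sum(axis=0), r1.sum(axis=0))
        np.testing.assert_array_equal(a0.sum(axis=0), a1.sum(axis=0))

    def test_target_uniform_over_other_samples(self):
        truth = simulate_truth(5, 2000, seed=36)
        reads = simulate_reads(truth, 5.0, 0.01, seed=37)
        out = inject_hopping(reads, 1.0, seed=38)
        # destinations of sample 0's fragments spread evenly over 1..4
        dest = out.assigned_sample[out.true_sample == 0]
        counts = np.bincount(dest, minlength=5)
        assert counts[0] == 0
        expected = len(dest) / 4
        assert (np.abs(counts[1:] - expected) < 5 * np.sqrt(expected)).all()

    def test_single_sample_multiplex_rejected(self):
        truth = simulate_truth(1, 10, seed=39)
        reads = simulate_reads(truth, 2.0, 0.01, seed=40)
        with pytest.raises(ValueError, match="single-sample"):
            inject_hopping(reads, 0.1, seed=0)


class TestIlr:
    def test_published_cells(self):
        assert round(ilr_3part(98.45, 1.42, 0.13), 2) == 4.44
        assert round(ilr_3part(96.34, 3.29, 0.37), 2) == 3.65
        assert round(ilr_2part(98.45, 1.42), 2) == 3.00
        assert round(ilr_2part(98.10, 1.71), 2) == 2.86

    @settings(derandomize=True, max_examples=100)
    @given(x=st.floats(0.01, 99.9))
    def test_equal_parts_give_zero(self, x):
        assert ilr_3part(x, x, x) == pytest.approx(0.0, abs=1e-12)
        assert ilr_2part(x, x) == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.floats(0.1, 99.0),
        b=st.floats(0.1, 99.0),
        c=st.floats(0.1, 99.0),
        k=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, a, b, c, k):
        # counts and percentages give identical ilr values
        assert ilr_3part(k * a, k * b, k * c) == pytest.approx(ilr_3part(a, b, c), rel=1e-9)
        assert ilr_2part(k * a, k * b) == pytest.approx(ilr_2part(a, b), rel=1e-9)

    def test_zero_part_raises(self):
        with pytest.raises(ValueError, match="positive"):
            ilr_3part(10.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="positive"):
            ilr_2part(0.0, 1.0)


class TestRegression:
    def test_collinear_points_fit_perfectly(self):
        fit = fit_level_regression([0, 1, 2, 5], [1.0, 3.0, 5.0, 11.0], degree=1)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.coefficients[1] == pytest.approx(2.0)

    def test_quadratic_interpolates_four_points_on_parabola(self):
        levels = [0.0, 1.0, 2.0, 5.0]
        resp = [2 + 0.5 * l - 0.1 * l**2 for l in levels]
        fit = fit_level_regression(levels, resp, degree=2)
        assert fit.r_squared == pytest.approx(1.0)

    def test_published_homozygote_column_r2(self):
        fit = fit_level_regression(
            CALIBRATION_LEVELS, [99.62, 99.53, 99.28, 98.99, 98.20, 96.34], degree=1
        )
        assert round(fit.r_squared, 3) == 0.999

    def test_duplicate_levels_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_level_regression([0, 1, 1, 2], [1, 2, 3, 4], degree=1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_level_regression([0, 1], [1, 2], degree=1)


class TestEstimateHopLevel:
    def test_published_inverse_estimates(self):
        f02 = fit_level_regression(
            CALIBRATION_LEVELS, [0.04, 0.08, 0.10, 0.14, 0.23, 0.59], degree=1
        )
        assert round(estimate_hop_level(f02, 0.18), 2) == 1.28
        f12 = fit_level_regression(
            CALIBRATION_LEVELS, [0.47, 0.52, 0.92, 1.33, 2.16, 4.75], degree=1
        )
        assert round(estimate_hop_level(f12, 1.71), 2) == 1.45

    def test_inverse_of_own_prediction(self):
        fit = fit_level_regression(
            CALIBRATION_LEVELS, [99.62, 99.53, 99.28, 98.99, 98.20, 96.34], degree=1
        )
        assert estimate_hop_level(fit, float(fit.predict(2.0))) == pytest.approx(2.0)

    def test_quadratic_root_selection_in_span(self):
        levels = [0.0, 0.1, 0.5, 1.0, 2.0, 5.0]
        resp = [5.0 - 0.8 * l + 0.05 * l**2 for l in levels]
        fit = fit_level_regression(levels, resp, degree=2)
        est = estimate_hop_level(fit, 5.0 - 0.8 * 1.5 + 0.05 * 1.5**2)
        assert est == pytest.approx(1.5, abs=1e-6)

    def test_observed_outside_range_raises(self):
        levels = [0.0, 0.5, 1.0, 2.0, 5.0]
        resp = [5.0 - 0.8 * l + 0.05 * l**2 for l in levels]
        fit = fit_level_regression(levels, resp, degree=2)
        with pytest.raises(ValueError, match="calibrated range"):
            estimate_hop_level(fit, 100.0)

    def test_zero_slope_raises(self):
        fit = fit_level_regression([0, 1, 2, 3], [4.0, 4.0, 4.0, 4.0], degree=1)
        with pytest.raises(ValueError, match="slope"):
            estimate_hop_level(fit, 4.0)


class TestEstimateHoppingTable:
    def test_percent_estimates_match_published_cells(self):
        est = estimate_hopping(example_calibration(), example_observed(), "percent")
        by_var = est.set_index("variable")["estimate_percent"]
        assert round(by_var["0|2"], 2) == 1.28
        assert round(by_var["1|2"], 2) == 1.45

    def test_ilr_estimates_fall_in_published_range(self):
        for response in ("ilr3", "ilr2"):
            est = estimate_hopping(example_calibration(), example_observed(), response)
            hom = est[est["variable"].str.startswith(("0|0", "2|2"))]
            assert ((hom["estimate_percent"] > 1.25) & (hom["estimate_percent"] < 1.85)).all()

    def test_ilr_variables_helper_consistent(self):
        obs = example_observed()
        ilr = ilr_variables(obs)
        assert ilr["0|0 vs 1|0, 2|0"] == pytest.approx(
            ilr_3part(obs["0|0"], obs["1|0"], obs["2|0"])
        )
        assert ilr["2|2 vs 1|2"] == pytest.approx(ilr_2part(obs["2|2"], obs["1|2"]))
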