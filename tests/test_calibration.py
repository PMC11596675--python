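import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nadomics import calibration as cal
from nadomics.panel_io import build_peak_table


def _peaks(panel, rows):
    frame = pd.DataFrame(rows, columns=["sample_id", "channel_id", "area"])
    frame["rt"] = 1.0
    frame["role"] = "unknown"
    return build_peak_table(frame, panel)


class TestComputeResponses:
    def test_simple_ratio(self, panel):
        pt = _peaks(panel, [("s1", "NAD+|12C", 1000.0), ("s1", "NAD+|13C", 500.0)])
        resp = cal.compute_responses(pt, panel)
        row = resp[resp["analyte"] == "NAD+"].iloc[0]
        assert row["response"] == 2.0
        assert row["istd_channel"] == "NAD+|13C"

    def test_surrogate_channel_used_for_nca(self, panel):
        pt = _peaks(panel, [("s1", "NCA|12C", 300.0), ("s1", "NAM|13C", 600.0)])
        resp = cal.compute_responses(pt, panel)
        row = resp[resp["analyte"] == "NCA"].iloc[0]
        assert row["istd_channel"] == "NAM|13C"
        assert row["response"] == 0.5

    def test_zero_istd_flagged_no_response(self, panel):
        pt = _peaks(panel, [("s1", "NAD+|12C", 1000.0), ("s1", "NAD+|13C", 0.0)])
        resp = cal.compute_responses(pt, panel)
        row = resp[resp["analyte"] == "NAD+"].iloc[0]
        assert row["no_istd"]
        assert np.isnan(row["response"])


class TestBackgroundSubtraction:
    def _frames(self, std_resp, blank_resp):
        std = pd.DataFrame({
            "analyte": ["NAM"] * len(std_resp),
            "response": std_resp,
            "level_nM": np.arange(1, len(std_resp) + 1, dtype=float),
        })
        blank = pd.DataFrame({"analyte": ["NAM"] * len(blank_resp), "response": blank_resp})
        return std, blank

    def test_subtracts_blank_mean(self):
        std, blank = self._frames([2.0], [0.4, 0.6])
        out = cal.subtract_matrix_background(std, blank)
        assert out["response"].iloc[0] == 1.5
        assert not out["clipped"].any()

    def test_zero_blank_is_identity(self):
        std, blank = self._frames([2.0, 3.0], [0.0])
        out = cal.subtract_matrix_background(std, blank)
        assert list(out["response"]) == [2.0, 3.0]

    def test_negative_corrected_clipped_and_flagged(self):
        std, blank = self._frames([0.1], [0.5])
        out = cal.subtract_matrix_background(std, blank)
        assert out["response"].iloc[0] == 0.0
        assert out["clipped"].iloc[0]

    def test_no_blanks_is_error(self):
        std, _ = self._frames([1.0], [0.0])
        with pytest.raises(cal.CalibrationError):
            cal.subtract_matrix_background(std, pd.DataFrame(columns=["analyte", "response"]))

    def test_constant_background_recovers_background_free_fit(self):
        # adding a constant background b to every standard, then subtracting
        # the blank mean, must reproduce the clean fit to machine precision
        levels = np.geomspace(50, 10000, 12)
        clean = pd.DataFrame({
            "analyte": "NAM", "level_nM": levels, "response": 0.002 * levels + 0.01,
        })
        b = 0.7
        contaminated = clean.assign(response=clean["response"] + b)
        blanks = pd.DataFrame({"analyte": ["NAM"] * 3, "response": [b, b, b]})
        corrected = cal.subtract_matrix_background(contaminated, blanks)
        fit_clean = cal.fit_calibration(clean, analyte="NAM")
        fit_corr = cal.fit_calibration(corrected, analyte="NAM")
        assert fit_corr.slope == pytest.approx(fit_clean.slope, rel=1e-12)
        assert fit_corr.intercept == pytest.approx(fit_clean.intercept, abs=1e-12)


class TestFitCalibration:
    def test_exact_line(self):
        levels = np.geomspace(50, 10000, 12)
        curve = cal.fit_calibration(list(zip(levels, 0.001 * levels)))
        assert curve.slope == pytest.approx(0.001)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.residual_sd == pytest.approx(0.0, abs=1e-12)
        assert not curve.rejected

    def test_noisy_duplicates_recover_slope(self):
        rng = np.random.default_rng(11)
        levels = np.repeat(np.geomspace(50, 10000, 12), 2)
        y = 0.001 * levels + rng.normal(0, 0.01, len(levels))
        curve = cal.fit_calibration(list(zip(levels, y)))
        se = stats.linregress(levels, y).stderr
        assert abs(curve.slope - 0.001) < 3 * se
        assert curve.r_squared >= 0.98
        assert curve.n_points == 24

    def test_two_levels_rejected(self):
        with pytest.raises(cal.CalibrationError, match="3 distinct"):
            cal.fit_calibration([(1.0, 1.0), (1.0, 1.1), (2.0, 2.0)])

    def test_negative_slope_marks_rejected(self):
        curve = cal.fit_calibration([(1.0, 3.0), (2.0, 2.0), (3.0, 1.0)])
        assert curve.rejected

    def test_slope_coverage_over_simulated_batches(self):
        # +-2 SE covers the true slope in >= 90% of seeded batches
        rng = np.random.default_rng(202)
        levels = np.repeat(np.geomspace(50, 10000, 12), 2)
        true_slope, hits, n_batches = 0.001, 0, 200
        for _ in range(n_batches):
            y = true_slope * levels + rng.normal(0, 0.05, len(levels))
            fit = stats.linregress(levels, y)
            if abs(fit.slope - true_slope) <= 2 * fit.stderr:
                hits += 1
        assert hits / n_batches >= 0.90


class TestLodLoq:
    def test_hand_constructed_sigma_and_slope(self):
        # orthogonal residual pattern: slope exactly 0.001, residual SD exactly 0.002
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pattern = np.array([2.0, -1.0, -2.0, -1.0, 2.0])  # orthogonal to 1 and x
        c = 0.002 * np.sqrt(3.0 / 14.0)  # SSR = 14 c^2, sigma^2 = SSR / (n-2)
        y = 0.001 * x + c * pattern
        lod, loq = cal.estimate_lod_loq(list(zip(x, y)))
        assert lod == pytest.approx(6.6, rel=1e-9)
        assert loq == pytest.approx(20.0, rel=1e-9)

    def test_noiseless_series_gives_zero(self):
        x = np.array([0.78, 1.56, 3.13, 6.25, 12.5, 25, 50, 100])
        lod, loq = cal.estimate_lod_loq(list(zip(x, 0.001 * x)))
        assert lod == pytest.approx(0.0, abs=1e-12)
        assert loq == pytest.approx(0.0, abs=1e-12)

    def test_ratio_is_ten_over_three_point_three(self):
        rng = np.random.default_rng(5)
        x = np.repeat([0.78, 1.56, 3.13, 6.25, 12.5, 25, 50, 100], 2)
        y = 0.002 * x + rng.normal(0, 0.001, len(x))
        lod, loq = cal.estimate_lod_loq(list(zip(x, y)))
        assert loq / lod == pytest.approx(10 / 3.3, rel=1e-12)
        assert cal.loq_from_lod(lod) == pytest.approx(loq, rel=1e-12)

    def test_too_few_levels_rejected(self):
        with pytest.raises(cal.CalibrationError, match="levels"):
            cal.estimate_lod_loq([(1, 1), (2, 2), (3, 3), (4, 4)])


class TestBackCalculate:
    def _curve(self, slope=0.001, intercept=0.0):
        return cal.CalibrationCurve(
            analyte="X", slope=slope, intercept=intercept, r_squared=1.0,
            residual_sd=0.0, n_points=12,
        )

    def test_simple_inversion(self):
        assert cal.back_calculate(1.0, self._curve()) == pytest.approx(1000.0)

    def test_response_at_intercept_is_zero(self):
        assert cal.back_calculate(0.25, self._curve(intercept=0.25)) == 0.0

    def test_negative_clipped_to_zero(self):
        assert cal.back_calculate(-0.5, self._curve()) == 0.0

    def test_rejected_curve_refuses(self):
        curve = cal.fit_calibration([(1.0, 3.0), (2.0, 2.0), (3.0, 1.0)])
        with pytest.raises(cal.CalibrationError, match="rejected"):
            cal.back_calculate(1.0, curve)

    def test_noiseless_qc_round_trip(self):
        levels = np.geomspace(50, 10000, 12)
        curve = cal.fit_calibration(list(zip(levels, 0.004 * levels)))
        assert cal.back_calculate(0.004 * 2500, curve) == pytest.approx(2500.0)

    def test_mean_residual_of_fitting_points_is_zero(self):
        rng = np.random.default_rng(3)
        levels = np.repeat(np.geomspace(50, 10000, 12), 2)
        y = 0.001 * levels + rng.normal(0, 0.02, len(levels))
        curve = cal.fit_calibration(list(zip(levels, y)))
        back = cal.back_calculate(y, curve)
        # least-squares projection: residuals of back-calculated vs nominal average out
        assert np.mean(back - levels) == pytest.approx(0.0, abs=1e-8 * levels.mean())
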