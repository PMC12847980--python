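"""One-predictor OLS fits, their statistics, grids and model comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from topoqspr import (DescriptorRegression, RankError, best_predictor,
                      compare_forms, data, fit_model, r2_grid)
from topoqspr.regression import standardized_residuals


class TestFitModel:
    def test_three_point_hand_oracle(self):
        # x=(1,2,3), y=(1,2,4): normal equations give beta=3/2, alpha=-2/3
        res = fit_model([1, 2, 3], [1, 2, 4], "linear")
        assert res.beta == pytest.approx(1.5, abs=1e-12)
        assert res.alpha == pytest.approx(-2 / 3, abs=1e-12)

    def test_perfect_fit_sentinels(self):
        x = np.arange(1.0, 7.0)
        res = fit_model(x, 2 * x + 1, "linear")
        assert res.rsquared == 1.0
        assert math.isinf(res.fvalue) and res.f_pvalue == 0.0
        assert res.perfect_fit
        assert np.allclose(res.resid, 0)

    def test_logarithmic_equals_linear_on_log_predictor(self, study_tables):
        props, idx = study_tables
        x = idx["RI"].to_numpy()
        y = props["MV"].to_numpy()
        a = fit_model(x, y, "logarithmic")
        b = fit_model(np.log(x), y, "linear")
        assert a.alpha == pytest.approx(b.alpha, rel=1e-12)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.rsquared == pytest.approx(b.rsquared, rel=1e-12)

    def test_f_and_r2_consistency(self, study_tables):
        props, idx = study_tables
        for form, k in [("linear", 1), ("quadratic", 2), ("logarithmic", 1)]:
            res = fit_model(idx["H"].to_numpy(), props["BP"].to_numpy(), form)
            n, r2 = res.nobs, res.rsquared
            assert res.fvalue == pytest.approx((r2 / k) / ((1 - r2) / (n - k - 1)), rel=1e-9)

    def test_signed_r_for_negative_slope(self):
        x = np.arange(1.0, 10.0)
        res = fit_model(x, -3 * x + np.sin(x), "linear")
        assert res.rvalue < 0
        assert res.rvalue == pytest.approx(-math.sqrt(res.rsquared), rel=1e-12)

    def test_quadratic_r_is_positive_root(self, study_tables):
        props, idx = study_tables
        res = fit_model(idx["H"].to_numpy(), props["MP"].to_numpy(), "quadratic")
        assert res.rvalue == pytest.approx(math.sqrt(res.rsquared))

    def test_constant_predictor_raises_rank_error(self):
        with pytest.raises(RankError):
            fit_model([2.0] * 6, [1, 2, 3, 4, 5, 6], "linear")

    def test_nonpositive_predictor_rejected_for_log(self):
        with pytest.raises(ValueError, match="positive"):
            fit_model([-1, 1, 2, 3], [1, 2, 3, 4], "logarithmic")

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="at least"):
            fit_model([1, 2, 3], [1, 2, 3], "quadratic")


class TestStudyFits:
    def test_mv_ri_linear_matches_published_row(self):
        res = DescriptorRegression.from_study("MV", "RI", "linear").fit()
        assert res.beta == pytest.approx(26.866, abs=0.01)
        assert res.alpha == pytest.approx(4.223, abs=0.01)
        assert res.rsquared == pytest.approx(0.967, abs=0.001)
        assert res.fvalue == pytest.approx(202.938, abs=0.5)
        assert res.resid_se == pytest.approx(12.634, abs=0.01)
        assert res.f_pvalue <= 0.001  # displayed as 0.001 by SPSS-style output

    def test_mv_ri_quadratic_coefficients(self):
        res = DescriptorRegression.from_study("MV", "RI", "quadratic").fit()
        assert res.gamma == pytest.approx(-0.448, abs=0.01)
        assert res.beta == pytest.approx(32.180, abs=0.01)
        assert res.alpha == pytest.approx(-9.117, abs=0.01)

    def test_printed_index_source_agrees_closely(self):
        a = DescriptorRegression.from_study("MV", "RI", "linear").fit()
        b = DescriptorRegression.from_study("MV", "RI", "linear",
                                            index_source="printed").fit()
        assert a.rsquared == pytest.approx(b.rsquared, abs=1e-4)

    def test_summary_contains_key_statistics(self):
        s = DescriptorRegression.from_study("MV", "RI", "linear").fit().summary()
        assert "26.866" in s and "0.967" in s and "MV" in s


class TestStandardizedResiduals:
    def test_perfect_fit_gives_zeros(self):
        x = np.arange(1.0, 8.0)
        res = fit_model(x, 5 * x, "linear")
        assert np.all(standardized_residuals(res) == 0)

    def test_raw_residual_mean_is_zero(self, study_tables):
        props, idx = study_tables
        res = fit_model(idx["ABC"].to_numpy(), props["HAC"].to_numpy(), "linear")
        assert res.resid.mean() == pytest.approx(0.0, abs=1e-9)

    def test_largest_mv_ri_residual_is_nacetylglucosamine(self, study_tables):
        props, idx = study_tables
        res = fit_model(idx["RI"].to_numpy(), props["MV"].to_numpy(), "linear")
        z = standardized_residuals(res)
        assert len(z) == 9
        assert list(data.DRUGS)[int(np.argmax(np.abs(z)))] == "N-acetylglucosamine"


class TestGridAndComparison:
    def test_grid_cells_match_published_values(self, study_tables):
        props, idx = study_tables
        lin = r2_grid(props, idx, "linear")
        quad = r2_grid(props, idx, "quadratic")
        assert lin.loc["EV", "M2"] == pytest.approx(0.955, abs=0.001)
        assert quad.loc["MV", "RI"] == pytest.approx(0.968, abs=0.001)

    def test_misaligned_tables_rejected(self, study_tables):
        props, idx = study_tables
        with pytest.raises(ValueError, match="aligned"):
            r2_grid(props.iloc[:-1], idx, "linear")

    def test_nested_model_monotonicity_full_grid(self, study_tables):
        """Quadratic nests linear, so its R² can never be smaller."""
        props, idx = study_tables
        lin = r2_grid(props, idx, "linear")
        quad = r2_grid(props, idx, "quadratic")
        assert (quad.to_numpy() >= lin.to_numpy() - 1e-12).all()

    def test_best_predictor_mv_linear(self, study_tables):
        props, idx = study_tables
        ids, r2 = best_predictor(r2_grid(props, idx, "linear"), "MV")
        assert ids == ["RI"] and r2 == 0.967

    def test_best_predictor_tie_ev_logarithmic(self, study_tables):
        props, idx = study_tables
        ids, r2 = best_predictor(r2_grid(props, idx, "logarithmic"), "EV")
        assert ids == ["M1", "M2"] and r2 == 0.947

    def test_single_candidate_returns_itself(self, study_tables):
        props, idx = study_tables
        ids, _ = best_predictor(r2_grid(props, idx, "linear"), "BP", ["GA"])
        assert ids == ["GA"]

    def test_empty_candidates_rejected(self, study_tables):
        props, idx = study_tables
        with pytest.raises(ValueError):
            best_predictor(r2_grid(props, idx, "linear"), "BP", [])

    def test_compare_forms_winner_and_ties(self, study_tables):
        props, idx = study_tables
        grids = {f: r2_grid(props, idx, f) for f in ("linear", "quadratic", "logarithmic")}
        report = compare_forms(grids)
        assert all(report.winner(p) == "quadratic" for p in props.columns)
        # identical grids across forms -> every form ties, none silently dropped
        tied = compare_forms({"linear": grids["linear"], "logarithmic": grids["linear"]})
        assert all(set(w) == {"linear", "logarithmic"} for w in tied.winners.values())

    def test_comparison_frame_layout(self, study_tables):
        props, idx = study_tables
        grids = {f: r2_grid(props, idx, f) for f in ("linear", "quadratic", "logarithmic")}
        frame = compare_forms(grids).to_frame()
        assert set(frame.columns) == {"property", "form", "best_predictor", "R2",
                                      "winning_form"}
        assert len(frame) == 8 * 3
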