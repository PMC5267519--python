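"""RIS computation, Hill-3 calibration, prediction and cutoff inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cypind import (
    CalibrationModel,
    ConfigurationError,
    DataError,
    FitMethod,
    InductionCurveFit,
    RISValue,
    compute_ris,
    fit_calibration,
    predict_auc_change,
    ris_cutoff,
    summarize_ris,
)
from cypind.fixtures import calibration_points


def _fit(e_max, ec50):
    return InductionCurveFit(e_min=0.0, e_max=e_max, ec50=ec50, slope_b=1.0,
                             r_squared=1.0, method=FitMethod.FULL_FIT,
                             n_points_used=8, accepted=True)


class TestComputeRIS:
    def test_half_saturation(self):
        assert compute_ris(_fit(22.0, 0.36), cmax_ub=0.36).ris == pytest.approx(11.0)

    def test_saturation_limit(self):
        assert compute_ris(_fit(22.0, 0.36), cmax_ub=1e9).ris == pytest.approx(22.0, rel=1e-6)

    def test_direct_evaluation(self):
        # E_max 25, EC50 187 µM, unbound C_max 28 µM
        assert compute_ris(_fit(25.0, 187.0), cmax_ub=28.0).ris == pytest.approx(3.2558, abs=1e-3)

    def test_missing_cmax_raises(self):
        with pytest.raises(DataError, match="probenecid"):
            compute_ris(_fit(25.0, 187.0), cmax_ub=0.0, compound="probenecid")

    @given(
        e_max=st.floats(1.0, 100.0), ec50=st.floats(0.01, 100.0),
        cmax=st.floats(0.001, 100.0), factor=st.floats(1.01, 10.0),
    )
    @settings(deadline=None)
    def test_monotonicity(self, e_max, ec50, cmax, factor):
        base = compute_ris(_fit(e_max, ec50), cmax).ris
        assert compute_ris(_fit(e_max * factor, ec50), cmax).ris > base
        assert compute_ris(_fit(e_max, ec50 * factor), cmax).ris < base
        assert compute_ris(_fit(e_max, ec50), cmax * factor).ris > base


class TestSummarize:
    @staticmethod
    def _values(vals, compound="x"):
        return [RISValue(compound, f"L{i}", "mrna", v) for i, v in enumerate(vals)]

    def test_rifampicin_row(self):
        summary, _ = summarize_ris(self._values([19.1, 24.8, 21.5]))
        row = summary.iloc[0]
        assert row["mean_ris"] == pytest.approx(21.8, abs=0.05)
        assert round(row["cv_pct"]) == 13

    def test_identical_lots_zero_cv(self):
        summary, _ = summarize_ris(self._values([2.0, 2.0, 2.0]))
        assert summary.iloc[0]["cv_pct"] == pytest.approx(0.0)

    def test_two_lot_cv(self):
        summary, _ = summarize_ris(self._values([1.0, 3.0]))
        assert summary.iloc[0]["cv_pct"] == pytest.approx(70.7, abs=0.05)

    def test_single_lot_raises(self):
        with pytest.raises(DataError):
            summarize_ris(self._values([1.0]))


class TestCalibration:
    def test_noise_free_recovery(self):
        truth = CalibrationModel(a=95.0, b_slope=2.0, c=0.4)
        x = np.array([0.05, 0.1, 0.3, 0.8, 3.0, 20.0])
        y = truth.predict(x)
        model = fit_calibration(x, y)
        assert model.a == pytest.approx(95.0, rel=1e-6)
        assert model.b_slope == pytest.approx(2.0, rel=1e-6)
        assert model.c == pytest.approx(0.4, rel=1e-6)
        assert model.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_published_lot3b_mrna(self):
        _, ris, obs = calibration_points("mrna", "3B")
        model = fit_calibration(ris, obs, lot="3B", endpoint="mrna")
        assert model.r_squared == pytest.approx(0.99, abs=0.01)

    def test_published_lot2b_mrna(self):
        _, ris, obs = calibration_points("mrna", "2B")
        model = fit_calibration(ris, obs, lot="2B", endpoint="mrna")
        assert model.r_squared == pytest.approx(0.95, abs=0.01)

    def test_against_grid_search_oracle(self):
        """The optimizer beats an exhaustive coarse grid search and lands on
        the same basin (independent check of the nonlinear fit)."""
        _, ris, obs = calibration_points("mrna", "3B")
        x, y = np.asarray(ris), np.asarray(obs)
        a = np.linspace(80.0, 110.0, 61)
        b = np.geomspace(0.5, 8.0, 48)
        c = np.geomspace(0.05, 1.0, 48)
        A, B, C = np.meshgrid(a, b, c, indexing="ij")
        pred = A[..., None] * x**B[..., None] / (C[..., None] ** B[..., None] + x**B[..., None])
        sse = ((pred - y) ** 2).sum(axis=-1)
        idx = np.unravel_index(np.argmin(sse), sse.shape)
        grid_best = (A[idx], B[idx], C[idx])

        model = fit_calibration(ris, obs)
        model_sse = float(((model.predict(x) - y) ** 2).sum())
        assert model_sse <= sse[idx] + 1e-9
        assert model.a == pytest.approx(grid_best[0], rel=0.05)
        assert model.b_slope == pytest.approx(grid_best[1], rel=0.15)
        assert model.c == pytest.approx(grid_best[2], rel=0.15)

    def test_too_few_points(self):
        with pytest.raises(ConfigurationError):
            fit_calibration([0.1, 1.0, 10.0], [10.0, 50.0, 90.0])

    def test_negative_observed_rejected(self):
        with pytest.raises(DataError):
            fit_calibration([0.1, 1.0, 5.0, 10.0], [10.0, 50.0, -25.0, 90.0])


class TestPredictAndCutoff:
    model = CalibrationModel(a=98.0, b_slope=2.0, c=0.4)

    def test_zero_ris_predicts_zero(self):
        assert predict_auc_change(self.model, 0.0) == 0.0

    def test_half_max_at_c(self):
        assert predict_auc_change(self.model, 0.4) == pytest.approx(49.0)

    def test_no_ris_predicts_zero(self):
        assert predict_auc_change(self.model, None) == 0.0

    def test_cutoff_closed_form(self):
        assert ris_cutoff(self.model, 20.0) == pytest.approx(0.2026, abs=5e-4)

    def test_cutoff_at_half_max_is_c(self):
        assert ris_cutoff(self.model, 49.0) == pytest.approx(0.4, rel=1e-12)

    def test_threshold_above_plateau_raises(self):
        with pytest.raises(ConfigurationError):
            ris_cutoff(CalibrationModel(a=15.0, b_slope=1.0, c=0.1), 20.0)

    @given(
        a=st.floats(25.0, 110.0), b=st.floats(0.3, 6.0), c=st.floats(0.01, 10.0),
        t=st.floats(1.0, 24.0),
    )
    @settings(deadline=None)
    def test_predict_cutoff_round_trip(self, a, b, c, t):
        model = CalibrationModel(a=a, b_slope=b, c=c)
        assert predict_auc_change(model, ris_cutoff(model, t)) == pytest.approx(t, abs=1e-9)

    @given(st.floats(0.001, 100.0), st.floats(1.01, 20.0))
    @settings(deadline=None)
    def test_prediction_increasing_and_bounded(self, ris, factor):
        lo = predict_auc_change(self.model, ris)
        hi = predict_auc_change(self.model, ris * factor)
        assert hi > lo
        assert hi < self.model.a
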