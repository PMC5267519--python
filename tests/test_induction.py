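"""Fold-induction computation, replicate QC and induction classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cypind import (
    ConcentrationSeries,
    DataError,
    ExclusionReason,
    FoldIncreasePoint,
    PipelineConfig,
    Verdict,
    apply_replicate_qc,
    classify_induction,
    fold_increase_points,
    fold_induction_activity,
    fold_induction_mrna,
    replicate_cv,
)


@pytest.mark.parametrize(
    "treated,vehicle,expected",
    [
        ((10, 10, 10), (10, 10, 10), 1.0),
        ((20, 20, 20), (10, 10, 10), 2.0),
        ((9, 10, 11), (4, 5, 6), 2.0),  # mean ratio 10/5
    ],
)
def test_fold_induction_activity(treated, vehicle, expected):
    assert fold_induction_activity(treated, vehicle) == pytest.approx(expected)


def test_fold_induction_activity_rejects_nonpositive_vehicle():
    with pytest.raises(DataError):
        fold_induction_activity((1, 2, 3), (0, 0, 0))


@pytest.mark.parametrize("ddct,expected", [(0.0, 1.0), (-3.0, 8.0), (1.0, 0.5)])
def test_fold_induction_mrna(ddct, expected):
    assert fold_induction_mrna(ddct) == pytest.approx(expected)


@given(a=st.floats(-10, 10), b=st.floats(-10, 10))
def test_mrna_exponential_homomorphism(a, b):
    assert fold_induction_mrna(a + b) == pytest.approx(
        fold_induction_mrna(a) * fold_induction_mrna(b), rel=1e-12
    )


class TestReplicateQC:
    def test_zero_cv_accepted(self):
        pts = [FoldIncreasePoint(1.0, 2.0, replicate_cv((10, 10, 10)))]
        assert apply_replicate_qc(pts)[0].accepted

    def test_cv_half_rejected(self):
        cv = replicate_cv((1, 2, 3))  # sd 1, mean 2
        assert cv == pytest.approx(0.5)
        out = apply_replicate_qc([FoldIncreasePoint(1.0, 2.0, cv)])
        assert not out[0].accepted and out[0].exclusion_reason is ExclusionReason.CV

    def test_two_replicates_allowed(self):
        cv = replicate_cv((9, 11))
        assert cv == pytest.approx(0.1414, abs=1e-4)
        assert apply_replicate_qc([FoldIncreasePoint(1.0, 2.0, cv)])[0].accepted

    def test_upstream_toxicity_reason_preserved(self):
        pts = [FoldIncreasePoint(1.0, 0.1, 0.0, exclusion_reason=ExclusionReason.TOXICITY)]
        out = apply_replicate_qc(pts)
        assert not out[0].accepted and out[0].exclusion_reason is ExclusionReason.TOXICITY

    @given(st.lists(st.floats(0.0, 2.0), min_size=1, max_size=20), st.floats(0.05, 0.40))
    @settings(deadline=None)
    def test_qc_monotone_in_threshold(self, cvs, tighter):
        """Lowering the CV threshold never accepts a previously rejected point."""
        pts = [FoldIncreasePoint(1.0, 2.0, cv) for cv in cvs]
        base = apply_replicate_qc(pts, PipelineConfig(cv_threshold=0.40))
        strict = apply_replicate_qc(pts, PipelineConfig(cv_threshold=tighter))
        for b, s in zip(base, strict):
            if s.accepted:
                assert b.accepted


def _points(folds, accepted=True):
    return [
        FoldIncreasePoint(conc, fi, 0.0, accepted=accepted)
        for conc, fi in zip(np.geomspace(0.01, 50, len(folds)), folds)
    ]


class TestClassification:
    def test_flat_series_negative(self):
        flat = _points([1.0, 1.02, 0.98, 1.01, 0.99, 1.0, 1.02, 0.97])
        call = classify_induction(flat, flat)
        assert call.combined is Verdict.NEGATIVE
        assert not call.fit_eligible["activity"]

    def test_monotone_strong_inducer_positive(self):
        rising = _points([1.1, 1.5, 3.0, 7.0, 13.0, 19.0, 21.5, 22.0])
        call = classify_induction(rising, rising)
        assert call.combined is Verdict.POSITIVE
        assert call.fit_eligible["activity"] and call.fit_eligible["mrna"]

    def test_mrna_only_responder_indeterminate(self):
        # enzyme inhibition masks the activity signal (clotrimazole pattern)
        flat = _points([1.0, 1.01, 0.99, 1.0, 1.0, 0.98, 1.02, 1.0])
        rising = _points([1.2, 2.0, 4.0, 8.0, 12.0, 15.0, 16.5, 17.0])
        call = classify_induction(flat, rising)
        assert call.mrna is Verdict.POSITIVE
        assert call.activity is Verdict.NEGATIVE
        assert call.combined is Verdict.INDETERMINATE

    def test_weak_response_not_fit_eligible(self):
        weak = _points([1.0, 1.05, 1.1, 1.2, 1.25, 1.3, 1.35, 1.38])
        call = classify_induction(weak, weak)
        assert not call.fit_eligible["activity"]


class TestSeriesValidation:
    def test_duplicate_concentrations_rejected(self):
        with pytest.raises(DataError):
            ConcentrationSeries("x", "L1", "activity",
                                points=((1.0, (1, 2, 3)), (1.0, (2, 3, 4))), vehicle=(1, 1, 1))

    def test_single_replicate_rejected(self):
        with pytest.raises(DataError):
            ConcentrationSeries("x", "L1", "activity", points=((1.0, (1.0,)),), vehicle=(1, 1))

    def test_vehicle_self_normalization(self):
        s = ConcentrationSeries(
            "x", "L1", "activity",
            points=((1.0, (100.0, 100.0, 100.0)),), vehicle=(100.0, 100.0, 100.0),
        )
        pts = fold_increase_points(s)
        assert pts[0].fold_induction == pytest.approx(1.0)
        assert pts[0].fold_increase == pytest.approx(0.0)
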