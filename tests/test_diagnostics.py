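"""Contingency metrics, Bayes-rule reconstruction, ROC and cutoffs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovupredict.cycle_data import ValidationError
from ovupredict.diagnostics import (
    ContingencyTable,
    build_contingency,
    diagnostic_metrics,
    format_percent,
    metrics_from_rates,
    roc_curve,
    select_cutoff,
)


def auc_by_pair_counting(scores, truth):
    """Independent oracle: concordant-pair fraction with ties counted 1/2."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestContingency:
    def test_perfect_agreement(self):
        t = build_contingency([1, 1, 0, 0], [1, 1, 0, 0])
        assert (t.tp, t.tn, t.fp, t.fn) == (2, 2, 0, 0)

    def test_disagreement(self):
        t = build_contingency([1, 0], [0, 1])
        assert (t.fn, t.fp) == (1, 1)

    def test_hand_tally(self):
        truth = [1, 1, 1, 1, 0, 0, 0, 0, 0, 1]
        pred = [1, 0, 1, 1, 0, 1, 0, 0, 1, 0]
        t = build_contingency(truth, pred)
        assert (t.tp, t.fn, t.fp, t.tn) == (3, 2, 2, 3)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            build_contingency([1, 0], [1])

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(tp=-1, fp=0, fn=0, tn=1)


class TestDiagnosticMetrics:
    def test_estrogen_decrease_shaped_table(self):
        # balanced-class counts with perfect specificity
        m = diagnostic_metrics(ContingencyTable(tp=56, fn=13, tn=69, fp=0))
        assert m.sensitivity.percent == pytest.approx(81.2, abs=0.05)
        assert m.specificity.percent == 100.0
        assert m.ppv.percent == 100.0

    def test_perfect_predictions(self):
        m = diagnostic_metrics(ContingencyTable(tp=10, fn=0, fp=0, tn=10))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            assert getattr(m, name).point == 1.0

    def test_zero_denominator_flags_metric(self):
        m = diagnostic_metrics(ContingencyTable(tp=0, fp=0, fn=5, tn=5))
        assert not m.ppv.defined and m.ppv.point is None
        assert m.sensitivity.defined and m.npv.defined

    def test_ci_contains_point_and_shrinks(self):
        small = diagnostic_metrics(ContingencyTable(tp=8, fn=2, fp=3, tn=7))
        large = diagnostic_metrics(
            ContingencyTable(tp=800, fn=200, fp=300, tn=700)
        )
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            s, l = getattr(small, name), getattr(large, name)
            assert s.ci_low <= s.point <= s.ci_high
            assert 0.0 <= s.ci_low and s.ci_high <= 1.0
            assert (l.ci_high - l.ci_low) < (s.ci_high - s.ci_low)

    def test_bayes_consistency_with_table_prevalence(self):
        t = ContingencyTable(tp=42, fn=8, fp=11, tn=39)
        m = diagnostic_metrics(t)
        ppv, npv, acc = metrics_from_rates(
            m.sensitivity.point, m.specificity.point, t.prevalence
        )
        assert ppv == pytest.approx(m.ppv.point, abs=1e-12)
        assert npv == pytest.approx(m.npv.point, abs=1e-12)
        assert acc == pytest.approx(m.accuracy.point, abs=1e-12)


class TestMetricsFromRates:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [
            ((0.830), 0.822, (82.3, 82.9, 82.6)),
            (0.915, 0.627, (71.0, 88.1, 77.1)),
        ],
    )
    def test_published_rows_at_balanced_prevalence(self, sens, spec, expected):
        ppv, npv, acc = metrics_from_rates(sens, spec, 0.5)
        assert 100 * ppv == pytest.approx(expected[0], abs=0.05)
        assert 100 * npv == pytest.approx(expected[1], abs=0.05)
        assert 100 * acc == pytest.approx(expected[2], abs=0.05)

    @pytest.mark.parametrize("prevalence", [0.1, 0.5, 0.9])
    def test_perfect_test(self, prevalence):
        assert metrics_from_rates(1.0, 1.0, prevalence) == (1.0, 1.0, 1.0)

    def test_undefined_ppv_at_degenerate_rates(self):
        ppv, npv, acc = metrics_from_rates(0.0, 1.0, 1.0)
        assert ppv is None

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            metrics_from_rates(1.2, 0.5, 0.5)


class TestRocCurve:
    def test_perfect_separation(self):
        curve = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert curve.auc == 1.0

    def test_all_ties(self):
        curve = roc_curve([5, 5, 5, 5], [0, 1, 0, 1])
        assert curve.auc == pytest.approx(0.5)

    def test_partial_separation(self):
        curve = roc_curve([1, 3, 2, 4], [0, 0, 1, 1])
        assert curve.auc == pytest.approx(0.75)

    def test_endpoints_present(self):
        curve = roc_curve([1, 3, 2, 4, 2], [0, 0, 1, 1, 0])
        pts = set(zip(curve.one_minus_specificity, curve.sensitivity))
        assert (0.0, 0.0) in pts and (1.0, 1.0) in pts

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve([1, 2, 3], [1, 1, 1])

    def test_orientation_flag(self):
        # more-negative scores indicate the positive class
        scores = [-60.0, -55.0, 10.0, 20.0]
        truth = [1, 1, 0, 0]
        assert roc_curve(scores, truth, higher_is_positive=False).auc == 1.0

    def test_ci_contains_auc(self):
        curve = roc_curve([1, 3, 2, 4, 5, 0], [0, 0, 1, 1, 1, 0])
        assert curve.auc_ci[0] <= curve.auc <= curve.auc_ci[1]

    @settings(max_examples=120, derandomize=True)
    @given(
        n=st.integers(4, 50),
        seed=st.integers(0, 2**20),
        ties=st.booleans(),
    )
    def test_auc_matches_pair_counting_oracle(self, n, seed, ties):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, n) if ties else rng.normal(size=n)
        truth = rng.integers(0, 2, n)
        if truth.sum() in (0, n):
            truth[0] = 1 - truth[0]
        curve = roc_curve(list(map(float, scores)), list(truth))
        assert curve.auc == pytest.approx(
            auc_by_pair_counting(scores, truth), abs=1e-12
        )

    @settings(max_examples=40, derandomize=True)
    @given(n=st.integers(4, 30), seed=st.integers(0, 2**20))
    def test_auc_invariant_under_monotone_transform(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=n)
        truth = rng.integers(0, 2, n)
        if truth.sum() in (0, n):
            truth[0] = 1 - truth[0]
        base = roc_curve(scores, truth).auc
        assert roc_curve(np.exp(scores), truth).auc == pytest.approx(base)
        assert roc_curve(3.0 * scores + 7.0, truth).auc == pytest.approx(base)


def cutoff_by_exhaustive_scan(scores, truth, criterion):
    """Oracle: evaluate every 'call positive at >= threshold' rule."""
    best = None
    for thr in sorted(set(scores), reverse=True):
        pred = [1 if s >= thr else 0 for s in scores]
        tp = sum(1 for p, t in zip(pred, truth) if p and t)
        fn = sum(1 for p, t in zip(pred, truth) if not p and t)
        fp = sum(1 for p, t in zip(pred, truth) if p and not t)
        tn = sum(1 for p, t in zip(pred, truth) if not p and not t)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        value = sens * spec if criterion == "sens_times_spec" else sens + spec - 1
        key = (value, spec, thr)
        if best is None or key > best[0]:
            best = (key, (thr, sens, spec))
    return best[1]


class TestSelectCutoff:
    def test_perfect_separation_threshold(self):
        curve = roc_curve([1.0, 2.0, 10.0, 11.0], [0, 0, 1, 1])
        thr, sens, spec = select_cutoff(curve)
        assert sens == 1.0 and spec == 1.0
        assert 2.0 < thr <= 10.0

    @pytest.mark.parametrize("criterion", ["sens_times_spec", "youden"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 10])
    def test_matches_exhaustive_scan(self, criterion, seed):
        rng = np.random.default_rng(seed)
        n = 20
        truth = rng.integers(0, 2, n)
        if truth.sum() in (0, n):
            truth[0] = 1 - truth[0]
        scores = np.round(rng.normal(size=n) + truth, 1)
        curve = roc_curve(scores, truth)
        thr, sens, spec = select_cutoff(curve, criterion)
        o_thr, o_sens, o_spec = cutoff_by_exhaustive_scan(
            list(scores), list(truth), criterion
        )
        assert (sens, spec) == pytest.approx((o_sens, o_spec))

    def test_unknown_criterion(self):
        curve = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        with pytest.raises(ValidationError):
            select_cutoff(curve, "accuracy")


def test_format_percent_rounds_half_up():
    assert format_percent(0.8125) == "81.3%"
    assert format_percent(0.81249) == "81.2%"
    assert format_percent(1.0) == "100.0%"
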