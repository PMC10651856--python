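"""The combined decision rule and single-marker predictors."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovupredict.cycle_data import ValidationError
from ovupredict.predictor import (
    DEFAULT_RULE_CONFIG,
    Marker,
    MarkerRule,
    PredictionError,
    PredictionLabel,
    RuleConfig,
    evaluate_marker,
    marker_indicator,
    predict_day,
)

from conftest import make_cycle, make_dataset, make_obs


def present(day=13, lh=20.0, estrogen=1200.0, progesterone=1.5, follicle=17.0):
    return make_obs(
        day, lh=lh, estrogen=estrogen, progesterone=progesterone, follicle=follicle
    )


def absent(day=14, progesterone=4.0, estrogen=400.0, lh=15.0):
    return make_obs(
        day, lh=lh, estrogen=estrogen, progesterone=progesterone, follicle=None
    )


class TestCombinedRule:
    def test_estrogen_drop_with_follicle_predicts_next_day(self):
        result = predict_day(
            present(day=13, estrogen=1100.0), present(day=12, estrogen=1400.0)
        )
        assert result.label is PredictionLabel.DAY_MINUS_1
        assert result.rule_id == "E-DROP"
        assert result.confidence_band == "100%"

    def test_progesterone_and_lh_rescue_rising_estrogen(self):
        result = predict_day(
            present(day=13, estrogen=1500.0, progesterone=2.5, lh=45.0),
            present(day=12, estrogen=1200.0),
        )
        assert result.label is PredictionLabel.DAY_MINUS_1
        assert result.rule_id == "P+LH"
        assert result.confidence_band == "95%"

    def test_quiet_hormones_mean_two_days_or_more(self):
        result = predict_day(
            present(day=13, estrogen=1500.0, progesterone=1.5, lh=20.0),
            present(day=12, estrogen=1200.0),
        )
        assert result.label is PredictionLabel.DAY_MINUS_2_OR_EARLIER
        assert result.confidence_band == "95-99%"

    def test_absent_follicle_low_progesterone_is_rupture_day(self):
        result = predict_day(
            absent(progesterone=4.0), prior_follicle_documented=True
        )
        assert result.label is PredictionLabel.DAY_0
        assert result.confidence_band == "96.6%"

    def test_absent_follicle_overlap_zone_is_indeterminate(self):
        result = predict_day(
            absent(progesterone=7.0), prior_follicle_documented=True
        )
        assert result.label is PredictionLabel.INDETERMINATE

    def test_absent_follicle_high_progesterone_is_later(self):
        result = predict_day(
            absent(progesterone=12.0), prior_follicle_documented=True
        )
        assert result.label is PredictionLabel.DAY_PLUS_1_ONWARD
        assert result.confidence_band == "99%"

    def test_unchanged_estrogen_is_not_a_decrease(self):
        result = predict_day(
            present(day=13, estrogen=1000.0, progesterone=1.0, lh=10.0),
            present(day=12, estrogen=1000.0),
        )
        assert result.label is PredictionLabel.DAY_MINUS_2_OR_EARLIER

    @pytest.mark.parametrize(
        "progesterone,lh,expected",
        [
            (2.0, 40.0, PredictionLabel.DAY_MINUS_1),  # inclusive boundaries
            (1.99, 40.0, PredictionLabel.DAY_MINUS_2_OR_EARLIER),
            (2.0, 39.9, PredictionLabel.DAY_MINUS_2_OR_EARLIER),
        ],
    )
    def test_combined_rule_boundaries(self, progesterone, lh, expected):
        result = predict_day(
            present(estrogen=1500.0, progesterone=progesterone, lh=lh),
            present(day=12, estrogen=1200.0),
        )
        assert result.label is expected

    @pytest.mark.parametrize(
        "progesterone,expected",
        [
            (5.0, PredictionLabel.DAY_0),  # inclusive
            (5.01, PredictionLabel.INDETERMINATE),
            (9.0, PredictionLabel.INDETERMINATE),  # strict upper boundary
            (9.01, PredictionLabel.DAY_PLUS_1_ONWARD),
        ],
    )
    def test_postovulatory_boundaries(self, progesterone, expected):
        result = predict_day(
            absent(progesterone=progesterone), prior_follicle_documented=True
        )
        assert result.label is expected

    def test_estrogen_drop_shadows_combined_rule(self):
        result = predict_day(
            present(day=13, estrogen=1100.0, progesterone=3.0, lh=50.0),
            present(day=12, estrogen=1400.0),
        )
        assert result.rule_id == "E-DROP"

    def test_stale_previous_estrogen_is_flagged_and_skipped(self):
        result = predict_day(
            present(day=13, estrogen=1100.0, progesterone=2.5, lh=45.0),
            present(day=10, estrogen=1400.0),
        )
        assert result.rule_id == "P+LH"
        assert "estrogen_comparison_unavailable" in result.notes

    def test_absent_follicle_without_prior_documentation_errors(self):
        with pytest.raises(PredictionError):
            predict_day(absent(), prior_follicle_documented=False)

    def test_unassessed_follicle_errors(self):
        obs = make_obs(13, follicle=None, assessed=False, estrogen=1000.0)
        with pytest.raises(PredictionError):
            predict_day(obs)

    def test_missing_hormones_error_rather_than_guess(self):
        bare = make_obs(13, follicle=17.0)
        with pytest.raises(PredictionError, match="progesterone|lh"):
            predict_day(bare)

    def test_missing_progesterone_named_in_error(self):
        obs = absent(progesterone=None)
        with pytest.raises(PredictionError, match="progesterone"):
            predict_day(obs, prior_follicle_documented=True)

    @settings(max_examples=50, derandomize=True)
    @given(
        progesterone=st.floats(0.1, 30.0),
        raised_cutoff=st.floats(9.0, 20.0),
    )
    def test_raising_post_cutoff_never_creates_day0(self, progesterone, raised_cutoff):
        base = predict_day(
            absent(progesterone=progesterone), prior_follicle_documented=True
        )
        raised = predict_day(
            absent(progesterone=progesterone),
            config=RuleConfig(progesterone_postovulatory_cutoff=raised_cutoff),
            prior_follicle_documented=True,
        )
        if base.label is PredictionLabel.DAY_PLUS_1_ONWARD:
            assert raised.label in (
                PredictionLabel.DAY_PLUS_1_ONWARD,
                PredictionLabel.INDETERMINATE,
            )

    def test_config_invariants(self):
        with pytest.raises(ValidationError):
            RuleConfig(progesterone_d0_cutoff=10.0)  # above the post cutoff
        with pytest.raises(ValidationError):
            RuleConfig(lh_combined_cutoff=0.0)


class TestMarkerIndicator:
    def test_lh_threshold_is_inclusive(self):
        rule = MarkerRule(Marker.LH_ABS, ">=", 35.0)
        assert marker_indicator(rule, present(lh=35.0)) == 1
        assert marker_indicator(rule, present(lh=34.9)) == 0

    def test_estrogen_tie_is_not_a_decrease(self):
        rule = MarkerRule(Marker.E_CHANGE, "any_decrease")
        assert (
            marker_indicator(
                rule, present(estrogen=1000.0), present(day=12, estrogen=1000.0)
            )
            == 0
        )

    def test_sharp_drop_threshold(self):
        rule = MarkerRule(Marker.E_SHARP_DROP, ">=", 50.0)
        assert (
            marker_indicator(
                rule, present(estrogen=480.0), present(day=12, estrogen=1000.0)
            )
            == 1
        )
        assert (
            marker_indicator(
                rule, present(estrogen=520.0), present(day=12, estrogen=1000.0)
            )
            == 0
        )

    def test_change_marker_requires_previous(self):
        rule = MarkerRule(Marker.E_CHANGE, "any_decrease")
        with pytest.raises(PredictionError):
            marker_indicator(rule, present())

    def test_rule_validation(self):
        with pytest.raises(ValidationError):
            MarkerRule(Marker.LH_ABS, ">=", None)
        with pytest.raises(ValidationError):
            MarkerRule(Marker.E_CHANGE, ">=", 1.0)


def _marker_fixture():
    """8 annotated cycles; progesterone at D(-1) alternates around 2."""
    cycles = []
    prog_m1 = [2.5, 1.0, 3.0, 2.0, 0.5, 4.0, 1.9, 2.1]
    prog_m2 = [1.0, 1.0, 2.5, 0.5, 0.4, 1.8, 2.2, 1.0]
    for i in range(8):
        cycles.append(
            make_cycle(
                [
                    make_obs(11, cycle=f"C{i}", progesterone=0.8,
                             estrogen=900.0, lh=10.0, follicle=15.0),
                    make_obs(12, cycle=f"C{i}", progesterone=prog_m2[i],
                             estrogen=1300.0, lh=20.0, follicle=17.0),
                    make_obs(13, cycle=f"C{i}", progesterone=prog_m1[i],
                             estrogen=1000.0, lh=50.0, follicle=19.0),
                    make_obs(14, cycle=f"C{i}", progesterone=5.0,
                             estrogen=400.0, lh=18.0, follicle=None),
                ],
                ovulation_cycle_day=14,
            )
        )
    return make_dataset(*cycles)


class TestEvaluateMarker:
    def test_hand_tally_on_fixture(self):
        ds = _marker_fixture()
        ev = evaluate_marker(
            ds, MarkerRule(Marker.P_ABS, ">", 2.0), -1, -2
        )
        # D(-1) values > 2: 2.5, 3.0, 4.0, 2.1 -> tp=4, fn=4
        # D(-2) values > 2: 2.5, 2.2 -> fp=2, tn=6
        assert (ev.table.tp, ev.table.fn, ev.table.fp, ev.table.tn) == (4, 4, 2, 6)
        assert ev.metrics.sensitivity.point == pytest.approx(0.5)
        assert ev.metrics.specificity.point == pytest.approx(0.75)

    def test_always_positive_marker(self):
        ds = _marker_fixture()
        ev = evaluate_marker(ds, MarkerRule(Marker.P_ABS, ">=", 0.0), -1, -2)
        assert ev.metrics.sensitivity.point == 1.0
        assert ev.metrics.specificity.point == 0.0

    def test_change_marker_uses_previous_visit(self):
        ds = _marker_fixture()
        ev = evaluate_marker(
            ds, MarkerRule(Marker.E_CHANGE, "any_decrease"), -1, -2
        )
        # estrogen falls into every D(-1) and rises into every D(-2)
        assert ev.metrics.sensitivity.point == 1.0
        assert ev.metrics.specificity.point == 1.0
        assert ev.n_excluded == 0

    def test_visits_without_required_inputs_are_tallied(self):
        # one cycle lacks the visit before D(-2); its D(-2) comparison
        # cannot be formed and is excluded rather than guessed
        with_prior = make_cycle(
            [
                make_obs(11, cycle="A", estrogen=900.0, follicle=15.0),
                make_obs(12, cycle="A", estrogen=1300.0, follicle=17.0),
                make_obs(13, cycle="A", estrogen=1000.0, follicle=19.0),
                make_obs(14, cycle="A", estrogen=400.0, follicle=None),
            ],
            ovulation_cycle_day=14,
        )
        without_prior = make_cycle(
            [
                make_obs(12, cycle="B", estrogen=1300.0, follicle=17.0),
                make_obs(13, cycle="B", estrogen=1000.0, follicle=19.0),
                make_obs(14, cycle="B", estrogen=400.0, follicle=None),
            ],
            ovulation_cycle_day=14,
        )
        ev = evaluate_marker(
            make_dataset(with_prior, without_prior),
            MarkerRule(Marker.E_CHANGE, "any_decrease"),
            -1,
            -2,
        )
        assert ev.n_excluded == 1
        assert ev.table.total == 3

    def test_estrogen_decrease_has_perfect_specificity_on_simulated_data(
        self, cohort_500
    ):
        ev = evaluate_marker(
            cohort_500, MarkerRule(Marker.E_CHANGE, "any_decrease"), -1, -2
        )
        assert ev.metrics.specificity.point == 1.0

    def test_overlapping_offsets_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_marker(
                _marker_fixture(), MarkerRule(Marker.P_ABS, ">", 2.0), -1, -1
            )
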