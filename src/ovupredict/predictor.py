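"""The ovulation-day decision rule and single-marker cutoff predictors.

Given the current visit, the most recent previous visit and follicle
status, the combined rule assigns one of five day labels:

FOLLICLE PRESENT
    1. estrogen strictly below the previous measurement (taken no more
       than ``max_gap_days_for_estrogen_comparison`` days earlier)
       -> ``DAY_MINUS_1`` (rupture expected the next day);
    2. otherwise, progesterone >= 2 nmol/L and LH >= 40 IU/L
       -> ``DAY_MINUS_1``;
    3. otherwise -> ``DAY_MINUS_2_OR_EARLIER``.

FOLLICLE ABSENT (valid only when follicle development was documented
earlier in the cycle)
    4. progesterone <= 5 nmol/L -> ``DAY_0`` (rupture today);
    5. progesterone > 9 nmol/L -> ``DAY_PLUS_1_ONWARD``;
    6. progesterone in (5, 9] nmol/L -> ``INDETERMINATE``.

Each branch carries the certainty figure reported for it in the
development cohort, stored as opaque text.  Single-marker rules (absolute
LH, LH rise, absolute progesterone, any/sharp estrogen decrease) are
evaluated against day-offset contrasts to produce 2x2 diagnostic metrics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .cycle_data import Cycle, CycleObservation, MonitoringDataset, ValidationError
from .diagnostics import ContingencyTable, DiagnosticMetrics, build_contingency, diagnostic_metrics
from .trajectory_stats import relative_change

__all__ = [
    "DEFAULT_RULE_CONFIG",
    "Marker",
    "MarkerEvaluation",
    "MarkerRule",
    "PredictionError",
    "PredictionLabel",
    "PredictionResult",
    "RuleConfig",
    "evaluate_marker",
    "marker_indicator",
    "predict_day",
]


class PredictionError(ValueError):
    """The decision rule cannot be applied to the given inputs."""


class PredictionLabel(str, enum.Enum):
    DAY_MINUS_1 = "DAY_MINUS_1"
    DAY_MINUS_2_OR_EARLIER = "DAY_MINUS_2_OR_EARLIER"
    DAY_0 = "DAY_0"
    DAY_PLUS_1_ONWARD = "DAY_PLUS_1_ONWARD"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds of the combined decision rule (all strictly positive)."""

    lh_combined_cutoff: float = 40.0  # IU/L
    progesterone_preovulatory_cutoff: float = 2.0  # nmol/L
    progesterone_d0_cutoff: float = 5.0  # nmol/L
    progesterone_postovulatory_cutoff: float = 9.0  # nmol/L
    estrogen_sharp_drop_percent: float = 50.0
    max_gap_days_for_estrogen_comparison: int = 2

    def __post_init__(self) -> None:
        for name in (
            "lh_combined_cutoff",
            "progesterone_preovulatory_cutoff",
            "progesterone_d0_cutoff",
            "progesterone_postovulatory_cutoff",
            "estrogen_sharp_drop_percent",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.progesterone_d0_cutoff >= self.progesterone_postovulatory_cutoff:
            raise ValidationError(
                "the D(0) progesterone cutoff must lie below the "
                "post-ovulatory cutoff"
            )
        if self.max_gap_days_for_estrogen_comparison < 1:
            raise ValidationError("max_gap_days_for_estrogen_comparison must be >= 1")


DEFAULT_RULE_CONFIG = RuleConfig()

#: rule_id -> (label, certainty text reported for that branch)
RULE_TABLE: Dict[str, Tuple[PredictionLabel, str]] = {
    "E-DROP": (PredictionLabel.DAY_MINUS_1, "100%"),
    "P+LH": (PredictionLabel.DAY_MINUS_1, "95%"),
    "PRE-SURGE": (PredictionLabel.DAY_MINUS_2_OR_EARLIER, "95-99%"),
    "P-LOW-D0": (PredictionLabel.DAY_0, "96.6%"),
    "P-HIGH-POST": (PredictionLabel.DAY_PLUS_1_ONWARD, "99%"),
    "P-INDETERMINATE": (PredictionLabel.INDETERMINATE, "n/a"),
}


@dataclass(frozen=True)
class PredictionResult:
    label: PredictionLabel
    rule_id: str
    confidence_band: str
    notes: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = RULE_TABLE[self.rule_id]
        if expected[0] is not self.label or expected[1] != self.confidence_band:
            raise ValidationError("label and rule_id are inconsistent")


def _result(rule_id: str, notes: Sequence[str] = ()) -> PredictionResult:
    label, confidence = RULE_TABLE[rule_id]
    return PredictionResult(
        label=label, rule_id=rule_id, confidence_band=confidence, notes=tuple(notes)
    )


def _require(observation: CycleObservation, hormone: str) -> float:
    value = getattr(observation, hormone)
    if value is None:
        raise PredictionError(
            f"{hormone} is required by the rule branch reached but missing "
            f"on cycle_day {observation.cycle_day}"
        )
    return value


def predict_day(
    current: CycleObservation,
    previous: Optional[CycleObservation] = None,
    config: RuleConfig = DEFAULT_RULE_CONFIG,
    prior_follicle_documented: bool = False,
) -> PredictionResult:
    """Apply the combined decision rule at one visit.

    ``previous`` is the most recent earlier visit of the same cycle (used
    only for the estrogen-decrease comparison); ties count as "unchanged",
    not as a decrease.  Exactly one branch fires.
    """
    if not current.follicle_assessed:
        raise PredictionError(
            "follicle status was not assessed at this visit; the rule needs it"
        )
    notes: List[str] = []
    if current.follicle_present:
        comparison_ok = (
            previous is not None
            and previous.estrogen is not None
            and current.estrogen is not None
            and previous.cycle_day < current.cycle_day
            and current.cycle_day - previous.cycle_day
            <= config.max_gap_days_for_estrogen_comparison
        )
        if not comparison_ok:
            notes.append("estrogen_comparison_unavailable")
        elif current.estrogen < previous.estrogen:
            return _result("E-DROP", notes)
        progesterone = _require(current, "progesterone")
        lh = _require(current, "lh")
        if (
            progesterone >= config.progesterone_preovulatory_cutoff
            and lh >= config.lh_combined_cutoff
        ):
            return _result("P+LH", notes)
        return _result("PRE-SURGE", notes)

    if not prior_follicle_documented:
        raise PredictionError(
            "follicle ABSENT without documented earlier follicle development; "
            "the rule is inapplicable"
        )
    progesterone = _require(current, "progesterone")
    if progesterone <= config.progesterone_d0_cutoff:
        return _result("P-LOW-D0", notes)
    if progesterone > config.progesterone_postovulatory_cutoff:
        return _result("P-HIGH-POST", notes)
    return _result("P-INDETERMINATE", notes)


# ---------------------------------------------------------------------------
# Single-marker rules
# ---------------------------------------------------------------------------

class Marker(str, enum.Enum):
    LH_ABS = "LH_abs"
    LH_CHANGE = "LH_change"
    P_ABS = "P_abs"
    E_CHANGE = "E_change"  # any strict decrease
    E_SHARP_DROP = "E_sharp_drop"  # relative change <= -threshold


_COMPARATORS = (">=", ">", "<=", "any_decrease")


@dataclass(frozen=True)
class MarkerRule:
    """A thresholded single-marker predictor for a day contrast."""

    marker: Marker
    comparator: str = ">="
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ValidationError(f"comparator must be one of {_COMPARATORS}")
        needs_threshold = self.marker in (
            Marker.LH_ABS,
            Marker.LH_CHANGE,
            Marker.P_ABS,
            Marker.E_SHARP_DROP,
        )
        if needs_threshold and self.threshold is None:
            raise ValidationError(f"{self.marker.value} requires a threshold")
        if self.marker is Marker.E_CHANGE and self.comparator != "any_decrease":
            raise ValidationError("E_change uses the any_decrease comparator")

    @property
    def needs_previous(self) -> bool:
        return self.marker in (Marker.LH_CHANGE, Marker.E_CHANGE, Marker.E_SHARP_DROP)

    def describe(self) -> str:
        if self.marker is Marker.E_CHANGE:
            return "any decrease in estrogen"
        if self.marker is Marker.E_SHARP_DROP:
            return f"estrogen drop >= {self.threshold}%"
        if self.marker is Marker.LH_CHANGE:
            return f"LH rise {self.comparator} {self.threshold}%"
        name = "LH" if self.marker is Marker.LH_ABS else "progesterone"
        return f"{name} {self.comparator} {self.threshold}"


def _compare(value: float, comparator: str, threshold: float) -> bool:
    if comparator == ">=":
        return value >= threshold
    if comparator == ">":
        return value > threshold
    if comparator == "<=":
        return value <= threshold
    raise ValidationError(f"comparator {comparator!r} needs a threshold rule")


def marker_indicator(
    rule: MarkerRule,
    current: CycleObservation,
    previous: Optional[CycleObservation] = None,
) -> int:
    """1 iff the marker condition holds at ``current``."""
    if rule.needs_previous and previous is None:
        raise PredictionError(
            f"{rule.marker.value} needs the previous observation"
        )
    if rule.marker is Marker.LH_ABS:
        return int(_compare(_require(current, "lh"), rule.comparator, rule.threshold))
    if rule.marker is Marker.P_ABS:
        return int(
            _compare(_require(current, "progesterone"), rule.comparator, rule.threshold)
        )
    if rule.marker is Marker.LH_CHANGE:
        change = relative_change(
            _require(current, "lh"), _require(previous, "lh")
        )
        return int(_compare(change, rule.comparator, rule.threshold))
    prev_e = _require(previous, "estrogen")
    cur_e = _require(current, "estrogen")
    if rule.marker is Marker.E_CHANGE:
        return int(cur_e < prev_e)
    # sharp drop: relative change at or below -threshold percent
    return int(relative_change(cur_e, prev_e) <= -float(rule.threshold))


@dataclass(frozen=True)
class MarkerEvaluation:
    rule: MarkerRule
    table: ContingencyTable
    metrics: DiagnosticMetrics
    n_excluded: int


def _previous_visit(
    cycle: Cycle, observation: CycleObservation
) -> Optional[CycleObservation]:
    prev = None
    for o in cycle.observations:
        if o.cycle_day >= observation.cycle_day:
            break
        prev = o
    return prev


def evaluate_marker(
    dataset: MonitoringDataset,
    rule: MarkerRule,
    positive_offset: Union[int, Sequence[int]],
    negative_offset: Union[int, Sequence[int]],
) -> MarkerEvaluation:
    """2x2 evaluation of a marker over two sets of day offsets.

    Every observation of an annotated cycle at a positive offset counts as
    condition-present, at a negative offset as condition-absent.  Visits
    lacking the marker's inputs (including a missing previous visit for
    change markers) are excluded and tallied.
    """
    pos = (positive_offset,) if isinstance(positive_offset, int) else tuple(positive_offset)
    neg = (negative_offset,) if isinstance(negative_offset, int) else tuple(negative_offset)
    if set(pos) & set(neg):
        raise ValidationError("positive and negative offsets overlap")
    truth: List[int] = []
    predicted: List[int] = []
    n_excluded = 0
    for cycle in dataset.annotated_cycles:
        for offset, is_positive in [(o, 1) for o in pos] + [(o, 0) for o in neg]:
            obs = cycle.observation_at_offset(offset)
            if obs is None:
                continue
            previous = _previous_visit(cycle, obs) if rule.needs_previous else None
            try:
                indicator = marker_indicator(rule, obs, previous)
            except (PredictionError, ValidationError):
                n_excluded += 1
                continue
            truth.append(is_positive)
            predicted.append(indicator)
    if not truth or len(set(truth)) < 2:
        raise ValidationError(
            "marker evaluation needs observations in both day classes "
            "after exclusions"
        )
    table = build_contingency(truth, predicted)
    return MarkerEvaluation(
        rule=rule,
        table=table,
        metrics=diagnostic_metrics(table),
        n_excluded=n_excluded,
    )


def load_rule_config(path) -> RuleConfig:
    """Read a flat ``key=value`` threshold config."""
    values = {}
    with open(path, "r", encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"malformed config line: {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key == "max_gap_days_for_estrogen_comparison":
                values[key] = int(value)
            elif key in RuleConfig.__dataclass_fields__:
                values[key] = float(value)
            # unknown keys may belong to the simulator config; ignore them
    return RuleConfig(**values)
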