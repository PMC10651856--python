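"""End-to-end validation harness and full-report generator.

Reproduces the retrospective validation design on (synthetic) cohorts:
apply the combined decision rule at the true D(-1) visit of every eligible
cycle (pre-ovulatory validation) and at the true D(0) visit
(post-ovulatory validation, where progesterone in (5, 9] nmol/L yields an
indeterminate call), and report the resulting accuracies and the
indeterminate fraction.  ``run_full_report`` orchestrates simulation,
descriptive summaries, marker evaluations, ROC analysis, the
balanced-prevalence consistency check of the published cutoff table, and
the validation reports, writing everything as CSV/JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd

from .cycle_data import (
    Cycle,
    MonitoringDataset,
    ValidationError,
    write_monitoring_csv,
)
from .diagnostics import metrics_from_rates, roc_curve
from .predictor import (
    DEFAULT_RULE_CONFIG,
    Marker,
    MarkerRule,
    PredictionError,
    PredictionLabel,
    RuleConfig,
    evaluate_marker,
    predict_day,
)
from .reference import REPORTED_RULES
from .synthetic_cycles import SimulationParams, simulate_cohort
from .trajectory_stats import (
    MEASURES,
    per_day_summary,
    relative_change,
    relative_change_summary,
    summaries_to_frame,
)

__all__ = [
    "PostovulatoryValidation",
    "PreovulatoryValidation",
    "ReportBundle",
    "ValidationReport",
    "estrogen_drop_rupture_concordance",
    "run_full_report",
    "validate_postovulatory",
    "validate_preovulatory",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreovulatoryValidation:
    """Outcome of applying the rule at every eligible true D(-1) visit."""

    n_eligible: int
    n_correct: int
    n_repeat_test_needed: int  # rule-3 firings at the true D(-1)
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_eligible:
            raise ValidationError("correct count exceeds eligible count")
        if not 0 <= self.n_repeat_test_needed <= self.n_eligible:
            raise ValidationError("repeat-test count exceeds eligible count")

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * self.n_correct / self.n_eligible


@dataclass(frozen=True)
class PostovulatoryValidation:
    """Outcome of applying the rule at every eligible true D(0) visit."""

    n_eligible: int
    n_indeterminate: int
    n_determinate_correct: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.n_indeterminate > self.n_eligible:
            raise ValidationError("indeterminate count exceeds eligible count")
        if self.n_determinate_correct > self.n_eligible - self.n_indeterminate:
            raise ValidationError("correct count exceeds determinate count")

    @property
    def n_determinate(self) -> int:
        return self.n_eligible - self.n_indeterminate

    @property
    def indeterminate_percent(self) -> float:
        return 100.0 * self.n_indeterminate / self.n_eligible

    @property
    def accuracy_percent(self) -> float:
        if self.n_determinate == 0:
            raise ValidationError("no determinate cases")
        return 100.0 * self.n_determinate_correct / self.n_determinate


@dataclass(frozen=True)
class ValidationReport:
    preovulatory: PreovulatoryValidation
    postovulatory: PostovulatoryValidation


def _eligible_preovulatory(cycle: Cycle) -> bool:
    if not cycle.annotated:
        return False
    d0 = cycle.observation_at_offset(0)
    dm1 = cycle.observation_at_offset(-1)
    return d0 is not None and dm1 is not None and d0.follicle_absent


def validate_preovulatory(
    dataset: MonitoringDataset, config: RuleConfig = DEFAULT_RULE_CONFIG
) -> PreovulatoryValidation:
    """Apply the rule at the true D(-1) of every fully documented cycle.

    A prediction is correct iff the label is ``DAY_MINUS_1``.  Cycles where
    the fall-through branch fires (``DAY_MINUS_2_OR_EARLIER`` at the true
    D(-1)) are additionally tallied as needing a repeat test the next day.
    Visits the rule cannot process (missing hormones) are excluded.
    """
    n_eligible = n_correct = n_repeat = n_excluded = 0
    for cycle in dataset.annotated_cycles:
        if not _eligible_preovulatory(cycle):
            continue
        current = cycle.observation_at_offset(-1)
        previous = None
        for o in cycle.observations:
            if o.cycle_day >= current.cycle_day:
                break
            previous = o
        try:
            result = predict_day(
                current, previous, config, prior_follicle_documented=True
            )
        except PredictionError:
            n_excluded += 1
            continue
        n_eligible += 1
        if result.label is PredictionLabel.DAY_MINUS_1:
            n_correct += 1
        elif result.label is PredictionLabel.DAY_MINUS_2_OR_EARLIER:
            n_repeat += 1
    if n_eligible == 0:
        raise ValidationError("no eligible cycles for pre-ovulatory validation")
    logger.info(
        "pre-ovulatory validation: %d eligible, %d correct, %d repeat, %d excluded",
        n_eligible, n_correct, n_repeat, n_excluded,
    )
    return PreovulatoryValidation(
        n_eligible=n_eligible,
        n_correct=n_correct,
        n_repeat_test_needed=n_repeat,
        n_excluded=n_excluded,
    )


def validate_postovulatory(
    dataset: MonitoringDataset, config: RuleConfig = DEFAULT_RULE_CONFIG
) -> PostovulatoryValidation:
    """Apply the rule at the true D(0) (follicle newly ABSENT) visit.

    Tallies the indeterminate fraction (progesterone in the (5, 9] nmol/L
    zone) and, among determinate calls, the fraction labelled ``DAY_0``.
    """
    n_eligible = n_indet = n_correct = n_excluded = 0
    for cycle in dataset.annotated_cycles:
        current = cycle.observation_at_offset(0)
        if current is None or not current.follicle_absent:
            continue
        try:
            result = predict_day(
                current, None, config, prior_follicle_documented=True
            )
        except PredictionError:
            n_excluded += 1
            continue
        n_eligible += 1
        if result.label is PredictionLabel.INDETERMINATE:
            n_indet += 1
        elif result.label is PredictionLabel.DAY_0:
            n_correct += 1
    if n_eligible == 0:
        raise ValidationError("no eligible cases for post-ovulatory validation")
    logger.info(
        "post-ovulatory validation: %d eligible, %d indeterminate, %d correct, "
        "%d excluded",
        n_eligible, n_indet, n_correct, n_excluded,
    )
    return PostovulatoryValidation(
        n_eligible=n_eligible,
        n_indeterminate=n_indet,
        n_determinate_correct=n_correct,
        n_excluded=n_excluded,
    )


def estrogen_drop_rupture_concordance(
    dataset: MonitoringDataset,
) -> Tuple[int, int, Optional[float]]:
    """How often a follicle-present estrogen decrease precedes rupture.

    Scans consecutive visit pairs of every cycle for visits where the
    follicle is present and estrogen fell strictly below the previous
    visit's value, then checks whether the *next* visit shows follicle
    ABSENT.  Returns ``(n_events, n_followed_by_rupture, percent)``;
    events at the last visit of a cycle cannot be evaluated and are not
    counted.
    """
    n_events = n_followed = 0
    for cycle in dataset.cycles:
        obs = cycle.observations
        for i in range(1, len(obs) - 1):
            prev_o, cur_o, next_o = obs[i - 1], obs[i], obs[i + 1]
            if not cur_o.follicle_present:
                continue
            if prev_o.estrogen is None or cur_o.estrogen is None:
                continue
            if cur_o.estrogen < prev_o.estrogen:
                n_events += 1
                if next_o.follicle_absent:
                    n_followed += 1
    percent = 100.0 * n_followed / n_events if n_events else None
    return n_events, n_followed, percent


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

#: Hormone/day-pair layout of the relative-change table.
_CHANGE_PAIRS = ((-3, -2), (-2, -1), (-1, 0), (-3, -1), (-2, 0))


@dataclass(frozen=True)
class ReportBundle:
    dataset: MonitoringDataset
    per_day: pd.DataFrame
    relative_changes: pd.DataFrame
    marker_metrics: pd.DataFrame
    roc_auc: pd.DataFrame
    reference_consistency: pd.DataFrame
    validation: ValidationReport
    drop_rupture_concordance: Tuple[int, int, Optional[float]]


def _metric_row(name: str, est) -> Dict[str, Optional[float]]:
    return {
        f"{name}": None if est.point is None else 100.0 * est.point,
        f"{name}_ci_low": None if est.ci_low is None else 100.0 * est.ci_low,
        f"{name}_ci_high": None if est.ci_high is None else 100.0 * est.ci_high,
    }


def _roc_scores(dataset: MonitoringDataset):
    """Score sets for the D(-1) and D(0) discrimination analyses."""
    configs = [
        # (label, hormone accessor, positive offset, negative offset, higher_is_positive, use_change)
        ("lh_abs_dm1", "lh", -1, -2, True, False),
        ("estrogen_abs_dm1", "estrogen", -1, -2, True, False),
        ("progesterone_abs_dm1", "progesterone", -1, -2, True, False),
        ("estrogen_change_dm1", "estrogen", -1, -2, False, True),
        ("progesterone_abs_d0", "progesterone", 0, -1, True, False),
    ]
    for label, hormone, pos, neg, higher, use_change in configs:
        scores, truth = [], []
        for cycle in dataset.annotated_cycles:
            for offset, is_pos in ((pos, 1), (neg, 0)):
                obs = cycle.observation_at_offset(offset)
                if obs is None:
                    continue
                value = getattr(obs, hormone)
                if value is None:
                    continue
                if use_change:
                    prev = cycle.observation_at_offset(offset - 1)
                    if prev is None or getattr(prev, hormone) in (None, 0):
                        continue
                    value = relative_change(value, getattr(prev, hormone))
                scores.append(value)
                truth.append(is_pos)
        if truth and 0 < sum(truth) < len(truth):
            yield label, roc_curve(scores, truth, higher_is_positive=higher)


def run_full_report(
    params: SimulationParams,
    n_cycles: int,
    config: RuleConfig,
    rng_seed: int,
    out_dir: Optional[Union[str, os.PathLike]] = None,
) -> ReportBundle:
    """Simulate a cohort and compute every report section; optionally
    write the sections as CSV/JSON files under ``out_dir``.

    Deterministic given ``(params, n_cycles, config, rng_seed)``.
    """
    logger.info("report: n_cycles=%d seed=%d", n_cycles, rng_seed)
    dataset = simulate_cohort(params, n_cycles, rng_seed)

    per_day_rows = []
    for measure in MEASURES:
        per_day_rows.extend(per_day_summary(dataset, measure))
    per_day = summaries_to_frame(per_day_rows)

    change_rows = []
    for hormone in ("lh", "estrogen", "progesterone"):
        for from_day, to_day in _CHANGE_PAIRS:
            try:
                s = relative_change_summary(dataset, hormone, from_day, to_day)
            except ValidationError:
                continue
            change_rows.append(
                {
                    "hormone": hormone,
                    "from_day": from_day,
                    "to_day": to_day,
                    "n_pairs": s.n_pairs,
                    "mean_percent_change": s.mean_percent_change,
                    "sem_percent_change": s.sem_percent_change,
                }
            )
    relative_changes = pd.DataFrame(change_rows)

    marker_rows = []
    for ref in REPORTED_RULES:
        try:
            ev = evaluate_marker(
                dataset, ref.rule, ref.positive_offsets, ref.negative_offsets
            )
        except ValidationError:
            continue
        row = {
            "rule": ref.name,
            "description": ref.rule.describe(),
            "tp": ev.table.tp,
            "fp": ev.table.fp,
            "fn": ev.table.fn,
            "tn": ev.table.tn,
            "n_excluded": ev.n_excluded,
        }
        for metric in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            row.update(_metric_row(metric, getattr(ev.metrics, metric)))
        marker_rows.append(row)
    marker_metrics = pd.DataFrame(marker_rows)

    roc_rows = [
        {
            "score": label,
            "auc": curve.auc,
            "auc_ci_low": curve.auc_ci[0],
            "auc_ci_high": curve.auc_ci[1],
            "n_positive": curve.n_positive,
            "n_negative": curve.n_negative,
        }
        for label, curve in _roc_scores(dataset)
    ]
    roc_auc = pd.DataFrame(roc_rows)

    consistency_rows = []
    for ref in REPORTED_RULES:
        ppv, npv, acc = metrics_from_rates(
            ref.sensitivity / 100.0, ref.specificity / 100.0, prevalence=0.5
        )
        consistency_rows.append(
            {
                "rule": ref.name,
                "reported_ppv": ref.ppv,
                "recomputed_ppv": 100.0 * ppv,
                "reported_npv": ref.npv,
                "recomputed_npv": 100.0 * npv,
                "reported_accuracy": ref.accuracy,
                "recomputed_accuracy": 100.0 * acc,
            }
        )
    reference_consistency = pd.DataFrame(consistency_rows)

    report = ValidationReport(
        preovulatory=validate_preovulatory(dataset, config),
        postovulatory=validate_postovulatory(dataset, config),
    )
    concordance = estrogen_drop_rupture_concordance(dataset)

    bundle = ReportBundle(
        dataset=dataset,
        per_day=per_day,
        relative_changes=relative_changes,
        marker_metrics=marker_metrics,
        roc_auc=roc_auc,
        reference_consistency=reference_consistency,
        validation=report,
        drop_rupture_concordance=concordance,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir), params, config, n_cycles, rng_seed)
    return bundle


def _write_bundle(
    bundle: ReportBundle,
    out_dir: Path,
    params: SimulationParams,
    config: RuleConfig,
    n_cycles: int,
    rng_seed: int,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_monitoring_csv(bundle.dataset, out_dir / "cohort.csv")
    bundle.per_day.to_csv(out_dir / "per_day_summary.csv", index=False)
    bundle.relative_changes.to_csv(out_dir / "relative_changes.csv", index=False)
    bundle.marker_metrics.to_csv(out_dir / "marker_metrics.csv", index=False)
    bundle.roc_auc.to_csv(out_dir / "roc_auc.csv", index=False)
    bundle.reference_consistency.to_csv(
        out_dir / "reference_consistency.csv", index=False
    )
    pre, post = bundle.validation.preovulatory, bundle.validation.postovulatory
    n_events, n_followed, percent = bundle.drop_rupture_concordance
    payload = {
        "seed": rng_seed,
        "n_cycles": n_cycles,
        "params_digest": params.digest(),
        "rule_config": dataclasses.asdict(config),
        "preovulatory": {
            "n_eligible": pre.n_eligible,
            "n_correct": pre.n_correct,
            "accuracy_percent": pre.accuracy_percent,
            "n_repeat_test_needed": pre.n_repeat_test_needed,
            "n_excluded": pre.n_excluded,
        },
        "postovulatory": {
            "n_eligible": post.n_eligible,
            "n_indeterminate": post.n_indeterminate,
            "indeterminate_percent": post.indeterminate_percent,
            "n_determinate_correct": post.n_determinate_correct,
            "determinate_accuracy_percent": post.accuracy_percent,
            "n_excluded": post.n_excluded,
        },
        "estrogen_drop_rupture_concordance": {
            "n_events": n_events,
            "n_followed_by_rupture": n_followed,
            "percent": percent,
        },
    }
    with open(out_dir / "validation.json", "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")
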