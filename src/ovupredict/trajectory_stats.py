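"""Descriptive statistics for periovulatory trajectories.

Per-day summaries (mean ± SEM with range), within-cycle relative-change
statistics between test days, and box-plot five-number summaries with
1.5x/3x IQR outlier fences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cycle_data import (
    CycleObservation,
    MonitoringDataset,
    ValidationError,
    to_day_offsets,
)

__all__ = [
    "FiveNumberSummary",
    "MEASURES",
    "PerDaySummary",
    "RelativeChangeSummary",
    "boxplot_summary",
    "per_day_summary",
    "relative_change",
    "relative_change_summary",
    "summaries_to_frame",
]

logger = logging.getLogger(__name__)

#: Measures addressable in per-day summaries, mapped to observation fields.
MEASURES: Dict[str, str] = {
    "lh": "lh",
    "estrogen": "estrogen",
    "progesterone": "progesterone",
    "endometrium": "endometrium_mm",
}


@dataclass(frozen=True)
class PerDaySummary:
    measure: str
    day_offset: int
    n: int
    mean: float
    sem: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("per-day summary needs n >= 1")
        if not (self.min <= self.mean <= self.max) or self.sem < 0:
            raise ValidationError("inconsistent per-day summary")


@dataclass(frozen=True)
class RelativeChangeSummary:
    hormone: str
    from_day: int
    to_day: int
    n_pairs: int
    mean_percent_change: float
    sem_percent_change: float


@dataclass(frozen=True)
class FiveNumberSummary:
    min: float
    q1: float
    median: float
    q3: float
    max: float
    outliers: Tuple[float, ...]
    extremes: Tuple[float, ...]


def relative_change(value_t: float, value_prev: float) -> float:
    """Signed percent change 100 * (v_t - v_prev) / v_prev.

    The previous value anchors the denominator, so a fall from 1000 to 800
    is -20% and the statistic is invariant under rescaling both values.
    """
    if value_prev <= 0:
        raise ValidationError(
            f"relative change needs a positive previous value, got {value_prev}"
        )
    return 100.0 * (value_t - value_prev) / value_prev


def _mean_sem(values: Sequence[float], context: str) -> Tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if arr.size == 1:
        logger.warning("SEM reported as 0 for n=1 in %s", context)
        return mean, 0.0
    return mean, float(arr.std(ddof=1) / np.sqrt(arr.size))


def per_day_summary(
    dataset: MonitoringDataset, measure: str
) -> Tuple[PerDaySummary, ...]:
    """One summary row per day offset with at least one non-missing value.

    Only annotated cycles contribute (alignment needs a D(0) anchor);
    missing values are excluded cell-wise.  SEM uses the n-1 sd and is
    reported as 0 at n = 1 with a logged warning.
    """
    if measure not in MEASURES:
        raise ValidationError(f"unknown measure {measure!r}; one of {sorted(MEASURES)}")
    attr = MEASURES[measure]
    cycles = dataset.annotated_cycles
    if not cycles:
        raise ValidationError("per_day_summary needs at least one annotated cycle")
    per_day: Dict[int, List[float]] = {}
    for cycle in cycles:
        for rec in to_day_offsets(cycle):
            value = getattr(rec.observation, attr)
            if value is not None:
                per_day.setdefault(rec.day_offset, []).append(float(value))
    rows = []
    for day in sorted(per_day):
        values = per_day[day]
        mean, sem = _mean_sem(values, f"{measure} D({day:+d})")
        rows.append(
            PerDaySummary(
                measure=measure,
                day_offset=day,
                n=len(values),
                mean=mean,
                sem=sem,
                min=min(values),
                max=max(values),
            )
        )
    return tuple(rows)


def relative_change_summary(
    dataset: MonitoringDataset, hormone: str, from_day: int, to_day: int
) -> RelativeChangeSummary:
    """Mean ± SEM of within-cycle percent changes between two day offsets.

    Changes are computed per pair and then averaged (not as a ratio of
    day means), over every annotated cycle contributing both days.
    """
    if to_day <= from_day:
        raise ValidationError("to_day must be after from_day")
    if hormone not in ("lh", "estrogen", "progesterone"):
        raise ValidationError(f"unknown hormone {hormone!r}")
    changes = []
    for cycle in dataset.annotated_cycles:
        earlier = cycle.observation_at_offset(from_day)
        later = cycle.observation_at_offset(to_day)
        if earlier is None or later is None:
            continue
        v_prev = getattr(earlier, hormone)
        v_t = getattr(later, hormone)
        if v_prev is None or v_t is None or v_prev <= 0:
            continue
        changes.append(relative_change(v_t, v_prev))
    if not changes:
        raise ValidationError(
            f"no qualifying {hormone} pairs between D({from_day:+d}) and "
            f"D({to_day:+d})"
        )
    mean, sem = _mean_sem(changes, f"{hormone} change D({from_day:+d})->D({to_day:+d})")
    return RelativeChangeSummary(
        hormone=hormone,
        from_day=from_day,
        to_day=to_day,
        n_pairs=len(changes),
        mean_percent_change=mean,
        sem_percent_change=sem,
    )


def boxplot_summary(
    values: Sequence[float], convention: str = "linear"
) -> FiveNumberSummary:
    """Five-number summary with inclusive 1.5x/3x IQR fences.

    ``convention`` selects the quartile rule: ``"linear"`` interpolates
    between order statistics (the common statistical-package default);
    ``"spss"`` uses the weighted-average (n+1)p definition.  Values at or
    beyond 1.5 IQR outside the quartiles are outliers; at or beyond 3 IQR,
    extremes (a subset of the outliers).
    """
    if len(values) == 0:
        raise ValidationError("boxplot_summary needs at least one value")
    methods = {"linear": "linear", "spss": "weibull"}
    if convention not in methods:
        raise ValidationError(f"unknown quartile convention {convention!r}")
    arr = np.asarray(sorted(values), dtype=float)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method=methods[convention])
    iqr = q3 - q1
    out_lo, out_hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    ext_lo, ext_hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    if iqr > 0:
        outliers = tuple(float(v) for v in arr if v <= out_lo or v >= out_hi)
        extremes = tuple(float(v) for v in arr if v <= ext_lo or v >= ext_hi)
    else:
        # zero IQR: the inclusive fences collapse onto the quartiles; only
        # values away from the (degenerate) box are flagged
        outliers = tuple(float(v) for v in arr if v != q1)
        extremes = outliers
    return FiveNumberSummary(
        min=float(arr[0]),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(arr[-1]),
        outliers=outliers,
        extremes=extremes,
    )


def summaries_to_frame(rows: Sequence[PerDaySummary]) -> pd.DataFrame:
    """Long-format table (measure, day, n, mean, sem, min, max)."""
    return pd.DataFrame(
        [
            {
                "measure": r.measure,
                "day_offset": r.day_offset,
                "n": r.n,
                "mean": r.mean,
                "sem": r.sem,
                "min": r.min,
                "max": r.max,
            }
            for r in rows
        ]
    )
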