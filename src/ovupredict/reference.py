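"""Published operating characteristics of the single-marker cutoff rules.

These are the development-cohort values (percent, one decimal as printed)
for each marker rule, used for the internal-consistency reconstruction:
under balanced day classes, PPV, NPV and accuracy recomputed from a row's
sensitivity and specificity by Bayes' rule should reproduce the printed
values.  They are reference constants, not package outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .predictor import Marker, MarkerRule

__all__ = ["ReportedRule", "REPORTED_RULES"]


@dataclass(frozen=True)
class ReportedRule:
    name: str
    rule: MarkerRule
    #: (positive day offsets, comparison day offsets) of the contrast
    positive_offsets: Tuple[int, ...]
    negative_offsets: Tuple[int, ...]
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


#: Pre-ovulatory rows contrast D(-1) against D(-2); the low-progesterone
#: row contrasts D(0) against D(-1); the high-progesterone row contrasts
#: D(+1)/D(+2) against D(0).
REPORTED_RULES: Tuple[ReportedRule, ...] = (
    ReportedRule(
        name="any_estrogen_decrease",
        rule=MarkerRule(Marker.E_CHANGE, comparator="any_decrease"),
        positive_offsets=(-1,),
        negative_offsets=(-2,),
        sensitivity=81.2,
        specificity=100.0,
        ppv=100.0,
        npv=84.2,
        accuracy=90.6,
    ),
    ReportedRule(
        name="lh_ge_35",
        rule=MarkerRule(Marker.LH_ABS, ">=", 35.0),
        positive_offsets=(-1,),
        negative_offsets=(-2,),
        sensitivity=83.0,
        specificity=82.2,
        ppv=82.3,
        npv=82.9,
        accuracy=82.6,
    ),
    ReportedRule(
        name="lh_ge_60",
        rule=MarkerRule(Marker.LH_ABS, ">=", 60.0),
        positive_offsets=(-1,),
        negative_offsets=(-2,),
        sensitivity=29.7,
        specificity=100.0,
        ppv=100.0,
        npv=58.7,
        accuracy=64.8,
    ),
    ReportedRule(
        name="lh_rise_ge_100",
        rule=MarkerRule(Marker.LH_CHANGE, ">=", 100.0),
        positive_offsets=(-1,),
        negative_offsets=(-2,),
        sensitivity=65.0,
        specificity=52.4,
        ppv=57.7,
        npv=60.0,
        accuracy=58.7,
    ),
    ReportedRule(
        name="lh_rise_ge_200",
        rule=MarkerRule(Marker.LH_CHANGE, ">=", 200.0),
        positive_offsets=(-1,),
        negative_offsets=(-2,),
        sensitivity=39.7,
        specificity=85.7,
        ppv=73.5,
        npv=58.7,
        accuracy=62.7,
    ),
    ReportedRule(
        name="progesterone_gt_2",
        rule=MarkerRule(Marker.P_ABS, ">", 2.0),
        positive_offsets=(-1,),
        negative_offsets=(-2,),
        sensitivity=91.5,
        specificity=62.7,
        ppv=71.0,
        npv=88.1,
        accuracy=77.1,
    ),
    ReportedRule(
        name="progesterone_le_5",
        rule=MarkerRule(Marker.P_ABS, "<=", 5.0),
        positive_offsets=(0,),
        negative_offsets=(-1,),
        sensitivity=55.0,
        specificity=96.6,
        ppv=94.2,
        npv=68.3,
        accuracy=75.8,
    ),
    ReportedRule(
        name="progesterone_ge_9_post",
        rule=MarkerRule(Marker.P_ABS, ">=", 9.0),
        positive_offsets=(1, 2),
        negative_offsets=(0,),
        sensitivity=91.5,
        specificity=62.7,
        ppv=71.0,
        npv=88.1,
        accuracy=77.15,
    ),
)
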