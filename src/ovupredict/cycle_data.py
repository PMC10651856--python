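"""Data model for longitudinal ovulation-monitoring cycles.

A *cycle* is an ordered sequence of monitoring visits.  Each visit records
serum LH (IU/L), estrogen (pmol/L) and progesterone (nmol/L), the leading
follicle diameter on transvaginal ultrasound (mm) and endometrial thickness
(mm).  Day 1 of a cycle is the onset of menstrual bleeding.  The ovulation
day D(0) is defined operationally as the first monitoring day on which a
previously documented leading follicle is no longer visualized (follicular
rupture); days are then re-expressed as signed offsets D(-3)..D(+3) around
that anchor.

The follicle field carries three states:

* **present** -- a positive diameter in mm;
* **ABSENT**  -- ultrasound was performed and no leading follicle was seen
  (the rupture signal);
* **not assessed** -- no usable follicle reading at that visit.

CSV I/O uses the fixed header
``participant_id,cycle_id,cycle_day,lh_iu_l,estrogen_pmol_l,progesterone_nmol_l,follicle_mm,endometrium_mm``
with an empty ``follicle_mm`` meaning ABSENT when an earlier visit in the
same cycle visualized a follicle (otherwise "not assessed"), and the literal
``NA`` always meaning "not assessed".
"""

from __future__ import annotations

import csv

import os
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence, TextIO, Tuple, Union

__all__ = [
    "CSV_HEADER",
    "Cycle",
    "CycleObservation",
    "DayOffsetObservation",
    "MonitoringDataset",
    "ParseError",
    "ValidationError",
    "annotate_ovulation_day",
    "pair_consecutive_tests",
    "read_monitoring_csv",
    "to_day_offsets",
    "write_monitoring_csv",
]

CSV_HEADER = [
    "participant_id",
    "cycle_id",
    "cycle_day",
    "lh_iu_l",
    "estrogen_pmol_l",
    "progesterone_nmol_l",
    "follicle_mm",
    "endometrium_mm",
]

#: Day-offset window retained around the rupture day.
OFFSET_WINDOW = (-3, 3)


class ValidationError(ValueError):
    """A record or dataset violates a structural invariant."""


class ParseError(ValueError):
    """A CSV field could not be interpreted."""


@dataclass(frozen=True)
class CycleObservation:
    """One monitoring visit.

    ``follicle_mm`` is a positive diameter when the leading follicle was
    visualized, or ``None``.  ``follicle_assessed`` disambiguates the two
    ``None`` meanings: ``True`` means ultrasound showed no follicle
    (ABSENT), ``False`` means there is no usable reading.
    """

    participant_id: str
    cycle_id: str
    cycle_day: int
    lh: Optional[float] = None
    estrogen: Optional[float] = None
    progesterone: Optional[float] = None
    follicle_mm: Optional[float] = None
    endometrium_mm: Optional[float] = None
    follicle_assessed: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.cycle_day, int) or self.cycle_day < 1:
            raise ValidationError(
                f"cycle_day must be an integer >= 1, got {self.cycle_day!r}"
            )
        if self.lh is not None and self.lh < 0:
            raise ValidationError(f"LH must be >= 0 IU/L, got {self.lh}")
        if self.estrogen is not None and self.estrogen <= 0:
            raise ValidationError(
                f"estrogen must be > 0 pmol/L, got {self.estrogen}"
            )
        if self.progesterone is not None and self.progesterone < 0:
            raise ValidationError(
                f"progesterone must be >= 0 nmol/L, got {self.progesterone}"
            )
        if self.follicle_mm is not None and self.follicle_mm <= 0:
            raise ValidationError(
                "follicle diameter must be > 0 mm when visualized "
                f"(never zero), got {self.follicle_mm}"
            )
        if self.endometrium_mm is not None and self.endometrium_mm <= 0:
            raise ValidationError(
                f"endometrial thickness must be > 0 mm, got {self.endometrium_mm}"
            )

    @property
    def follicle_present(self) -> bool:
        return self.follicle_mm is not None

    @property
    def follicle_absent(self) -> bool:
        """Ultrasound performed, no leading follicle visualized."""
        return self.follicle_mm is None and self.follicle_assessed


@dataclass(frozen=True)
class Cycle:
    """Ordered monitoring visits of one participant-cycle.

    ``ovulation_cycle_day`` is the (optional) cycle day of documented
    follicular rupture, i.e. D(0).
    """

    observations: Tuple[CycleObservation, ...]
    ovulation_cycle_day: Optional[int] = None
    cycle_length: Optional[int] = None

    def __post_init__(self) -> None:
        obs = tuple(self.observations)
        object.__setattr__(self, "observations", obs)
        if not obs:
            raise ValidationError("a cycle needs at least one observation")
        pid, cid = obs[0].participant_id, obs[0].cycle_id
        for o in obs:
            if (o.participant_id, o.cycle_id) != (pid, cid):
                raise ValidationError(
                    "all observations in a cycle must share participant and "
                    f"cycle identifiers; found ({o.participant_id}, {o.cycle_id}) "
                    f"next to ({pid}, {cid})"
                )
        days = [o.cycle_day for o in obs]
        for a, b in zip(days, days[1:]):
            if a == b:
                raise ValidationError(
                    f"duplicate observation on cycle_day {a} in cycle {cid}"
                )
            if a > b:
                raise ValidationError(
                    f"observations of cycle {cid} are not sorted by cycle_day"
                )
        if self.ovulation_cycle_day is not None:
            d0 = self.observation_on(self.ovulation_cycle_day)
            if d0 is None or not d0.follicle_absent:
                raise ValidationError(
                    f"cycle {cid}: annotated rupture day {self.ovulation_cycle_day} "
                    "must carry an observation with follicle ABSENT"
                )
            if not any(
                o.follicle_present and o.cycle_day < self.ovulation_cycle_day
                for o in obs
            ):
                raise ValidationError(
                    f"cycle {cid}: no visualized follicle precedes the "
                    "annotated rupture day"
                )

    @property
    def participant_id(self) -> str:
        return self.observations[0].participant_id

    @property
    def cycle_id(self) -> str:
        return self.observations[0].cycle_id

    @property
    def annotated(self) -> bool:
        return self.ovulation_cycle_day is not None

    def observation_on(self, cycle_day: int) -> Optional[CycleObservation]:
        for o in self.observations:
            if o.cycle_day == cycle_day:
                return o
        return None

    def observation_at_offset(self, day_offset: int) -> Optional[CycleObservation]:
        """Observation at ``D(day_offset)``; requires annotation."""
        if self.ovulation_cycle_day is None:
            raise ValidationError("cycle is not annotated with an ovulation day")
        return self.observation_on(self.ovulation_cycle_day + day_offset)


@dataclass(frozen=True)
class DayOffsetObservation:
    """An observation re-indexed relative to the rupture day D(0)."""

    day_offset: int
    observation: CycleObservation

    def __post_init__(self) -> None:
        lo, hi = OFFSET_WINDOW
        if not lo <= self.day_offset <= hi:
            raise ValidationError(
                f"day_offset must lie in [{lo}, {hi}], got {self.day_offset}"
            )


@dataclass(frozen=True)
class MonitoringDataset:
    """A collection of cycles plus free-text provenance."""

    cycles: Tuple[Cycle, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cycles", tuple(self.cycles))
        seen = set()
        for c in self.cycles:
            key = (c.participant_id, c.cycle_id)
            if key in seen:
                raise ValidationError(f"duplicate cycle identifier {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self):
        return iter(self.cycles)

    @property
    def annotated_cycles(self) -> Tuple[Cycle, ...]:
        return tuple(c for c in self.cycles if c.annotated)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _parse_float(raw: str, row_no: int, column: str) -> Optional[float]:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise ParseError(
            f"row {row_no}: malformed numeric field {column!r}: {raw!r}"
        ) from exc


def read_monitoring_csv(source: Union[str, os.PathLike, TextIO]) -> MonitoringDataset:
    """Read a monitoring dataset from a CSV path or text stream.

    Rows are grouped by ``(participant_id, cycle_id)`` and sorted by
    ``cycle_day`` within each cycle.  Duplicate ``(cycle_id, cycle_day)``
    rows and negative hormone values raise :class:`ValidationError`;
    malformed numbers raise :class:`ParseError` naming the offending row.
    """
    if hasattr(source, "read"):
        return _read_stream(source, provenance="<stream>")
    with open(source, "r", encoding="utf-8", newline="") as handle:
        return _read_stream(handle, provenance=str(source))


def _read_stream(stream: TextIO, provenance: str) -> MonitoringDataset:
    reader = csv.reader(stream)
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("empty input: missing CSV header") from None
    if [h.strip() for h in header] != CSV_HEADER:
        raise ParseError(
            f"unexpected CSV header {header!r}; expected {CSV_HEADER!r}"
        )

    # raw rows keyed by cycle, kept with their row numbers for error messages
    groups: "dict[tuple[str, str], list[tuple[int, list[str]]]]" = {}
    order: "list[tuple[str, str]]" = []
    for row_no, row in enumerate(reader, start=2):
        if not row or all(f.strip() == "" for f in row):
            continue
        if len(row) != len(CSV_HEADER):
            raise ParseError(
                f"row {row_no}: expected {len(CSV_HEADER)} fields, got {len(row)}"
            )
        key = (row[0].strip(), row[1].strip())
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append((row_no, row))

    cycles = []
    for key in order:
        rows = groups[key]
        parsed = []
        for row_no, row in rows:
            day_raw = row[2].strip()
            try:
                cycle_day = int(day_raw)
            except ValueError as exc:
                raise ParseError(
                    f"row {row_no}: malformed cycle_day {day_raw!r}"
                ) from exc
            parsed.append((cycle_day, row_no, row))
        parsed.sort(key=lambda item: item[0])
        for (da, ra, _), (db, rb, _) in zip(parsed, parsed[1:]):
            if da == db:
                raise ValidationError(
                    f"duplicate (cycle_id={key[1]!r}, cycle_day={da}) "
                    f"at rows {ra} and {rb}"
                )
        observations = []
        follicle_seen = False
        for cycle_day, row_no, row in parsed:
            follicle_raw = row[6].strip()
            if follicle_raw.upper() == "NA":
                follicle_mm, assessed = None, False
            elif follicle_raw == "":
                # empty means ABSENT once a follicle was documented earlier
                follicle_mm, assessed = None, follicle_seen
            else:
                follicle_mm = _parse_float(follicle_raw, row_no, "follicle_mm")
                assessed = True
                follicle_seen = True
            try:
                obs = CycleObservation(
                    participant_id=row[0].strip(),
                    cycle_id=row[1].strip(),
                    cycle_day=cycle_day,
                    lh=_parse_float(row[3], row_no, "lh_iu_l"),
                    estrogen=_parse_float(row[4], row_no, "estrogen_pmol_l"),
                    progesterone=_parse_float(row[5], row_no, "progesterone_nmol_l"),
                    follicle_mm=follicle_mm,
                    endometrium_mm=_parse_float(row[7], row_no, "endometrium_mm"),
                    follicle_assessed=assessed,
                )
            except ValidationError as exc:
                raise ValidationError(f"row {row_no}: {exc}") from exc
            observations.append(obs)
        cycles.append(Cycle(observations=tuple(observations)))
    return MonitoringDataset(cycles=tuple(cycles), provenance=provenance)


def _format_value(value: Optional[float]) -> str:
    if value is None:
        return ""
    if float(value).is_integer():
        return str(int(value)) if abs(value) < 1e15 else repr(value)
    return repr(float(value))


def write_monitoring_csv(
    dataset: MonitoringDataset, sink: Union[str, os.PathLike, TextIO]
) -> None:
    """Write ``dataset`` as CSV; ``read(write(d))`` round-trips losslessly.

    A follicle ABSENT observation is written as an empty ``follicle_mm``
    field and a not-assessed one as ``NA``.
    """
    if hasattr(sink, "write"):
        _write_stream(dataset, sink)
        return
    with open(sink, "w", encoding="utf-8", newline="") as handle:
        _write_stream(dataset, handle)


def _write_stream(dataset: MonitoringDataset, stream: TextIO) -> None:
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(CSV_HEADER)
    for cycle in dataset.cycles:
        for o in cycle.observations:
            if o.follicle_mm is not None:
                follicle = _format_value(o.follicle_mm)
            elif o.follicle_assessed:
                follicle = ""
            else:
                follicle = "NA"
            writer.writerow(
                [
                    o.participant_id,
                    o.cycle_id,
                    str(o.cycle_day),
                    _format_value(o.lh),
                    _format_value(o.estrogen),
                    _format_value(o.progesterone),
                    follicle,
                    _format_value(o.endometrium_mm),
                ]
            )


# ---------------------------------------------------------------------------
# Alignment to the rupture day
# ---------------------------------------------------------------------------

def annotate_ovulation_day(
    cycle: Cycle, min_prior_follicle_mm: float = 14.0
) -> Cycle:
    """Locate D(0) retrospectively and return an annotated copy.

    D(0) is the first observation with follicle ABSENT that is preceded by
    some observation whose follicle diameter reached
    ``min_prior_follicle_mm``.  The threshold guards against labelling the
    loss of a small, non-dominant follicle as ovulation.  If no such day
    exists the cycle is returned unannotated.  Idempotent: the annotation
    is recomputed from the observations alone.
    """
    if len(cycle.observations) < 2:
        raise ValidationError("annotation needs at least two observations")
    best_prior = 0.0
    rupture_day: Optional[int] = None
    for o in cycle.observations:
        if o.follicle_present:
            best_prior = max(best_prior, float(o.follicle_mm))
        elif o.follicle_absent and best_prior >= min_prior_follicle_mm:
            rupture_day = o.cycle_day
            break
    return replace(cycle, ovulation_cycle_day=rupture_day)


def to_day_offsets(cycle: Cycle) -> Tuple[DayOffsetObservation, ...]:
    """Re-index observations as offsets in [-3, +3] around D(0).

    Observations outside the window are dropped.  Raises
    :class:`ValidationError` for unannotated cycles.
    """
    if cycle.ovulation_cycle_day is None:
        raise ValidationError(
            f"cycle {cycle.cycle_id} has no ovulation-day annotation"
        )
    lo, hi = OFFSET_WINDOW
    out = []
    for o in cycle.observations:
        offset = o.cycle_day - cycle.ovulation_cycle_day
        if lo <= offset <= hi:
            out.append(DayOffsetObservation(day_offset=offset, observation=o))
    return tuple(out)


def pair_consecutive_tests(
    cycle: Cycle, gap_days: int
) -> Tuple[Tuple[CycleObservation, CycleObservation], ...]:
    """All (earlier, later) visit pairs exactly ``gap_days`` apart.

    ``gap_days`` must be 1 or 2, matching the daily / every-other-day
    monitoring cadence that the relative-change statistics assume.
    """
    if gap_days not in (1, 2):
        raise ValidationError(f"gap_days must be 1 or 2, got {gap_days}")
    by_day = {o.cycle_day: o for o in cycle.observations}
    pairs = []
    for day in sorted(by_day):
        later = by_day.get(day + gap_days)
        if later is not None:
            pairs.append((by_day[day], later))
    return tuple(pairs)
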