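"""Synthetic periovulatory-cycle generator.

Generates monitoring datasets whose statistical and structural properties
match a 118-cycle development cohort of healthy normo-ovulatory volunteers:

* per-day hormone and endometrium marginals anchored on the rupture day
  (mean, SEM-derived sd, and range for offsets D(-3)..D(+3));
* the LH peak at D(-1), displaced to D(-2) in a configurable fraction of
  cycles (default 5.9%);
* a two-phase estrogen fall: the per-cycle estrogen peak at D(-2), a first
  decrease at D(-1) in most cycles, but in a configurable fraction
  (default 19%) the decrease appearing only on the rupture day itself;
* a >= 50% cumulative estrogen fall from D(-2) to D(0) in a configurable
  fraction of cycles (default 85%);
* progesterone nondecreasing across the whole window;
* follicle >= 16 mm through D(-1) and ABSENT from D(0) onward.

Each per-day cell is a truncated log-normal whose *truncated* mean is
solved to equal the published per-day mean, so empirical cohort means
recover the calibration targets.  The "late estrogen drop" frequency is
hit without distorting either day's marginal by coupling D(-2) and D(-1)
through a Gaussian copula whose correlation is solved numerically.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
from scipy.special import ndtr

from ._samplers import ParameterError, TruncatedLogNormal, solve_copula_rho
from .cycle_data import Cycle, CycleObservation, MonitoringDataset

__all__ = [
    "CellParams",
    "HORMONES",
    "DAY_OFFSETS",
    "ParameterError",
    "SimulationParams",
    "cohort_attrition",
    "default_simulation_params",
    "load_simulation_params",
    "save_simulation_params",
    "simulate_cohort",
    "simulate_cycle",
]

HORMONES = ("lh", "estrogen", "progesterone")
DAY_OFFSETS = (-3, -2, -1, 0, 1, 2, 3)

#: Cycles contributing to each day's summary in the development cohort
#: (monitoring often started later than D(-3) and few cycles were followed
#: to D(+3)); used to convert per-day SEMs to sds and for the optional
#: attrition pattern.
DAY_N = {-3: 54, -2: 64, -1: 118, 0: 118, 1: 55, 2: 42, 3: 8}

# Per-day calibration constants: mean, SEM, (min, max).  The published
# LH ranges at D(-1) ("89.0-120.0", excluding the mean of 51.9) and D(0)
# ("73.8-60.8", inverted) are internally inconsistent, so wide plausible
# bounds are substituted for those two cells.
_LH = {
    -3: (12.1, 0.7, 5.3, 21.0),
    -2: (24.2, 1.5, 7.0, 58.0),
    -1: (51.9, 1.9, 10.0, 120.0),
    0: (18.0, 0.8, 3.0, 75.0),
    1: (10.5, 0.5, 3.0, 23.0),
    2: (11.3, 1.2, 2.9, 57.5),
    3: (10.5, 0.8, 7.4, 14.0),
}
_ESTROGEN = {
    -3: (1034.7, 49.2, 388.0, 1870.0),
    -2: (1378.2, 66.0, 481.0, 2625.0),
    -1: (1013.3, 35.7, 406.0, 2499.0),
    0: (393.2, 14.1, 152.0, 923.0),
    1: (357.7, 14.7, 170.0, 632.0),
    2: (420.5, 27.0, 205.0, 1063.0),
    3: (389.0, 68.7, 267.0, 723.0),
}
_PROGESTERONE = {
    -3: (1.5, 0.1, 0.4, 3.9),
    -2: (1.9, 0.10, 0.5, 4.1),
    -1: (3.2, 0.9, 1.6, 5.6),
    0: (5.1, 0.1, 1.8, 10.5),
    1: (11.2, 0.5, 3.7, 20.7),
    2: (19.7, 1.0, 3.9, 30.0),
    3: (20.2, 3.0, 9.2, 39.0),
}
_ENDOMETRIUM = {
    -3: (9.0, 0.2, 6.5, 14.0),
    -2: (9.5, 0.2, 2.7, 14.0),
    -1: (10.1, 0.2, 4.3, 25.0),
    0: (10.1, 0.2, 6.0, 19.0),
    1: (9.5, 0.2, 6.0, 14.0),
    2: (9.3, 0.2, 6.0, 13.0),
    3: (10.2, 0.8, 7.0, 13.0),
}
_TABLES = {"lh": _LH, "estrogen": _ESTROGEN, "progesterone": _PROGESTERONE}


@dataclass(frozen=True)
class CellParams:
    """Marginal parameters of one (measure, day-offset) cell."""

    mean: float
    sd: float
    min: float
    max: float

    def validate(self, label: str) -> None:
        if self.min >= self.max:
            raise ParameterError(f"{label}: min {self.min} >= max {self.max}")
        if self.sd < 0:
            raise ParameterError(f"{label}: sd {self.sd} < 0")
        if not self.min <= self.mean <= self.max:
            raise ParameterError(
                f"{label}: mean {self.mean} outside ({self.min}, {self.max})"
            )


@dataclass
class SimulationParams:
    """All tunables of the cohort generator.

    Defaults are the development-cohort calibration constants; the three
    event probabilities control the structural features described in the
    module docstring.  ``within_cycle_level_sd`` is the log-scale spread of
    a per-(cycle, hormone) multiplicative random effect that induces
    within-cycle correlation for LH and endometrium (estrogen and
    progesterone derive their coherence from the structural coupling).
    ``attrition_per_day`` optionally maps day offsets to inclusion
    probabilities (contiguous truncation of follow-up); ``None`` keeps the
    full 7-day window.
    """

    per_day_hormone: Dict[Tuple[str, int], CellParams]
    endometrium: Dict[int, CellParams]
    cycle_length_mean: float = 27.6
    cycle_length_sd: float = 3.3
    cycle_length_range: Tuple[int, int] = (17, 38)
    follicular_length_mean: float = 14.4
    follicular_length_sd: float = 2.2
    follicular_length_range: Tuple[int, int] = (9, 23)
    luteal_length_mean: float = 13.5
    luteal_length_sd: float = 2.2
    luteal_length_range: Tuple[int, int] = (9, 21)
    p_lh_peak_at_minus2: float = 0.059
    p_estrogen_drop_only_at_d0: float = 0.19
    p_sharp_drop_ge50: float = 0.85
    within_cycle_level_sd: float = 0.15
    attrition_per_day: Optional[Dict[int, float]] = None

    def validate(self) -> None:
        for name in (
            "p_lh_peak_at_minus2",
            "p_estrogen_drop_only_at_d0",
            "p_sharp_drop_ge50",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name}={p} outside [0, 1]")
        if self.within_cycle_level_sd < 0:
            raise ParameterError("within_cycle_level_sd must be >= 0")
        for hormone in HORMONES:
            for day in DAY_OFFSETS:
                cell = self.per_day_hormone.get((hormone, day))
                if cell is None:
                    raise ParameterError(f"missing cell ({hormone}, {day})")
                cell.validate(f"{hormone} D({day:+d})")
        for day in DAY_OFFSETS:
            cell = self.endometrium.get(day)
            if cell is None:
                raise ParameterError(f"missing endometrium cell for D({day:+d})")
            cell.validate(f"endometrium D({day:+d})")
        if self.attrition_per_day is not None:
            a = {d: float(self.attrition_per_day.get(d, 1.0)) for d in DAY_OFFSETS}
            for d, v in a.items():
                if not 0.0 <= v <= 1.0:
                    raise ParameterError(f"attrition[{d}]={v} outside [0, 1]")
            if a[-1] < 1.0 or a[0] < 1.0:
                raise ParameterError("D(-1) and D(0) must always be observed")
            if not a[-3] <= a[-2]:
                raise ParameterError("pre-ovulatory attrition must be monotone")
            if not a[1] >= a[2] >= a[3]:
                raise ParameterError("post-ovulatory attrition must be monotone")

    def digest(self) -> str:
        """Stable hash of the parameter set, for provenance records."""
        payload = {
            "per_day_hormone": {
                f"{h}.{d}": vars(self.per_day_hormone[(h, d)])
                for h in HORMONES
                for d in DAY_OFFSETS
            },
            "endometrium": {str(d): vars(self.endometrium[d]) for d in DAY_OFFSETS},
            "scalars": {
                k: getattr(self, k)
                for k in (
                    "cycle_length_mean",
                    "cycle_length_sd",
                    "cycle_length_range",
                    "follicular_length_mean",
                    "follicular_length_sd",
                    "follicular_length_range",
                    "luteal_length_mean",
                    "luteal_length_sd",
                    "luteal_length_range",
                    "p_lh_peak_at_minus2",
                    "p_estrogen_drop_only_at_d0",
                    "p_sharp_drop_ge50",
                    "within_cycle_level_sd",
                )
            },
            "attrition": self.attrition_per_day,
        }
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()


def default_simulation_params() -> SimulationParams:
    """The calibration defaults (per-day cells with sd = SEM * sqrt(n))."""
    per_day = {}
    for hormone, table in _TABLES.items():
        for day, (mean, sem, lo, hi) in table.items():
            per_day[(hormone, day)] = CellParams(
                mean=mean, sd=sem * math.sqrt(DAY_N[day]), min=lo, max=hi
            )
    endo = {
        day: CellParams(mean=m, sd=sem * math.sqrt(DAY_N[day]), min=lo, max=hi)
        for day, (m, sem, lo, hi) in _ENDOMETRIUM.items()
    }
    return SimulationParams(per_day_hormone=per_day, endometrium=endo)


def cohort_attrition() -> Dict[int, float]:
    """Per-day inclusion probabilities reproducing the cohort's n pattern."""
    return {d: DAY_N[d] / DAY_N[0] for d in DAY_OFFSETS}


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

class _CohortSampler:
    """Pre-solved distributions and couplings for one parameter set."""

    def __init__(self, params: SimulationParams):
        params.validate()
        self.params = params
        self.cells: Dict[Tuple[str, int], TruncatedLogNormal] = {}
        for hormone in HORMONES:
            for day in DAY_OFFSETS:
                c = params.per_day_hormone[(hormone, day)]
                self.cells[(hormone, day)] = TruncatedLogNormal(
                    c.mean, c.sd, c.min, c.max
                )
        self.endo = {
            day: TruncatedLogNormal(c.mean, c.sd, c.min, c.max)
            for day, c in params.endometrium.items()
        }
        # Structural event frequencies are hit, wherever achievable, by
        # Gaussian-copula couplings whose correlation is solved so the
        # event emerges at its configured probability while both day
        # marginals stay exact.  A None correlation means the target is
        # outside the achievable range (e.g. degenerate cells or extreme
        # probabilities) and the sampler falls back to explicit
        # conditional enforcement, which honours the event frequency at
        # the cost of some marginal distortion.
        e2 = self.cells[("estrogen", -2)]
        e1 = self.cells[("estrogen", -1)]
        e0 = self.cells[("estrogen", 0)]
        self.rho_late_drop = solve_copula_rho(
            e2, e1, params.p_estrogen_drop_only_at_d0
        )
        # sharp fall: P(E(0) <= 0.5 E(-2)) = p_sharp -> solve on the
        # complementary event with a 0.5 scale factor
        self.rho_sharp = solve_copula_rho(
            e2, e0, 1.0 - params.p_sharp_drop_ge50, scale=0.5
        )
        # LH peak day: P(LH(-1) >= LH(-2)) = 1 - p_lh_peak_at_minus2
        self.rho_lh_peak = solve_copula_rho(
            self.cells[("lh", -2)],
            self.cells[("lh", -1)],
            1.0 - params.p_lh_peak_at_minus2,
        )
        # fallback coin for the sharp fall, corrected for cycles whose
        # D(-2) level makes a non-sharp D(0) infeasible within the D(0)
        # bounds (those cycles end up sharp regardless)
        f_forced = float(1.0 - e2.cdf(2.0 * e0.hi)) if not e2.degenerate else 0.0
        p = params.p_sharp_drop_ge50
        if p <= f_forced or f_forced >= 1.0:
            self.p_sharp_eff = 0.0 if p <= f_forced else 1.0
        else:
            self.p_sharp_eff = (p - f_forced) / (1.0 - f_forced)

    # -- helpers ----------------------------------------------------------

    def _coherent_u(self, z_cycle: float, cell: TruncatedLogNormal,
                    rng: np.random.Generator) -> float:
        """Uniform draw correlated with the cycle-level latent."""
        s = self.params.within_cycle_level_sd
        if s <= 0 or cell.sigma <= 0:
            return float(rng.random())
        a = min(0.95, s / cell.sigma)
        z = a * z_cycle + math.sqrt(1.0 - a * a) * rng.standard_normal()
        return float(ndtr(z))

    def _estrogen_path(self, rng: np.random.Generator) -> Dict[int, float]:
        p = self.params
        E = {d: self.cells[("estrogen", d)] for d in DAY_OFFSETS}
        z2 = rng.standard_normal()
        v2 = float(ndtr(z2))
        e = {
            -3: float(E[-3].ppf(v2)),
            -2: float(E[-2].ppf(v2)),
        }
        if e[-3] >= e[-2]:  # comonotone guard; essentially never binds
            e[-3] = max(E[-3].lo, min(e[-2] * (1.0 - 1e-6), E[-3].hi))
            e[-3] = min(e[-3], e[-2] * (1.0 - 1e-9))
        if self.rho_late_drop is not None:
            rho = self.rho_late_drop
            z1 = rho * z2 + math.sqrt(1.0 - rho**2) * rng.standard_normal()
            e[-1] = float(E[-1].ppf(ndtr(z1)))
        else:
            # degenerate / extreme configurations: enforce the branch coin
            # explicitly (structure takes precedence over the cell bounds)
            if rng.random() < p.p_estrogen_drop_only_at_d0:
                e[-1] = E[-1].sample_conditional(rng, e[-2], None)
                e[-1] = max(e[-1], e[-2])
            else:
                e[-1] = E[-1].sample_conditional(rng, None, e[-2] * (1 - 1e-9))
                e[-1] = min(e[-1], e[-2] * (1.0 - 1e-9))
        no_drop_at_m1 = e[-1] >= e[-2]
        if self.rho_sharp is not None:
            rho = self.rho_sharp
            z0 = rho * z2 + math.sqrt(1.0 - rho**2) * rng.standard_normal()
            e[0] = float(E[0].ppf(ndtr(z0)))
            if no_drop_at_m1 and e[0] >= e[-1]:
                # the first decrease must occur on the rupture day
                e[0] = E[0].sample_conditional(rng, None, e[-1] * (1.0 - 1e-9))
        else:
            sharp = rng.random() < self.p_sharp_eff
            lb: Optional[float] = None
            ub: Optional[float] = None
            if no_drop_at_m1:
                ub = e[-1] * (1.0 - 1e-9)
            if sharp:
                ub = min(ub, 0.5 * e[-2]) if ub is not None else 0.5 * e[-2]
            else:
                lb = float(np.nextafter(0.5 * e[-2], np.inf))
                if lb >= (ub if ub is not None else E[0].hi):
                    # non-sharp infeasible within bounds; forced sharp
                    lb = None
                    ub = min(
                        0.5 * e[-2],
                        ub if ub is not None else 0.5 * e[-2],
                    )
            e[0] = E[0].sample_conditional(rng, lb, ub)
        for d in (1, 2, 3):
            e[d] = float(E[d].ppf(self._coherent_u(z2, E[d], rng)))
        return e

    def _lh_path(self, rng: np.random.Generator) -> Dict[int, float]:
        L = {d: self.cells[("lh", d)] for d in DAY_OFFSETS}
        z = rng.standard_normal()
        lh = {d: float(L[d].ppf(self._coherent_u(z, L[d], rng))) for d in DAY_OFFSETS}
        if self.rho_lh_peak is not None:
            rho = self.rho_lh_peak
            z2 = rng.standard_normal()
            z1 = rho * z2 + math.sqrt(1.0 - rho**2) * rng.standard_normal()
            lh[-2] = float(L[-2].ppf(ndtr(z2)))
            lh[-1] = float(L[-1].ppf(ndtr(z1)))
            peak_day = -1 if lh[-1] >= lh[-2] else -2
        else:
            # fallback: designate the peak day by coin and swap the pair
            peak_at_m2 = rng.random() < self.params.p_lh_peak_at_minus2
            hi_v = max(lh[-2], lh[-1])
            lo_v = min(lh[-2], lh[-1])
            if peak_at_m2:
                lh[-2], lh[-1] = hi_v, lo_v
                peak_day = -2
            else:
                lh[-2], lh[-1] = lo_v, hi_v
                peak_day = -1
        peak = lh[peak_day]
        for d in DAY_OFFSETS:
            if d != peak_day and lh[d] >= peak:
                # keep the per-cycle maximum at the designated peak day;
                # respect the cell's lower bound unless it conflicts
                lh[d] = max(min(peak * (1.0 - 1e-6), lh[d]), L[d].lo)
                if lh[d] >= peak:
                    lh[d] = peak * (1.0 - 1e-6)
        return lh

    def _progesterone_path(self, rng: np.random.Generator) -> Dict[int, float]:
        # comonotone across days (one luteinization trajectory per cycle),
        # with a running-max guard securing monotone nondecrease
        v = float(rng.random())
        values = [float(self.cells[("progesterone", d)].ppf(v)) for d in DAY_OFFSETS]
        values = np.maximum.accumulate(values)
        return dict(zip(DAY_OFFSETS, (float(x) for x in values)))

    def _included_offsets(self, rng: np.random.Generator) -> Tuple[int, ...]:
        a = self.params.attrition_per_day
        if a is None:
            return DAY_OFFSETS
        a = {d: float(a.get(d, 1.0)) for d in DAY_OFFSETS}
        u_pre, u_post = rng.random(), rng.random()
        included = [-1, 0]
        if u_pre < a[-2]:
            included.append(-2)
            if u_pre < a[-3]:
                included.append(-3)
        if u_post < a[1]:
            included.append(1)
            if u_post < a[2]:
                included.append(2)
                if u_post < a[3]:
                    included.append(3)
        return tuple(sorted(included))

    # -- cycle assembly ---------------------------------------------------

    def simulate_one(
        self, rng: np.random.Generator, participant_id: str, cycle_id: str
    ) -> Cycle:
        p = self.params
        foll = int(round(rng.normal(p.follicular_length_mean, p.follicular_length_sd)))
        foll = int(np.clip(foll, *p.follicular_length_range))
        luteal = int(round(rng.normal(p.luteal_length_mean, p.luteal_length_sd)))
        luteal = int(np.clip(luteal, *p.luteal_length_range))
        cycle_length = int(np.clip(foll + luteal, *p.cycle_length_range))
        ovulation_day = foll  # day 1 = menses onset; rupture ends the phase

        estrogen = self._estrogen_path(rng)
        lh = self._lh_path(rng)
        prog = self._progesterone_path(rng)
        z_endo = rng.standard_normal()
        endo = {
            d: float(self.endo[d].ppf(self._coherent_u(z_endo, self.endo[d], rng)))
            for d in DAY_OFFSETS
        }
        # leading follicle: >= 16 mm by D(-1), shrinking backwards in time
        f_m1 = float(np.clip(rng.normal(20.0, 1.5), 16.5, 25.0))
        f_m2 = f_m1 - rng.uniform(1.0, 2.5)
        f_m3 = f_m2 - rng.uniform(1.0, 2.5)
        follicle = {-3: f_m3, -2: f_m2, -1: f_m1, 0: None, 1: None, 2: None, 3: None}

        observations = []
        for d in self._included_offsets(rng):
            observations.append(
                CycleObservation(
                    participant_id=participant_id,
                    cycle_id=cycle_id,
                    cycle_day=ovulation_day + d,
                    lh=lh[d],
                    estrogen=estrogen[d],
                    progesterone=prog[d],
                    follicle_mm=None if follicle[d] is None else round(follicle[d], 1),
                    endometrium_mm=endo[d],
                    follicle_assessed=True,
                )
            )
        return Cycle(
            observations=tuple(observations),
            ovulation_cycle_day=ovulation_day,
            cycle_length=cycle_length,
        )


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def simulate_cycle(params: SimulationParams, rng_seed: int) -> Cycle:
    """One annotated cycle, deterministic in ``(params, rng_seed)``."""
    sampler = _CohortSampler(params)
    rng = np.random.default_rng(rng_seed)
    return sampler.simulate_one(rng, "P0001", "C0001")


def simulate_cohort(
    params: SimulationParams, n_cycles: int, rng_seed: int
) -> MonitoringDataset:
    """``n_cycles`` independent cycles; deterministic in all arguments.

    Participants are assigned round-robin at roughly three cycles each,
    mirroring the 37-participant / 118-cycle composition of the
    development cohort.
    """
    if n_cycles < 0:
        raise ParameterError(f"n_cycles must be >= 0, got {n_cycles}")
    sampler = _CohortSampler(params)
    master = np.random.default_rng(rng_seed)
    seeds = master.integers(0, 2**31 - 1, size=n_cycles)
    cycles = []
    for i in range(n_cycles):
        rng = np.random.default_rng(int(seeds[i]))
        cycles.append(
            sampler.simulate_one(rng, f"P{i // 3 + 1:04d}", f"C{i + 1:04d}")
        )
    provenance = (
        f"simulated seed={rng_seed} n={n_cycles} params={params.digest()[:12]}"
    )
    return MonitoringDataset(cycles=tuple(cycles), provenance=provenance)


# ---------------------------------------------------------------------------
# Flat key=value (de)serialization
# ---------------------------------------------------------------------------

_SCALAR_KEYS = (
    "cycle_length_mean",
    "cycle_length_sd",
    "follicular_length_mean",
    "follicular_length_sd",
    "luteal_length_mean",
    "luteal_length_sd",
    "p_lh_peak_at_minus2",
    "p_estrogen_drop_only_at_d0",
    "p_sharp_drop_ge50",
    "within_cycle_level_sd",
)


def save_simulation_params(params: SimulationParams, path: Union[str, os.PathLike]) -> None:
    """Write params as flat ``key=value`` lines (``hormone.day.field``)."""
    lines = []
    for key in _SCALAR_KEYS:
        lines.append(f"{key}={getattr(params, key)}")
    for hormone in HORMONES:
        for day in DAY_OFFSETS:
            c = params.per_day_hormone[(hormone, day)]
            for f in ("mean", "sd", "min", "max"):
                lines.append(f"{hormone}.{day}.{f}={getattr(c, f)}")
    for day in DAY_OFFSETS:
        c = params.endometrium[day]
        for f in ("mean", "sd", "min", "max"):
            lines.append(f"endometrium.{day}.{f}={getattr(c, f)}")
    if params.attrition_per_day is not None:
        for day in DAY_OFFSETS:
            if day in params.attrition_per_day:
                lines.append(f"attrition.{day}={params.attrition_per_day[day]}")
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\n".join(lines) + "\n")


def load_simulation_params(
    path: Union[str, os.PathLike], base: Optional[SimulationParams] = None
) -> SimulationParams:
    """Read a flat config, overriding ``base`` (defaults if omitted)."""
    params = base if base is not None else default_simulation_params()
    cells = dict(params.per_day_hormone)
    endo = dict(params.endometrium)
    scalars = {k: getattr(params, k) for k in _SCALAR_KEYS}
    attrition = dict(params.attrition_per_day or {}) or None
    with open(path, "r", encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParameterError(f"malformed config line: {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key in _SCALAR_KEYS:
                scalars[key] = float(value)
                continue
            parts = key.split(".")
            if parts[0] == "attrition" and len(parts) == 2:
                attrition = attrition or {}
                attrition[int(parts[1])] = float(value)
                continue
            if len(parts) != 3:
                raise ParameterError(f"unrecognized config key: {key!r}")
            measure, day_s, fieldname = parts
            day = int(day_s)
            if fieldname not in ("mean", "sd", "min", "max"):
                raise ParameterError(f"unrecognized cell field: {fieldname!r}")
            if measure == "endometrium":
                current = vars(endo[day]).copy()
                current[fieldname] = float(value)
                endo[day] = CellParams(**current)
            elif measure in HORMONES:
                current = vars(cells[(measure, day)]).copy()
                current[fieldname] = float(value)
                cells[(measure, day)] = CellParams(**current)
            else:
                raise ParameterError(f"unrecognized measure: {measure!r}")
    out = SimulationParams(
        per_day_hormone=cells,
        endometrium=endo,
        attrition_per_day=attrition,
        **scalars,
    )
    out.validate()
    return out
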