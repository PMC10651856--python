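"""Calibrated truncated log-normal samplers.

Hormone concentrations are positive and right-skewed, so each per-day cell
is modelled as a log-normal truncated to the cell's published (min, max)
range.  Two calibration steps make the simulated marginals honest:

* the log-scale spread ``sigma`` is moment-matched to the cell's
  coefficient of variation (``sigma^2 = ln(1 + (sd/mean)^2)``);
* the log-scale location ``mu`` is then solved numerically so that the
  *truncated* distribution's mean equals the cell's target mean.  Plain
  moment matching of the untruncated distribution followed by truncation
  would shift the realized mean whenever the bounds carry weight (for some
  cells the published sd is large relative to the printed range, and the
  truncation then dominates).

A small Gauss-Hermite helper solves the Gaussian-copula correlation that
yields a prescribed exceedance probability between two such cells; the
cohort simulator uses it to hit the configured frequency of
"estrogen not yet falling at D(-1)" while keeping both day marginals exact.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri


class ParameterError(ValueError):
    """Simulation parameters are infeasible."""


def _trunc_lognorm_mean(mu: float, sigma: float, ln_lo: float, ln_hi: float) -> float:
    """Mean of LogNormal(mu, sigma) truncated to [exp(ln_lo), exp(ln_hi)]."""
    a = (ln_lo - mu) / sigma
    b = (ln_hi - mu) / sigma
    mass = ndtr(b) - ndtr(a)
    if mass < 1e-14:
        # essentially all mass beyond one bound: limit is the nearer bound
        return math.exp(ln_lo) if a > 0 else math.exp(ln_hi)
    num = ndtr(b - sigma) - ndtr(a - sigma)
    return math.exp(mu + 0.5 * sigma * sigma) * num / mass


class TruncatedLogNormal:
    """Log-normal truncated to (lo, hi) with an exact target mean.

    ``sd == 0`` degenerates to a point mass at ``mean``.
    """

    def __init__(self, mean: float, sd: float, lo: float, hi: float):
        if not (lo > 0 and hi > lo):
            raise ParameterError(f"need 0 < min < max, got ({lo}, {hi})")
        if sd < 0:
            raise ParameterError(f"sd must be >= 0, got {sd}")
        if mean <= 0:
            raise ParameterError(f"mean must be > 0, got {mean}")
        self.mean = float(mean)
        self.sd = float(sd)
        self.lo = float(lo)
        self.hi = float(hi)
        self.degenerate = sd == 0
        if self.degenerate:
            if not lo <= mean <= hi:
                raise ParameterError(
                    f"degenerate cell mean {mean} outside bounds ({lo}, {hi})"
                )
            self.sigma = 0.0
            self.mu = math.log(mean)
            self._fa, self._fb = 0.0, 1.0
            return
        if not lo < mean < hi:
            raise ParameterError(
                f"cell mean {mean} must lie strictly inside bounds ({lo}, {hi})"
            )
        cv = sd / mean
        self.sigma = math.sqrt(math.log1p(cv * cv))
        ln_lo, ln_hi = math.log(lo), math.log(hi)
        lo_b = ln_lo - 6.0 * self.sigma - 6.0
        hi_b = ln_hi + 6.0 * self.sigma + 6.0
        self.mu = brentq(
            lambda m: _trunc_lognorm_mean(m, self.sigma, ln_lo, ln_hi) - mean,
            lo_b,
            hi_b,
            xtol=1e-10,
        )
        self._fa = float(ndtr((ln_lo - self.mu) / self.sigma))
        self._fb = float(ndtr((ln_hi - self.mu) / self.sigma))

    # -- distribution functions -------------------------------------------

    def ppf(self, q):
        """Quantile function; vectorized over ``q`` in [0, 1]."""
        if self.degenerate:
            return np.full_like(np.asarray(q, dtype=float), self.mean)
        u = self._fa + np.asarray(q, dtype=float) * (self._fb - self._fa)
        u = np.clip(u, 1e-13, 1.0 - 1e-13)
        return np.exp(self.mu + self.sigma * ndtri(u))

    def cdf(self, x):
        if self.degenerate:
            return np.where(np.asarray(x, dtype=float) >= self.mean, 1.0, 0.0)
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        u = ndtr((np.log(x) - self.mu) / self.sigma)
        return np.clip((u - self._fa) / (self._fb - self._fa), 0.0, 1.0)

    def sample(self, rng: np.random.Generator, size=None):
        return self.ppf(rng.random(size))

    def sample_conditional(
        self, rng: np.random.Generator, lo: Optional[float], hi: Optional[float]
    ) -> float:
        """One draw conditioned to the interval (lo, hi) ∩ (self.lo, self.hi).

        If the conditioning interval carries no mass the nearest feasible
        value is returned (a clamp); callers treat that as a rare edge.
        """
        lo_eff = self.lo if lo is None else max(lo, self.lo)
        hi_eff = self.hi if hi is None else min(hi, self.hi)
        if lo_eff >= hi_eff:
            return float(min(max(lo_eff, self.lo), self.hi))
        qlo = float(self.cdf(lo_eff))
        qhi = float(self.cdf(hi_eff))
        if qhi - qlo < 1e-12:
            return float(0.5 * (lo_eff + hi_eff))
        u = qlo + rng.random() * (qhi - qlo)
        return float(self.ppf(u))

    def theoretical_mean(self) -> float:
        if self.degenerate:
            return self.mean
        return _trunc_lognorm_mean(
            self.mu, self.sigma, math.log(self.lo), math.log(self.hi)
        )


def solve_copula_rho(
    dist_prev: TruncatedLogNormal,
    dist_cur: TruncatedLogNormal,
    target_p_geq: float,
    scale: float = 1.0,
    nodes: int = 96,
) -> Optional[float]:
    """Gaussian-copula correlation giving P(X_cur >= scale * X_prev) = target.

    ``X_prev = Q_prev(Phi(z))`` and ``X_cur = Q_cur(Phi(rho z + sqrt(1-rho^2) e))``
    with (z, e) independent standard normals.  For fixed z the event reduces
    to a threshold on e, so the probability is a smooth one-dimensional
    integral evaluated with Gauss-Hermite nodes.  Returns ``None`` when the
    target is outside the achievable range (the caller then falls back to
    explicit enforcement).
    """
    if dist_prev.degenerate or dist_cur.degenerate:
        return None
    z, w = np.polynomial.hermite_e.hermegauss(nodes)
    w = w / math.sqrt(2.0 * math.pi)
    x_prev = dist_prev.ppf(ndtr(z))
    v_star = np.clip(dist_cur.cdf(scale * x_prev), 1e-12, 1.0 - 1e-12)
    t = ndtri(v_star)

    def p_geq(rho: float) -> float:
        s = math.sqrt(max(1.0 - rho * rho, 1e-12))
        return float(np.sum(w * ndtr(-(t - rho * z) / s)))

    lo, hi = -0.995, 0.995
    p_lo, p_hi = p_geq(lo), p_geq(hi)
    # p is monotone decreasing in rho here (stronger coupling makes the
    # lower-mean day exceed the higher-mean day less often)
    p_min, p_max = min(p_lo, p_hi), max(p_lo, p_hi)
    if not p_min < target_p_geq < p_max:
        return None
    return float(brentq(lambda r: p_geq(r) - target_p_geq, lo, hi, xtol=1e-6))
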