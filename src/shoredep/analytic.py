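"""Closed-form moments of the interval estimator under binomial thinning.

Each of the ``D`` birds deposited at lag ``n`` reaches the collection count
independently with probability ``q_n = E * P_n``, so a search's collected
count is a sum of independent binomials,

    N_C ~ sum_{n=0}^{s-1} Binomial(D, q_n),

with mean ``D * E * SP`` and variance ``D * sum q_n (1 - q_n)``, where
``SP = sum_{n=0}^{s-1} P_n``.  The trial estimate averages ``K = period/s``
independent searches and rescales, giving

    E[total] = D * period
    Var[total] = period^2 * Var(N_C) / (K * (E * SP)^2)

The per-search counts are independent across searches because undetected
carcasses do not carry over between intervals — the same assumption the
simulator makes, so the two modules are a matched pair.

The bounding patterns put all ``s * D`` birds of an interval at a single
lag (``s - 1`` or ``0``), so the expected totals have the closed forms

    first_day: period * D * s * P_{s-1} / SP     (underestimate)
    last_day:  period * D * s / SP               (overestimate)

Searcher efficiency cancels in both, so the bias magnitudes depend only on
the persistence curve, the interval length and the deposition magnitude.
At ``s = 2`` the two magnitudes are equal for *any* persistence curve
(``SP = 1 + P_1`` makes both errors ``period*D*(1-P_1)/(1+P_1)``); for
longer intervals with decreasing persistence the overestimate dominates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import HabitatParams

__all__ = ["MomentReport", "BiasBounds", "analytic_moments", "bias_bounds"]


@dataclass(frozen=True)
class MomentReport:
    """Exact mean/variance/SD/CV of the trial total estimate."""

    expected_total: float
    variance: float
    sd: float

    @property
    def cv(self) -> float:
        return self.sd / self.expected_total

    @property
    def cv_percent(self) -> float:
        return 100.0 * self.cv


@dataclass(frozen=True)
class BiasBounds:
    """Expected totals and signed errors under the two bounding patterns.

    ``first_day_error <= 0 <= last_day_error`` always.  The SDs are the
    exact trial-estimate SDs under each pattern (error bars for the bias
    points).
    """

    true_total: float
    first_day_total: float
    last_day_total: float
    first_day_sd: float
    last_day_sd: float

    @property
    def first_day_error(self) -> float:
        return self.first_day_total - self.true_total

    @property
    def last_day_error(self) -> float:
        return self.last_day_total - self.true_total


def _validate(rate_D: float, s: int, params: HabitatParams, period: int) -> None:
    if rate_D < 0:
        raise ValueError("deposition rate must be non-negative")
    if s < 1 or period % s != 0:
        raise ValueError(f"search interval {s} must divide the period {period}")
    if s > params.persistence.n_max + 1:
        raise ValueError(
            f"search interval {s} exceeds persistence-curve support "
            f"(max {params.persistence.n_max + 1} days)"
        )


def _total_variance(
    var_nc: float, s: int, params: HabitatParams, period: int
) -> float:
    denom = params.searcher_efficiency * params.persistence.head_sum(s)
    if denom == 0.0:
        raise ZeroDivisionError("searcher efficiency x persistence sum is zero")
    k = period // s
    return period**2 * var_nc / (k * denom**2)


def analytic_moments(
    rate_D: float, s: int, params: HabitatParams, period: int = 12
) -> MomentReport:
    """Moments of the trial total under constant deposition of ``rate_D``/day.

    ``rate_D`` is the deposited-bird count per day on the (1-km) segment.
    The estimator is unbiased: the expected total is ``rate_D * period``.
    """
    _validate(rate_D, s, params, period)
    e = params.searcher_efficiency
    q = e * np.asarray(params.persistence.values[:s])
    var_nc = rate_D * float(np.sum(q * (1.0 - q)))
    var_total = _total_variance(var_nc, s, params, period)
    return MomentReport(
        expected_total=rate_D * period,
        variance=var_total,
        sd=math.sqrt(var_total),
    )


def bias_bounds(
    rate_D: float, s: int, params: HabitatParams, period: int = 12
) -> BiasBounds:
    """Exact expected totals and SDs under the first-day / last-day patterns."""
    _validate(rate_D, s, params, period)
    e = params.searcher_efficiency
    sp = params.persistence.head_sum(s)
    true_total = rate_D * period
    birds = s * rate_D  # all deposited at a single lag per interval

    def _pattern(lag: int) -> tuple[float, float]:
        p = params.persistence[lag]
        q = e * p
        total = period * rate_D * s * p / sp
        var_nc = birds * q * (1.0 - q)
        return total, math.sqrt(_total_variance(var_nc, s, params, period))

    first_total, first_sd = _pattern(s - 1)
    last_total, last_sd = _pattern(0)
    return BiasBounds(
        true_total=true_total,
        first_day_total=first_total,
        last_day_total=last_total,
        first_day_sd=first_sd,
        last_day_sd=last_sd,
    )
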