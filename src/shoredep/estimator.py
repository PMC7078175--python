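"""The per-interval daily deposition estimator and its forward model.

Shoreline segments are rarely searched daily, so the count of carcasses
collected at a search reflects every day since the previous search — thinned
by persistence (older carcasses are more likely to have been scavenged) and
by imperfect detection.  The forward model for the expected collection at
the end of a search interval of ``s`` days is

    E[N_C] = E * sum_{n=0}^{s-1} D_n * P_n

where ``D_n`` birds were deposited ``n`` days before the search, ``P_n`` is
the persistence probability at lag ``n`` and ``E`` the searcher efficiency.
Assuming deposition is constant within the interval (``D_n = D``), the model
inverts to the estimator used in the Shoreline Deposition Model:

    D = (N_C - N_O) / (L * E * sum_{n=0}^{s-1} P_n)

with ``N_O`` the "old" carcasses judged to belong to a previous interval and
``L`` the segment length in kilometres, so ``D`` is birds per kilometre per
day.  The same rate is attributed to every day of the interval.

Index convention: the persistence sum runs over exactly ``s`` lags,
``n = s-1 .. 0``.  A bird deposited on the search day itself has lag 0 and
``P_0 = 1``; an interval ending on day ``t`` covers deposition days
``(t-s, t]``, half-open at the start.
"""
from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Sequence

from .params import HabitatParams

__all__ = [
    "SearchInterval",
    "DepositionEstimate",
    "persistence_sum",
    "expected_collections",
    "estimate_daily_rate",
]

logger = logging.getLogger("shoredep")


@dataclass(frozen=True)
class SearchInterval:
    """One between-search record for a shoreline segment.

    ``end_date`` is the calendar day of the closing search; it is optional
    for pure rate calculations but required when intervals feed the
    day-by-day extrapolation.
    """

    segment_id: str
    habitat_label: str
    interval_length_s: int
    n_collected: int
    n_old: int
    segment_length_L: float
    end_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if self.interval_length_s < 1:
            raise ValueError(f"interval length must be >= 1 day, got {self.interval_length_s}")
        if self.n_collected < 0:
            raise ValueError("collected count must be non-negative")
        if not (0 <= self.n_old <= self.n_collected):
            raise ValueError(
                f"old-carcass count {self.n_old} must lie in [0, collected={self.n_collected}]"
            )
        if self.segment_length_L <= 0:
            raise ValueError("segment length must be positive")

    @property
    def start_date(self) -> _dt.date:
        """First deposition day covered by the interval (half-open start)."""
        if self.end_date is None:
            raise ValueError("interval has no end date")
        return self.end_date - _dt.timedelta(days=self.interval_length_s - 1)


@dataclass(frozen=True)
class DepositionEstimate:
    """Estimated daily deposition rate (birds/km/day) for one interval.

    The rate applies to each day the interval covers.
    """

    segment_id: str
    rate_D: float


def persistence_sum(params: HabitatParams, s: int) -> float:
    """Sum of persistence probabilities over the ``s`` lags of an interval.

    Returns ``sum_{n=0}^{s-1} P_n`` — the expected number of
    persistence-weighted "carcass-days" contributed by one bird per day of
    constant deposition.  Errors if ``s`` exceeds the curve's tabulated
    support.
    """
    return params.persistence.head_sum(s)


def expected_collections(daily_deposits: Sequence[float], params: HabitatParams) -> float:
    """Expected carcasses collected at the closing search of an interval.

    ``daily_deposits[n]`` is the number of birds deposited at lag ``n``
    (``n = 0`` is the search day itself).  With constant deposits this
    reduces to ``E * D * persistence_sum``.
    """
    curve = params.persistence
    if len(daily_deposits) > curve.n_max + 1:
        raise ValueError(
            f"deposits span {len(daily_deposits)} lags but the persistence curve "
            f"supports only 0..{curve.n_max}"
        )
    if any(d < 0 for d in daily_deposits):
        raise ValueError("deposit counts must be non-negative")
    return params.searcher_efficiency * sum(
        d * curve[n] for n, d in enumerate(daily_deposits)
    )


def daily_rate(
    n_collected: int,
    n_old: int,
    length_km: float,
    params: HabitatParams,
    s: int,
) -> float:
    """Core rate computation; clamps a negative numerator to zero.

    A negative ``N_C - N_O`` can only arise from relaxed upstream
    validation; negative deposition is physically meaningless, so the rate
    is clamped to 0 with a warning rather than returned negative.
    """
    denom = length_km * params.searcher_efficiency * persistence_sum(params, s)
    if denom == 0.0:
        raise ZeroDivisionError(
            "unusable parameters: searcher efficiency x persistence sum is zero"
        )
    net = n_collected - n_old
    if net < 0:
        logger.warning(
            "collected - old = %d is negative; clamping deposition rate to 0", net
        )
        net = 0
    return net / denom


def estimate_daily_rate(interval: SearchInterval, params: HabitatParams) -> DepositionEstimate:
    """Invert the forward model for one search interval.

    The estimator divides the net fresh-carcass count by segment length,
    searcher efficiency and the persistence sum; the resulting birds/km/day
    rate is attributed to each day of the interval.  Rates are kept at full
    precision — rounding happens only at reporting time.
    """
    rate = daily_rate(
        interval.n_collected,
        interval.n_old,
        interval.segment_length_L,
        params,
        interval.interval_length_s,
    )
    return DepositionEstimate(segment_id=interval.segment_id, rate_D=rate)
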