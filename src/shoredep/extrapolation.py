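"""Habitat-stratified daily averaging and shoreline extrapolation.

Searched segments are a sample of the shoreline.  For each calendar day,
the per-segment daily rates (birds/km/day) of segments sharing a habitat
within a user-defined extrapolation area are averaged — an *unweighted*
mean across segments, not a length-weighted one — and the mean rate is
multiplied by the total shoreline length of that habitat in the area.
Daily habitat estimates are then summed over areas and days for the final
deposition total.

Habitat-day cells with no qualifying segment are reported as missing and
excluded from the total (with a logged tally), never silently imputed as
zero: absence of search data is not evidence of absent deposition.
"""
from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .estimator import SearchInterval, estimate_daily_rate
from .params import HabitatParams

__all__ = [
    "Segment",
    "ExtrapolationArea",
    "DailyAreaEstimate",
    "TotalDeposition",
    "daily_rates",
    "extrapolate_day",
    "area_daily_estimates",
    "total_deposition",
]

logger = logging.getLogger("shoredep")

RATE_COLUMNS = ["segment_id", "date", "habitat", "rate_birds_per_km"]


@dataclass(frozen=True)
class Segment:
    segment_id: str
    habitat_label: str
    length_km: float
    extrapolation_area_id: str

    def __post_init__(self) -> None:
        if self.length_km <= 0:
            raise ValueError("segment length must be positive")


@dataclass(frozen=True)
class ExtrapolationArea:
    """Total shoreline length (km) per habitat within one extrapolation area."""

    area_id: str
    habitat_lengths: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.habitat_lengths.values()):
            raise ValueError("habitat shoreline lengths must be non-negative")
        if not any(v > 0 for v in self.habitat_lengths.values()):
            raise ValueError("area must contain at least one habitat with positive length")


@dataclass(frozen=True)
class DailyAreaEstimate:
    """One habitat-day cell of one extrapolation area.

    ``missing`` cells (no contributing segment) carry NaN rate and birds.
    """

    area_id: str
    date: _dt.date
    habitat_label: str
    mean_rate: float
    n_segments: int
    extrapolated_birds: float

    @property
    def missing(self) -> bool:
        return self.n_segments == 0


@dataclass(frozen=True)
class TotalDeposition:
    total_birds: float
    n_missing_cells: int
    breakdown: pd.DataFrame  # one row per habitat-day cell


def daily_rates(
    intervals: Iterable[SearchInterval],
    params_by_habitat: Mapping[str, HabitatParams],
    max_interval: int,
) -> pd.DataFrame:
    """Expand qualifying intervals into a per-segment-day rate table.

    Intervals longer than ``max_interval`` days are disqualified (logged);
    their days stay uncovered.  Each qualifying interval's rate is carried
    by every day it covers, ``(end - s, end]``.  Overlapping intervals for
    one segment are a validation error.
    """
    if max_interval < 1:
        raise ValueError("max_interval must be at least 1 day")
    by_segment: dict[str, list[SearchInterval]] = {}
    for iv in intervals:
        if iv.end_date is None:
            raise ValueError(f"interval for segment {iv.segment_id!r} has no end date")
        by_segment.setdefault(iv.segment_id, []).append(iv)

    rows: list[dict] = []
    n_disqualified = 0
    for seg_id, ivs in by_segment.items():
        ivs = sorted(ivs, key=lambda iv: iv.end_date)
        for prev, cur in zip(ivs, ivs[1:]):
            if cur.start_date <= prev.end_date:
                raise ValueError(
                    f"segment {seg_id!r}: intervals ending {prev.end_date} and "
                    f"{cur.end_date} overlap"
                )
        for iv in ivs:
            if iv.interval_length_s > max_interval:
                n_disqualified += 1
                logger.info(
                    "DISQUALIFIED_INTERVAL segment=%s end=%s s=%d > max_interval=%d",
                    seg_id, iv.end_date, iv.interval_length_s, max_interval,
                )
                continue
            if iv.habitat_label not in params_by_habitat:
                raise KeyError(
                    f"no habitat parameters for {iv.habitat_label!r} "
                    f"(segment {seg_id!r})"
                )
            rate = estimate_daily_rate(iv, params_by_habitat[iv.habitat_label]).rate_D
            for offset in range(iv.interval_length_s):
                rows.append(
                    {
                        "segment_id": seg_id,
                        "date": iv.start_date + _dt.timedelta(days=offset),
                        "habitat": iv.habitat_label,
                        "rate_birds_per_km": rate,
                    }
                )
    if n_disqualified:
        logger.info("daily_rates: %d interval(s) disqualified by max_interval", n_disqualified)
    return pd.DataFrame(rows, columns=RATE_COLUMNS)


def extrapolate_day(
    rates: pd.DataFrame, area: ExtrapolationArea, date: _dt.date
) -> list[DailyAreaEstimate]:
    """Extrapolate one day's segment rates over one area, per habitat.

    ``rates`` must already be restricted to segments of this area on this
    date.  For each habitat in the area: unweighted mean of contributing
    segment rates times the habitat's total shoreline length; habitats with
    no contributing segment are flagged missing.
    """
    out: list[DailyAreaEstimate] = []
    for habitat, length in area.habitat_lengths.items():
        sub = rates[rates["habitat"] == habitat]
        n = len(sub)
        if n == 0:
            logger.info(
                "MISSING_CELL area=%s date=%s habitat=%s", area.area_id, date, habitat
            )
            out.append(
                DailyAreaEstimate(area.area_id, date, habitat, math.nan, 0, math.nan)
            )
        else:
            mean_rate = float(sub["rate_birds_per_km"].mean())
            out.append(
                DailyAreaEstimate(
                    area.area_id, date, habitat, mean_rate, n, mean_rate * length
                )
            )
    return out


def area_daily_estimates(
    rates: pd.DataFrame,
    segments: Sequence[Segment],
    areas: Sequence[ExtrapolationArea],
) -> list[DailyAreaEstimate]:
    """Extrapolate every (area, date) cell from a segment-day rate table.

    Dates are the union of dates present in ``rates``; each area is
    evaluated on every such date so that coverage gaps surface as missing
    cells rather than vanish.
    """
    seg_area = {s.segment_id: s.extrapolation_area_id for s in segments}
    unknown = set(rates["segment_id"]) - set(seg_area)
    if unknown:
        raise KeyError(f"rates reference segments with no area assignment: {sorted(unknown)}")
    dates = sorted(set(rates["date"]))
    out: list[DailyAreaEstimate] = []
    for area in areas:
        area_rates = rates[rates["segment_id"].map(seg_area) == area.area_id]
        for date in dates:
            day = area_rates[area_rates["date"] == date]
            out.extend(extrapolate_day(day, area, date))
    return out


def total_deposition(estimates: Iterable[DailyAreaEstimate]) -> TotalDeposition:
    """Sum habitat-day estimates into the final deposition total.

    Missing cells are counted and logged but contribute nothing; the caller
    can judge from ``n_missing_cells`` how complete the coverage was.
    """
    rows = []
    total = 0.0
    n_missing = 0
    for est in estimates:
        rows.append(
            {
                "area_id": est.area_id,
                "date": est.date,
                "habitat": est.habitat_label,
                "mean_rate": est.mean_rate,
                "n_segments": est.n_segments,
                "birds": est.extrapolated_birds,
                "missing": est.missing,
            }
        )
        if est.missing:
            n_missing += 1
        else:
            total += est.extrapolated_birds
    if n_missing:
        logger.info("total_deposition: %d habitat-day cell(s) missing", n_missing)
    breakdown = pd.DataFrame(
        rows,
        columns=["area_id", "date", "habitat", "mean_rate", "n_segments", "birds", "missing"],
    )
    return TotalDeposition(total_birds=total, n_missing_cells=n_missing, breakdown=breakdown)
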