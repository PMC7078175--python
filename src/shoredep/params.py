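"""Habitat detection parameters and packaged reference tables.

The deposition estimator needs, for each shoreline habitat, two pieces of
information estimated from field trials:

* **searcher efficiency** ``E`` — the probability that a carcass present on a
  segment at search time is actually found and collected, and
* a **carcass persistence curve** ``P_n`` — the probability that a carcass
  deposited ``n`` days before the next search is still present (not lost to
  scavenging, burial or decomposition) when that search happens.

The values packaged here (``data/table1.csv``) are the beach- and
marsh-habitat values estimated for the northern Gulf of Mexico and used in
the Deepwater Horizon shoreline injury assessment.  A second fixture
(``data/table3.csv``) holds carcass counts from thirteen Gulf shoreline
segments that were searched on four consecutive days — the best available
picture of how day-to-day deposition actually fluctuates.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "PersistenceCurve",
    "HabitatParams",
    "ConsecutiveSearchTable",
    "load_table1",
    "load_table3",
    "summarize_daily_counts",
]


@dataclass(frozen=True)
class PersistenceCurve:
    """Carcass persistence probabilities indexed by integer lag in days.

    ``values[n]`` is the probability that a carcass deposited ``n`` days
    before the next search persists until that search.  Lag 0 (deposition on
    the search day itself) always persists, so ``values[0]`` must be exactly
    1.  Persistence cannot recover with time, so the curve is non-increasing.

    Curves are tabulated, not parametric: requesting a lag beyond the last
    tabulated value is an error rather than an extrapolation.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) == 0:
            raise ValueError("persistence curve needs at least the lag-0 entry")
        if vals[0] != 1.0:
            raise ValueError(f"P_0 must be exactly 1.0, got {vals[0]}")
        for n, v in enumerate(vals):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"P_{n}={v} is not a probability")
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError("persistence probabilities must be non-increasing in lag")

    @property
    def n_max(self) -> int:
        """Largest tabulated lag (days)."""
        return len(self.values) - 1

    def __getitem__(self, n: int) -> float:
        if not (0 <= n <= self.n_max):
            raise ValueError(
                f"lag {n} outside tabulated support 0..{self.n_max}; "
                "the curve is not extrapolated"
            )
        return self.values[n]

    def head_sum(self, s: int) -> float:
        """Sum of the first ``s`` probabilities, lags 0..s-1."""
        if not (1 <= s <= self.n_max + 1):
            raise ValueError(
                f"interval length {s} outside curve support (1..{self.n_max + 1})"
            )
        return float(sum(self.values[:s]))


@dataclass(frozen=True)
class HabitatParams:
    """Searcher efficiency paired with a persistence curve for one habitat."""

    habitat_label: str
    searcher_efficiency: float
    persistence: PersistenceCurve

    def __post_init__(self) -> None:
        e = float(self.searcher_efficiency)
        object.__setattr__(self, "searcher_efficiency", e)
        if not (0.0 < e <= 1.0):
            raise ValueError(f"searcher efficiency must be in (0, 1], got {e}")


@dataclass(frozen=True)
class ConsecutiveSearchTable:
    """Daily carcass counts from segments searched on consecutive days."""

    counts: Mapping[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        for seg, row in self.counts.items():
            if len(row) != 4:
                raise ValueError(f"segment {seg!r}: expected 4 daily counts, got {len(row)}")
            if any((not float(c).is_integer()) or c < 0 for c in row):
                raise ValueError(f"segment {seg!r}: counts must be non-negative integers")

    @property
    def segments(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def total(self) -> int:
        return int(sum(sum(row) for row in self.counts.values()))


def _data_path(name: str):
    return resources.files("shoredep").joinpath("data", name)


def load_table1() -> dict[str, HabitatParams]:
    """Load the packaged Gulf of Mexico habitat parameters.

    Returns a mapping with exactly two entries, ``"beach"`` and ``"marsh"``,
    each carrying a searcher efficiency and a 12-lag persistence curve
    (lags 0..11 days, supporting search intervals up to 12 days).
    """
    try:
        with _data_path("table1.csv").open("r", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        eff_row = next(r for r in rows if r["n"] == "E")
        lag_rows = sorted((r for r in rows if r["n"] != "E"), key=lambda r: int(r["n"]))
        lags = [int(r["n"]) for r in lag_rows]
        if lags != list(range(len(lags))):
            raise ValueError(f"lags are not contiguous from 0: {lags}")
        out: dict[str, HabitatParams] = {}
        for habitat in ("beach", "marsh"):
            col = f"{habitat}_persistence"
            curve = PersistenceCurve(tuple(float(r[col]) for r in lag_rows))
            out[habitat] = HabitatParams(habitat, float(eff_row[col]), curve)
        return out
    except (KeyError, StopIteration, TypeError, ValueError) as exc:
        raise ValueError(f"packaged habitat parameter table is corrupted: {exc}") from exc


def load_table3() -> ConsecutiveSearchTable:
    """Load the packaged consecutive-search carcass counts (13 segments x 4 days)."""
    try:
        with _data_path("table3.csv").open("r", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        counts = {
            r["segment"]: tuple(int(r[f"day{d}"]) for d in range(1, 5)) for r in rows
        }
        table = ConsecutiveSearchTable(counts)
        if len(table.segments) != 13:
            raise ValueError(f"expected 13 segments, got {len(table.segments)}")
        return table
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"packaged consecutive-search table is corrupted: {exc}") from exc


def summarize_daily_counts(table: ConsecutiveSearchTable) -> pd.DataFrame:
    """Per-segment mean and range (max minus min) of the daily carcass counts.

    A large range relative to the mean indicates deposition that fluctuates
    strongly between days, i.e. a departure from the constant-deposition
    assumption built into the interval estimator.
    """
    recs = [
        {
            "segment": seg,
            "mean_daily": sum(row) / len(row),
            "range": max(row) - min(row),
        }
        for seg, row in table.counts.items()
    ]
    return pd.DataFrame.from_records(recs, columns=["segment", "mean_daily", "range"])
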