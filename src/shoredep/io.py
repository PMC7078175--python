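"""CSV input/output and synthetic search-record generation.

File schemas (comma-separated, header required, UTF-8):

* ``search_records.csv``: ``segment_id,date,habitat,length_km,collected,old``
  — one row per search of a segment.  ``old`` may be blank (treated as 0
  with a logged notice).
* ``areas.csv``: ``area_id,habitat,total_length_km`` — one row per
  (area, habitat) with the total shoreline length to extrapolate over.
* ``params.csv``: same schema as the packaged ``table1.csv`` — a lag column
  ``n`` plus one ``<habitat>_persistence`` column per habitat, with a
  leading ``E`` row carrying the searcher efficiencies.

Consecutive searches of a segment define search intervals with
``s = exact day difference`` (Monday to Friday is a 4-day interval); the
first search of a segment opens no interval.
"""
from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .estimator import SearchInterval
from .params import HabitatParams, PersistenceCurve
from .simulator import simulate_interval, trial_rng

__all__ = [
    "SearchRecordRow",
    "SyntheticScenario",
    "read_search_records",
    "write_search_records",
    "read_areas",
    "read_params",
    "generate_synthetic_records",
]

logger = logging.getLogger("shoredep")

RECORD_FIELDS = ["segment_id", "date", "habitat", "length_km", "collected", "old"]


@dataclass(frozen=True)
class SearchRecordRow:
    segment_id: str
    date: _dt.date
    habitat: str
    length_km: float
    collected: int
    old: int


def _parse_record(row: Mapping[str, str], lineno: int, errors: list[str]) -> SearchRecordRow | None:
    try:
        date = _dt.date.fromisoformat(row["date"].strip())
    except (KeyError, ValueError):
        errors.append(f"line {lineno}: unparseable date {row.get('date')!r}")
        return None
    try:
        length = float(row["length_km"])
        collected = int(row["collected"])
        old_raw = (row.get("old") or "").strip()
        if old_raw == "":
            logger.info("line %d: missing old-carcass count, treated as 0", lineno)
            old = 0
        else:
            old = int(old_raw)
    except (KeyError, ValueError) as exc:
        errors.append(f"line {lineno}: bad numeric field ({exc})")
        return None
    if length <= 0:
        errors.append(f"line {lineno}: segment length must be positive, got {length}")
        return None
    if collected < 0 or old < 0:
        errors.append(f"line {lineno}: counts must be non-negative")
        return None
    if old > collected:
        errors.append(f"line {lineno}: old carcasses ({old}) exceed collected ({collected})")
        return None
    return SearchRecordRow(
        segment_id=row["segment_id"].strip(),
        date=date,
        habitat=row["habitat"].strip(),
        length_km=length,
        collected=collected,
        old=old,
    )


def read_search_records(
    source: str | Path | TextIO,
) -> tuple[list[SearchRecordRow], list[SearchInterval]]:
    """Read and validate a search-record CSV; derive the search intervals.

    Raises ``ValueError`` listing every offending line if any row fails
    validation (bad dates, negative counts, old > collected, duplicate
    (segment, date), inconsistent per-segment habitat or length).
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_search_records(fh)
    reader = csv.DictReader(source)
    if reader.fieldnames is None or not set(RECORD_FIELDS[:5]) <= set(reader.fieldnames):
        raise ValueError(
            f"search-record CSV must have columns {RECORD_FIELDS} "
            f"(got {reader.fieldnames})"
        )
    errors: list[str] = []
    rows: list[SearchRecordRow] = []
    seen: set[tuple[str, _dt.date]] = set()
    for lineno, raw in enumerate(reader, start=2):
        rec = _parse_record(raw, lineno, errors)
        if rec is None:
            continue
        key = (rec.segment_id, rec.date)
        if key in seen:
            errors.append(f"line {lineno}: duplicate search of {rec.segment_id!r} on {rec.date}")
            continue
        seen.add(key)
        rows.append(rec)
    if errors:
        raise ValueError("invalid search-record file:\n" + "\n".join(errors))

    by_segment: dict[str, list[SearchRecordRow]] = {}
    for rec in rows:
        by_segment.setdefault(rec.segment_id, []).append(rec)
    intervals: list[SearchInterval] = []
    for seg_id, recs in by_segment.items():
        recs = sorted(recs, key=lambda r: r.date)
        if len({r.habitat for r in recs}) > 1 or len({r.length_km for r in recs}) > 1:
            raise ValueError(
                f"segment {seg_id!r}: habitat/length must be consistent across searches"
            )
        for prev, cur in zip(recs, recs[1:]):
            intervals.append(
                SearchInterval(
                    segment_id=seg_id,
                    habitat_label=cur.habitat,
                    interval_length_s=(cur.date - prev.date).days,
                    n_collected=cur.collected,
                    n_old=cur.old,
                    segment_length_L=cur.length_km,
                    end_date=cur.date,
                )
            )
    return rows, intervals


def write_search_records(rows: Iterable[SearchRecordRow], dest: str | Path | TextIO) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            write_search_records(rows, fh)
        return
    writer = csv.writer(dest)
    writer.writerow(RECORD_FIELDS)
    for r in rows:
        writer.writerow(
            [r.segment_id, r.date.isoformat(), r.habitat, r.length_km, r.collected, r.old]
        )


def read_areas(source: str | Path) -> dict[str, dict[str, float]]:
    """Read areas.csv into {area_id: {habitat: total_length_km}}."""
    df = pd.read_csv(source)
    required = {"area_id", "habitat", "total_length_km"}
    if not required <= set(df.columns):
        raise ValueError(f"areas CSV must have columns {sorted(required)}")
    out: dict[str, dict[str, float]] = {}
    for rec in df.itertuples(index=False):
        out.setdefault(str(rec.area_id), {})[str(rec.habitat)] = float(rec.total_length_km)
    return out


def read_params(source: str | Path) -> dict[str, HabitatParams]:
    """Read a habitat-parameter CSV (same schema as the packaged table1.csv)."""
    with open(source, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    if not rows or "n" not in rows[0]:
        raise ValueError("parameter CSV must have an 'n' column")
    habitats = [c[: -len("_persistence")] for c in rows[0] if c.endswith("_persistence")]
    if not habitats:
        raise ValueError("parameter CSV has no <habitat>_persistence columns")
    eff_row = next((r for r in rows if r["n"] == "E"), None)
    if eff_row is None:
        raise ValueError("parameter CSV is missing the efficiency row (n == 'E')")
    lag_rows = sorted((r for r in rows if r["n"] != "E"), key=lambda r: int(r["n"]))
    out = {}
    for h in habitats:
        col = f"{h}_persistence"
        curve = PersistenceCurve(tuple(float(r[col]) for r in lag_rows))
        out[h] = HabitatParams(h, float(eff_row[col]), curve)
    return out


@dataclass(frozen=True)
class SyntheticScenario:
    """Configuration for generating paired search records and ground truth.

    Every segment receives a deterministic ``birds_per_day`` deposition
    (constant pattern) and a regular search schedule: day 0, then every
    ``search_interval_s`` days through ``period_days``.  Carcass counts are
    drawn through the simulator's persistence-then-detection process.
    """

    segments_per_habitat: Mapping[str, int]
    params_by_habitat: Mapping[str, HabitatParams]
    search_interval_s: int
    birds_per_day: int
    seed: int
    period_days: int = 12
    segment_length_km: float = 1.0
    start_date: _dt.date = _dt.date(2010, 8, 1)

    def __post_init__(self) -> None:
        if self.search_interval_s < 1 or self.period_days % self.search_interval_s != 0:
            raise ValueError("search interval must divide the period")
        if self.birds_per_day < 0:
            raise ValueError("deposition must be non-negative")
        missing = set(self.segments_per_habitat) - set(self.params_by_habitat)
        if missing:
            raise ValueError(f"no parameters for habitats {sorted(missing)}")


def generate_synthetic_records(
    scenario: SyntheticScenario,
) -> tuple[list[SearchRecordRow], pd.DataFrame]:
    """Generate search records with a paired per-segment-day truth table.

    The truth table (columns ``segment_id, date, deposited``) covers days
    1..period after the opening search, so its total is the known deposited
    count the estimation pipeline should recover.  Output is deterministic
    in the scenario seed.
    """
    rows: list[SearchRecordRow] = []
    truth: list[dict] = []
    s = scenario.search_interval_s
    seg_index = 0
    for habitat in sorted(scenario.segments_per_habitat):
        params = scenario.params_by_habitat[habitat]
        for i in range(scenario.segments_per_habitat[habitat]):
            seg_id = f"{habitat}-{i:03d}"
            rng = trial_rng(scenario.seed, seg_index)
            seg_index += 1
            # opening search: nothing deposited beforehand
            rows.append(
                SearchRecordRow(
                    seg_id, scenario.start_date, habitat,
                    scenario.segment_length_km, 0, 0,
                )
            )
            for k in range(scenario.period_days // s):
                deposits_by_lag = [scenario.birds_per_day] * s
                n_c = simulate_interval(deposits_by_lag, params, rng)
                search_date = scenario.start_date + _dt.timedelta(days=(k + 1) * s)
                rows.append(
                    SearchRecordRow(
                        seg_id, search_date, habitat,
                        scenario.segment_length_km, n_c, 0,
                    )
                )
            for d in range(1, scenario.period_days + 1):
                truth.append(
                    {
                        "segment_id": seg_id,
                        "date": scenario.start_date + _dt.timedelta(days=d),
                        "deposited": scenario.birds_per_day,
                    }
                )
    return rows, pd.DataFrame(truth, columns=["segment_id", "date", "deposited"])
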