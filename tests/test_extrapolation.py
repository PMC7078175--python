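import datetime as dt

import numpy as np
import pandas as pd
import pytest

from shoredep import (
    ExtrapolationArea,
    SearchInterval,
    Segment,
    area_daily_estimates,
    daily_rates,
    extrapolate_day,
    total_deposition,
)

DAY = dt.date(2010, 8, 7)


def rates_frame(rows):
    return pd.DataFrame(rows, columns=["segment_id", "date", "habitat", "rate_birds_per_km"])


def interval(seg, s, collected, end, habitat="beach", length=1.0):
    return SearchInterval(seg, habitat, s, collected, 0, length, end_date=end)


class TestDailyRates:
    def test_interval_rate_is_carried_by_every_covered_day(self, table1):
        ivs = [interval("s1", 4, 10, dt.date(2010, 8, 10))]
        rates = daily_rates(ivs, table1, max_interval=5)
        assert len(rates) == 4
        assert set(rates["date"]) == {dt.date(2010, 8, d) for d in (7, 8, 9, 10)}
        assert rates["rate_birds_per_km"].nunique() == 1

    def test_interval_longer_than_max_is_disqualified(self, table1):
        ivs = [interval("s1", 6, 10, dt.date(2010, 8, 10))]
        assert daily_rates(ivs, table1, max_interval=5).empty

    def test_overlapping_intervals_rejected(self, table1):
        ivs = [
            interval("s1", 4, 3, dt.date(2010, 8, 10)),
            interval("s1", 4, 3, dt.date(2010, 8, 12)),  # covers 8/9-8/12, overlaps
        ]
        with pytest.raises(ValueError):
            daily_rates(ivs, table1, max_interval=5)

    def test_segment_day_row_count_matches_qualifying_segments(self, table1):
        """Only segments with a qualifying interval on a day contribute rows."""
        ivs = [interval(f"s{i}", 1, 1, DAY) for i in range(27)] + [
            interval(f"t{i}", 6, 1, DAY) for i in range(87)
        ]
        rates = daily_rates(ivs, table1, max_interval=5)
        assert len(rates[rates["date"] == DAY]) == 27


class TestExtrapolateDay:
    def test_worked_beach_marsh_example(self):
        """25 beach rates averaging 0.13 birds/km over 116.5 km of beach give
        15.15 birds; two zero marsh rates give zero marsh deposition."""
        beach_rates = [0.0] * 10 + [
            0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50,
            0.10, 0.10, 0.10, 0.10, 0.10,
        ]
        assert np.mean(beach_rates) == pytest.approx(0.13)
        rows = [(f"b{i}", DAY, "beach", r) for i, r in enumerate(beach_rates)]
        rows += [("m0", DAY, "marsh", 0.0), ("m1", DAY, "marsh", 0.0)]
        area = ExtrapolationArea("MS-AL", {"beach": 116.5, "marsh": 40.0})
        ests = {e.habitat_label: e for e in extrapolate_day(rates_frame(rows), area, DAY)}
        assert ests["beach"].extrapolated_birds == pytest.approx(15.15, abs=0.01)
        assert ests["beach"].n_segments == 25
        assert ests["marsh"].extrapolated_birds == 0.0

    def test_self_extrapolation_identity(self):
        rows = [("b0", DAY, "beach", 0.4)]
        area = ExtrapolationArea("A", {"beach": 1.0})
        (est,) = extrapolate_day(rates_frame(rows), area, DAY)
        assert est.extrapolated_birds == pytest.approx(0.4)

    def test_mean_is_unweighted_across_segments(self):
        """Duplicating a contributing segment shifts the mean by count, not
        by shoreline length."""
        area = ExtrapolationArea("A", {"beach": 10.0})
        base = rates_frame([("b0", DAY, "beach", 0.2), ("b1", DAY, "beach", 0.4)])
        dup = rates_frame(
            [("b0", DAY, "beach", 0.2), ("b1", DAY, "beach", 0.4), ("b2", DAY, "beach", 0.4)]
        )
        (e1,) = extrapolate_day(base, area, DAY)
        (e2,) = extrapolate_day(dup, area, DAY)
        assert e1.mean_rate == pytest.approx(0.3)
        assert e2.mean_rate == pytest.approx(1.0 / 3)

    def test_habitat_without_data_is_flagged_missing(self):
        area = ExtrapolationArea("A", {"beach": 5.0, "marsh": 5.0})
        ests = {
            e.habitat_label: e
            for e in extrapolate_day(rates_frame([("b0", DAY, "beach", 0.1)]), area, DAY)
        }
        assert not ests["beach"].missing
        assert ests["marsh"].missing and np.isnan(ests["marsh"].extrapolated_birds)


class TestTotals:
    def test_empty_input(self):
        result = total_deposition([])
        assert result.total_birds == 0.0 and result.n_missing_cells == 0

    def test_additivity_over_areas(self, table1):
        ivs = [
            interval("a0", 1, 5, DAY),
            interval("b0", 1, 3, DAY),
        ]
        rates = daily_rates(ivs, table1, max_interval=5)
        segments = [
            Segment("a0", "beach", 1.0, "A"),
            Segment("b0", "beach", 1.0, "B"),
        ]
        areas = [
            ExtrapolationArea("A", {"beach": 2.0}),
            ExtrapolationArea("B", {"beach": 3.0}),
        ]
        combined = total_deposition(area_daily_estimates(rates, segments, areas))
        per_area = [
            total_deposition(area_daily_estimates(rates, segments, [a])).total_birds
            for a in areas
        ]
        assert combined.total_birds == pytest.approx(sum(per_area))

    def test_missing_cells_counted_not_zeroed(self):
        area = ExtrapolationArea("A", {"beach": 5.0, "marsh": 5.0})
        ests = extrapolate_day(rates_frame([("b0", DAY, "beach", 0.1)]), area, DAY)
        result = total_deposition(ests)
        assert result.n_missing_cells == 1
        assert result.total_birds == pytest.approx(0.5)

    def test_exact_recovery_under_perfect_detection(self, ideal):
        """Daily searches, E=1, P=1: the pipeline returns the true total."""
        start = dt.date(2010, 8, 1)
        ivs = [
            interval(f"s{i}", 1, 7, start + dt.timedelta(days=d), habitat="ideal")
            for i in range(3)
            for d in range(1, 5)
        ]
        rates = daily_rates(ivs, {"ideal": ideal}, max_interval=1)
        segments = [Segment(f"s{i}", "ideal", 1.0, "A") for i in range(3)]
        areas = [ExtrapolationArea("A", {"ideal": 3.0})]
        result = total_deposition(area_daily_estimates(rates, segments, areas))
        # 3 segments x 4 days x 7 birds
        assert result.total_birds == pytest.approx(84.0)
        assert result.n_missing_cells == 0
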