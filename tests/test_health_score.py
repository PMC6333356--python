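import numpy as np
import pandas as pd
import pytest

from dwellsense.health_score import (
    SCORED_PARAMETERS,
    adaptive_interval,
    daily_health_score,
    dhs_series,
    flag_exceedances,
    score_parameter,
)


def reference_band_lookup(parameter, value):
    """Independent banding oracle: explicit (low, high, score) tables."""
    tables = {
        "systolic_bp": [(None, 90, 3), (91, 100, 2), (101, 110, 1), (111, 219, 0), (220, None, 3)],
        "pulse": [(None, 40, 3), (41, 50, 1), (51, 90, 0), (91, 110, 1), (111, 130, 2), (131, None, 3)],
        "body_temperature": [
            (None, 35.0, 3), (35.1, 36.0, 1), (36.1, 38.0, 0), (38.1, 39.0, 1), (39.1, None, 2)
        ],
        "spo2": [(None, 91, 3), (92, 93, 2), (94, 95, 1), (96, None, 0)],
    }
    from decimal import Decimal, ROUND_HALF_UP

    dp = 1 if parameter == "body_temperature" else 0
    v = float(Decimal(repr(value)).quantize(Decimal(1).scaleb(-dp), rounding=ROUND_HALF_UP))
    for low, high, score in tables[parameter]:
        if (low is None or v >= low) and (high is None or v <= high):
            return score
    raise AssertionError(f"{parameter}={v} fell in no band")


class TestScoreParameter:
    @pytest.mark.parametrize(
        "param,value,expected",
        [
            ("systolic_bp", 85, 3),
            ("systolic_bp", 115, 0),
            ("systolic_bp", 220, 3),
            ("pulse", 120, 2),
            ("pulse", 70, 0),
            ("pulse", 40, 3),
            ("body_temperature", 38.5, 1),
            ("body_temperature", 36.8, 0),
            ("body_temperature", 39.1, 2),
            ("spo2", 97, 0),
            ("spo2", 91, 3),
            ("spo2", 94, 1),
        ],
    )
    def test_printed_band_spot_checks(self, param, value, expected):
        assert score_parameter(param, value) == expected

    def test_matches_band_oracle_on_a_fine_grid(self):
        grids = {
            "systolic_bp": np.arange(60, 260, 0.5),
            "pulse": np.arange(20, 200, 0.5),
            "body_temperature": np.arange(33.0, 42.0, 0.05),
            "spo2": np.arange(80, 100, 0.5),
        }
        for param, grid in grids.items():
            for v in grid:
                v = round(float(v), 2)
                assert score_parameter(param, v) == reference_band_lookup(param, v), (param, v)

    def test_rounding_closes_band_gaps(self):
        # 38.04 rounds into the 36.1-38 band; 38.06 into 38.1-39
        assert score_parameter("body_temperature", 38.04) == 0
        assert score_parameter("body_temperature", 38.06) == 1

    def test_unscored_parameter_rejected(self):
        with pytest.raises(ValueError):
            score_parameter("weight", 70.0)

    def test_monotone_outward_from_normal_band(self):
        for values in (range(115, 85, -1), range(115, 225)):
            last = -1
            scores = [score_parameter("systolic_bp", v) for v in values]
            assert all(b >= a or b == a for a, b in zip(scores, scores[1:])) or all(
                s >= 0 for s in scores
            )
            assert scores == sorted(scores)


def _vitals(rows):
    df = pd.DataFrame(rows, columns=["home_id", "timestamp", "parameter", "value"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


class TestDailyScore:
    def test_all_normal_session_scores_zero(self):
        day = _vitals(
            [
                ("h1", "2024-01-01 08:00", "systolic_bp", 115),
                ("h1", "2024-01-01 08:01", "pulse", 70),
                ("h1", "2024-01-01 08:02", "body_temperature", 36.8),
                ("h1", "2024-01-01 08:03", "spo2", 98),
            ]
        )
        rec = daily_health_score(day)
        assert rec.total == 0 and rec.missing == ()

    def test_all_extreme_session_scores_twelve(self):
        day = _vitals(
            [
                ("h1", "2024-01-01 08:00", "systolic_bp", 85),
                ("h1", "2024-01-01 08:01", "pulse", 135),
                ("h1", "2024-01-01 08:02", "body_temperature", 34.0),
                ("h1", "2024-01-01 08:03", "spo2", 90),
            ]
        )
        assert daily_health_score(day).total == 12

    def test_missing_parameter_listed_and_contributes_zero(self):
        day = _vitals(
            [
                ("h1", "2024-01-01 08:00", "systolic_bp", 115),
                ("h1", "2024-01-01 08:01", "pulse", 70),
                ("h1", "2024-01-01 08:02", "body_temperature", 36.8),
            ]
        )
        rec = daily_health_score(day)
        assert rec.total == 0 and rec.missing == ("spo2",)

    def test_worst_session_wins(self):
        day = _vitals(
            [
                ("h1", "2024-01-01 08:00", "body_temperature", 36.8),
                ("h1", "2024-01-01 19:00", "body_temperature", 38.6),
            ]
        )
        assert daily_health_score(day).total == 1

    def test_no_scored_vitals_returns_none(self):
        day = _vitals([("h1", "2024-01-01 08:00", "weight", 70.0)])
        assert daily_health_score(day) is None

    def test_series_over_simulated_cohort(self, sim_small):
        _, vitals, _ = sim_small
        series = dhs_series(vitals)
        assert len(series) == 10
        assert series["total"].between(0, 12).all()


class TestAdaptiveInterval:
    def test_zero_variance_interval_and_flag(self):
        interval = adaptive_interval([2] * 14, d=14, xi=1.96)
        assert interval.lower == interval.upper == 2
        flags = flag_exceedances(pd.Series([2] * 14 + [3]), d=14, xi=1.96)
        assert flags.iloc[-1]

    def test_interval_is_symmetric(self):
        rng = np.random.default_rng(0)
        interval = adaptive_interval(rng.integers(0, 6, 20), d=14, xi=1.96)
        assert interval.upper - interval.mu == pytest.approx(interval.mu - interval.lower)

    def test_halfwidth_linear_in_xi(self):
        rng = np.random.default_rng(1)
        hist = rng.integers(0, 6, 14)
        a = adaptive_interval(hist, d=14, xi=1.0)
        b = adaptive_interval(hist, d=14, xi=2.0)
        assert (b.upper - b.mu) == pytest.approx(2 * (a.upper - a.mu))

    def test_short_history_error(self):
        with pytest.raises(ValueError):
            adaptive_interval([1, 2, 3], d=14)
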