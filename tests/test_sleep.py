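import numpy as np
import pandas as pd
import pytest

import dwellsense as dw
from dwellsense.sleep import (
    AWAY,
    OUT_OF_BED,
    RESTLESS,
    SHORT_SLEEP,
    SLEEP_GOOD,
    SLEEP_MODERATE,
    VALID,
    WANDERING,
    BedEpoch,
    SleepNight,
    StageThresholds,
    adaptive_boundaries,
    detect_disturbance,
    label_sleep_states,
    preprocess_bed_epochs,
)

T = pd.Timestamp


def _epochs(*pairs):
    return [(T(a), T(b)) for a, b in pairs]


def _no_ambient():
    df = pd.DataFrame(columns=["home_id", "timestamp", "viewpoint", "state", "value"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def _ambient(rows):
    df = pd.DataFrame(rows, columns=["home_id", "timestamp", "viewpoint", "state", "value"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


class TestThresholds:
    def test_derived_stage_thresholds(self):
        thr = StageThresholds()
        assert thr.onset_minutes == pytest.approx(21.5)  # mean(1+10, 7+25)
        assert thr.restless_minutes == 11  # 1 + 10


class TestPreprocessing:
    def test_short_gap_is_merged(self):
        raw = _epochs(
            ("2024-01-01 22:00", "2024-01-01 23:30"),
            ("2024-01-01 23:31", "2024-01-02 06:00"),
        )
        clean = preprocess_bed_epochs(raw)
        assert len(clean) == 1
        assert clean[0].state == "in"
        assert clean[0].minutes == pytest.approx(8 * 60)

    def test_isolated_blip_is_removed(self):
        raw = _epochs(("2024-01-01 20:00", "2024-01-01 20:00:30"))
        assert preprocess_bed_epochs(raw) == []

    def test_strict_alternation_with_positive_durations(self):
        raw = _epochs(
            ("2024-01-01 22:00", "2024-01-02 01:00"),
            ("2024-01-02 01:20", "2024-01-02 03:00"),
            ("2024-01-02 03:10", "2024-01-02 07:00"),
        )
        clean = preprocess_bed_epochs(raw)
        states = [e.state for e in clean]
        assert states == ["in", "out", "in", "out", "in"]
        assert all(e.minutes > 0 for e in clean)

    def test_no_events_gives_empty(self):
        assert preprocess_bed_epochs([]) == []


def _in(a, b):
    return BedEpoch(start=T(a), end=T(b), state="in")


def _out(a, b):
    return BedEpoch(start=T(a), end=T(b), state="out")


class TestLabelling:
    def test_onset_at_first_sufficiently_long_epoch(self):
        clean = [_in("2024-01-01 22:00", "2024-01-01 22:30")]  # 30 min > 21.5
        night = label_sleep_states(clean, _no_ambient(), "2024-01-01")
        assert night.onset == T("2024-01-01 22:00")

    def test_short_epoch_after_onset_is_restless(self):
        clean = [
            _in("2024-01-01 22:00", "2024-01-02 00:00"),
            _out("2024-01-02 00:00", "2024-01-02 00:05"),
            _in("2024-01-02 00:05", "2024-01-02 00:13"),  # 8 min < 11
            _out("2024-01-02 00:13", "2024-01-02 00:20"),
            _in("2024-01-02 00:20", "2024-01-02 06:00"),
        ]
        night = label_sleep_states(clean, _no_ambient(), "2024-01-01")
        states = [s for _, _, s in night.blocks]
        assert RESTLESS in states
        assert night.restless_minutes == pytest.approx(8)

    def test_long_epochs_are_good_short_are_moderate(self):
        clean = [
            _in("2024-01-01 22:00", "2024-01-02 00:00"),  # 120 min -> good
            _out("2024-01-02 00:00", "2024-01-02 00:10"),
            _in("2024-01-02 00:10", "2024-01-02 01:00"),  # 50 min -> moderate
        ]
        night = label_sleep_states(clean, _no_ambient(), "2024-01-01")
        states = [s for _, _, s in night.blocks]
        assert states[0] == SLEEP_GOOD and states[2] == SLEEP_MODERATE

    def test_out_epoch_with_multichannel_activity_is_wandering(self):
        clean = [
            _in("2024-01-01 22:00", "2024-01-02 01:00"),
            _out("2024-01-02 01:00", "2024-01-02 01:40"),
            _in("2024-01-02 01:40", "2024-01-02 06:30"),
        ]
        rows = [
            ("h1", "2024-01-02 01:05", "hallway_pir", "on", np.nan),
            ("h1", "2024-01-02 01:10", "hallway_pir", "on", np.nan),
            ("h1", "2024-01-02 01:15", "kitchen_motion", "on", np.nan),
            ("h1", "2024-01-02 01:20", "hallway_pir", "on", np.nan),
            ("h1", "2024-01-02 01:30", "kitchen_motion", "on", np.nan),
        ]
        night = label_sleep_states(clean, _ambient(rows), "2024-01-01")
        assert [s for _, _, s in night.blocks][1] == WANDERING

    def test_bathroom_only_excursion_is_out_of_bed(self):
        clean = [
            _in("2024-01-01 22:00", "2024-01-02 01:00"),
            _out("2024-01-02 01:00", "2024-01-02 01:10"),
            _in("2024-01-02 01:10", "2024-01-02 06:30"),
        ]
        rows = [
            ("h1", "2024-01-02 01:02", "bathroom_door_motion", "on", np.nan),
            ("h1", "2024-01-02 01:08", "bathroom_door_motion", "on", np.nan),
        ]
        night = label_sleep_states(clean, _ambient(rows), "2024-01-01")
        assert [s for _, _, s in night.blocks][1] == OUT_OF_BED

    def test_no_bed_data_is_away(self):
        night = label_sleep_states([], _no_ambient(), "2024-01-01")
        assert night.validity == AWAY

    def test_under_three_hours_is_short_sleep(self):
        clean = [_in("2024-01-01 23:00", "2024-01-02 01:30")]  # 2.5 h
        night = label_sleep_states(clean, _no_ambient(), "2024-01-01")
        assert night.validity == SHORT_SLEEP

    def test_blocks_cover_onset_to_offset(self):
        clean = [
            _in("2024-01-01 22:00", "2024-01-02 01:00"),
            _out("2024-01-02 01:00", "2024-01-02 01:10"),
            _in("2024-01-02 01:10", "2024-01-02 06:30"),
        ]
        night = label_sleep_states(clean, _no_ambient(), "2024-01-01")
        total = sum((b1 - b0).total_seconds() / 60 for b0, b1, _ in night.blocks)
        span = (night.offset - night.onset).total_seconds() / 60
        assert total == pytest.approx(span)

    def test_labelling_is_deterministic(self, sim_small):
        events, _, _ = sim_small
        a = dw.analyse_night(events, "2024-01-03")
        b = dw.analyse_night(events, "2024-01-03")
        assert a == b


def _night(sleep_min, restless_min, wandering_min=0.0, validity=VALID):
    onset = T("2024-01-01 22:00")
    blocks = [(onset, onset + pd.Timedelta(minutes=sleep_min), SLEEP_GOOD)]
    t = blocks[0][1]
    if restless_min:
        blocks.append((t, t + pd.Timedelta(minutes=restless_min), RESTLESS))
        t = blocks[-1][1]
    if wandering_min:
        blocks.append((t, t + pd.Timedelta(minutes=wandering_min), WANDERING))
        t = blocks[-1][1]
    return SleepNight(
        date=T("2024-01-01"), onset=onset, offset=t, blocks=blocks, validity=validity
    )


class TestBoundariesAndDisturbance:
    def test_zero_variance_history_gives_exact_bounds(self):
        history = [_night(420, 10) for _ in range(30)]
        bounds = adaptive_boundaries(history, xi=2.0)
        assert bounds.min_sleep_minutes == pytest.approx(420)
        assert bounds.max_restless_wandering_minutes == pytest.approx(10)

    def test_bounds_widen_with_xi(self):
        rng = np.random.default_rng(0)
        history = [_night(420 + rng.normal(0, 30), 10 + abs(rng.normal(0, 5))) for _ in range(40)]
        b1 = adaptive_boundaries(history, xi=1.0)
        b2 = adaptive_boundaries(history, xi=2.0)
        assert b2.min_sleep_minutes < b1.min_sleep_minutes
        assert b2.max_restless_wandering_minutes > b1.max_restless_wandering_minutes

    def test_too_short_history_is_an_error(self):
        with pytest.raises(ValueError):
            adaptive_boundaries([_night(420, 10) for _ in range(29)])

    def test_disturbance_rules(self):
        history = [_night(420, 10) for _ in range(30)]
        bounds = adaptive_boundaries(history, xi=2.0)
        bounds.min_sleep_minutes = 350.0
        bounds.max_restless_wandering_minutes = 60.0
        assert detect_disturbance(_night(200, 10), bounds) == "disturbed"
        assert detect_disturbance(_night(400, 20), bounds) == "normal"
        assert detect_disturbance(_night(400, 20, 80), bounds) == "disturbed"
        assert detect_disturbance(_night(150, 0, validity=SHORT_SLEEP), bounds) == "excluded"

    def test_injected_disturbances_recovered_with_sensitivity_and_specificity(self, sim_nights):
        events, _, labels = sim_nights
        result = dw.sleep_injection_recovery(events, labels)
        assert result["sensitivity"] >= 0.8
        assert result["specificity"] >= 0.8
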