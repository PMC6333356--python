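import numpy as np
import pandas as pd
import pytest

import dwellsense as dw
from dwellsense.sensor_data import DAYPART_HOURS, DAYPART_VARIANTS, load_records, write_records

HOME = "home001"


class TestLoadRecords:
    def test_well_formed_csv_parses_without_rejections(self, tmp_path):
        p = tmp_path / "events.csv"
        p.write_text(
            "home_id,timestamp,viewpoint,state,value\n"
            "h1,2024-01-01 10:00:00,hallway_pir,on,\n"
            "h1,2024-01-01 10:05:00,bed_pressure,off,\n"
            "h1,2024-01-01 10:01:00,energy_monitor,value,512.5\n"
        )
        frame, report = load_records(p, "events")
        assert len(frame) == 3 and report.n_rejected == 0
        assert frame["timestamp"].is_monotonic_increasing

    def test_unknown_viewpoint_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "events.csv"
        p.write_text(
            "home_id,timestamp,viewpoint,state,value\n"
            "h1,2024-01-01 10:00:00,garage,on,\n"
            "h1,2024-01-01 10:05:00,hallway_pir,on,\n"
        )
        frame, report = load_records(p, "events")
        assert len(frame) == 1
        assert report.n_rejected == 1
        line, reason = report.rejections[0]
        assert line == 2 and "garage" in reason

    def test_empty_file_yields_empty_stream_with_warning(self, tmp_path):
        p = tmp_path / "events.csv"
        p.write_text("")
        frame, report = load_records(p, "events")
        assert frame.empty and report.empty

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_records(tmp_path / "nope.csv", "events")

    def test_vitals_bad_value_rejected(self, tmp_path):
        p = tmp_path / "vitals.csv"
        p.write_text(
            "home_id,timestamp,parameter,value\n"
            "h1,2024-01-01 08:00:00,body_temperature,36.8\n"
            "h1,2024-01-01 08:00:00,cholesterol,5.0\n"
        )
        frame, report = load_records(p, "vitals")
        assert len(frame) == 1 and report.n_rejected == 1

    @pytest.mark.parametrize("fmt", ["csv", "jsonl"])
    def test_round_trip(self, sim_small, tmp_path, fmt):
        events, vitals, _ = sim_small
        for frame, kind in ((events, "events"), (vitals, "vitals")):
            p = tmp_path / f"{kind}.{fmt}"
            write_records(frame, p, fmt=fmt)
            back, report = load_records(p, kind)
            assert report.n_rejected == 0
            a = frame.reset_index(drop=True)
            b = back.reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b, check_dtype=False)


class TestSimulator:
    def test_identical_config_and_seed_is_byte_identical(self, tmp_path):
        cfg = dw.SimulationConfig(n_homes=1, n_days=7, seed=1)
        paths = []
        for i in range(2):
            ev, vi, lab = dw.simulate_cohort(cfg)
            p = tmp_path / f"run{i}"
            p.mkdir()
            write_records(ev, p / "events.csv")
            write_records(vi, p / "vitals.csv")
            lab.to_csv(p / "labels.csv", index=False)
            paths.append(p)
        for name in ("events.csv", "vitals.csv", "labels.csv"):
            assert (paths[0] / name).read_bytes() == (paths[1] / name).read_bytes()

    def test_no_episodes_means_no_flags(self, sim_small):
        _, _, labels = sim_small
        for col in ("uti_episode", "sleep_disturbed", "routine_anomaly", "excluded_night"):
            assert not labels[col].any()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            dw.SimulationConfig(n_homes=0, n_days=7, seed=1).validate()
        bad = dw.SimulationConfig(n_homes=1, n_days=7, seed=1)
        bad.rate_profiles["hallway_pir"][0] = -1.0
        with pytest.raises(ValueError):
            bad.validate()

    def test_uti_episode_raises_night_bathroom_counts_and_temperature(self, sim_uti):
        events, vitals, labels = sim_uti
        labels = labels.assign(date=pd.to_datetime(labels["date"]))
        bath = events[events["viewpoint"] == "bathroom_door_motion"].copy()
        # night bathroom firings of day d land between 18:00 d and 12:00 d+1;
        # count the small hours of the following morning
        night = bath[bath["timestamp"].dt.hour < 6]
        night_of = night["timestamp"].dt.normalize() - pd.Timedelta(days=1)
        counts = night_of.value_counts()
        uti_days = set(labels.loc[labels["uti_episode"], "date"])
        routine = [counts.get(d, 0) for d in labels["date"] if d not in uti_days]
        episode = [counts.get(d, 0) for d in uti_days]
        assert np.mean(episode) > np.mean(routine)
        # every episode day has at least one febrile reading
        temps = vitals[vitals["parameter"] == "body_temperature"].copy()
        temps["date"] = temps["timestamp"].dt.normalize()
        by_day = temps.groupby("date")["value"].max()
        assert all(by_day.get(d, 0) > 38.0 for d in uti_days)
        # injected-episode days and only those days are flagged
        starts = (95, 105, 114)
        expected = {
            pd.Timestamp("2024-01-01") + pd.Timedelta(days=s + i)
            for s in starts
            for i in range(3)
        }
        assert uti_days == expected

    def test_hourly_rates_match_configured_poisson_means(self):
        # 200 days, nuisances off; pick channels untouched by day-part variants
        cfg = dw.SimulationConfig(
            n_homes=1,
            n_days=200,
            seed=1,
            nuisance=dw.NuisanceSpec(
                guest_day_prob=0.0,
                missing_gap_prob=0.0,
                spontaneous_disturbance_prob=0.0,
            ),
        )
        events, _, _ = dw.simulate_cohort(cfg)
        checks = [("pillbox_motion", 9), ("front_door", 10), ("front_door", 15)]
        for vp, hour in checks:
            rate = cfg.rate_profiles[vp][hour]
            for part, hours in DAYPART_HOURS.items():
                if hour in hours:
                    for variant in DAYPART_VARIANTS[part]:
                        assert vp not in variant  # untouched by variants
            sel = events[
                (events["viewpoint"] == vp) & (events["timestamp"].dt.hour == hour)
            ]
            mean = len(sel) / cfg.n_days
            se = np.sqrt(rate / cfg.n_days)
            assert abs(mean - rate) < 3 * se + 1e-9
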