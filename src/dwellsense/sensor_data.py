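"""Sensor data model, readers/writers and the synthetic smart-home cohort simulator.

The monitored household carries ten ambient channels ("viewpoints"): two PIR
sensors (hallway, living room), four motion sensors (kitchen, pill box,
bedroom door, bathroom door), two pressure sensors (bed, chair), a front-door
contact and a whole-home energy monitor.  Physiological readings (blood
pressure, pulse, body temperature, SpO2, weight, hydration) arrive in at most
two measurement sessions per day.

Because no public recording of such a cohort exists, this module also ships a
generative simulator that emulates the statistical structure the analytics
depend on: time-of-day activity rhythms, nightly bed-occupancy epochs with
bathroom excursions and turn-over blips, twice-daily vitals, multi-occupancy
nuisances (guests, pets), whole-sensor outage gaps, and injectable clinical
episodes — urinary-tract-infection days (raised night-time bathroom frequency,
night wandering, body temperature above 38 °C) and sleep-disturbance nights.
Ground-truth labels for every injected condition are emitted alongside the
streams so detection algorithms can be scored by injection recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

# Fixed viewpoint order. The first eight are the activity channels used for
# pattern profiling; front_door and energy_monitor are kept out of that path
# (they are dominated by multi-occupancy effects) but participate in the
# 10-sensor daily-routine matrices.
UTI_VIEWPOINTS: tuple[str, ...] = (
    "hallway_pir",
    "living_room_pir",
    "kitchen_motion",
    "pillbox_motion",
    "bedroom_door_motion",
    "bathroom_door_motion",
    "bed_pressure",
    "chair_pressure",
)
VIEWPOINTS: tuple[str, ...] = UTI_VIEWPOINTS + ("front_door", "energy_monitor")

VITAL_PARAMETERS: tuple[str, ...] = (
    "systolic_bp",
    "diastolic_bp",
    "pulse",
    "body_temperature",
    "spo2",
    "weight",
    "hydration",
)

EVENT_COLUMNS = ["home_id", "timestamp", "viewpoint", "state", "value"]
VITAL_COLUMNS = ["home_id", "timestamp", "parameter", "value"]
LABEL_COLUMNS = [
    "home_id",
    "date",
    "uti_episode",
    "sleep_disturbed",
    "routine_anomaly",
    "excluded_night",
]

_TS_FORMAT = "%Y-%m-%d %H:%M:%S"


@dataclass
class ValidationReport:
    """Outcome of parsing a record file: rejected rows are kept, not dropped."""

    n_parsed: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)
    empty: bool = False

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def _parse_events(df: pd.DataFrame, report: ValidationReport) -> pd.DataFrame:
    keep = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        vp = str(row.viewpoint)
        if vp not in VIEWPOINTS:
            report.rejections.append((line, f"unknown viewpoint {vp!r}"))
            continue
        ts = pd.to_datetime(row.timestamp, errors="coerce")
        if pd.isna(ts):
            report.rejections.append((line, f"unparseable timestamp {row.timestamp!r}"))
            continue
        value = float(row.value) if not pd.isna(row.value) else np.nan
        if vp == "energy_monitor" and (np.isnan(value) or value < 0):
            report.rejections.append((line, "energy_monitor requires a non-negative value"))
            continue
        keep.append((str(row.home_id), ts, vp, str(row.state), value))
    out = pd.DataFrame(keep, columns=EVENT_COLUMNS)
    return out.sort_values(["home_id", "timestamp"], kind="stable").reset_index(drop=True)


def _parse_vitals(df: pd.DataFrame, report: ValidationReport) -> pd.DataFrame:
    keep = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        param = str(row.parameter)
        if param not in VITAL_PARAMETERS:
            report.rejections.append((line, f"unknown parameter {param!r}"))
            continue
        ts = pd.to_datetime(row.timestamp, errors="coerce")
        if pd.isna(ts):
            report.rejections.append((line, f"unparseable timestamp {row.timestamp!r}"))
            continue
        try:
            value = float(row.value)
        except (TypeError, ValueError):
            report.rejections.append((line, f"non-numeric value {row.value!r}"))
            continue
        if not np.isfinite(value) or value < 0:
            report.rejections.append((line, f"value {value!r} not finite and non-negative"))
            continue
        keep.append((str(row.home_id), ts, param, value))
    out = pd.DataFrame(keep, columns=VITAL_COLUMNS)
    return out.sort_values(["home_id", "timestamp"], kind="stable").reset_index(drop=True)


def load_records(path: str | Path, kind: str) -> tuple[pd.DataFrame, ValidationReport]:
    """Load an event or vitals file (CSV or JSON-lines) with row-level validation.

    Parameters
    ----------
    path:
        CSV file with the documented columns, or JSON-lines mirroring them.
    kind:
        ``"events"`` or ``"vitals"``.

    Returns
    -------
    (frame, report):
        The parsed, time-sorted records and a :class:`ValidationReport` listing
        every rejected row with its line number and reason.
    """
    path = Path(path)
    if kind not in ("events", "vitals"):
        raise ValueError(f"kind must be 'events' or 'vitals', got {kind!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    columns = EVENT_COLUMNS if kind == "events" else VITAL_COLUMNS
    report = ValidationReport()
    if path.stat().st_size == 0:
        report.empty = True
        empty = pd.DataFrame(columns=columns)
        empty["timestamp"] = pd.to_datetime(empty["timestamp"])
        return empty, report
    if path.suffix in (".jsonl", ".json"):
        raw = pd.read_json(path, lines=True, dtype=False, convert_dates=False)
    else:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        raw = raw.mask(raw == "")
    missing = set(columns) - set(raw.columns)
    if kind == "events" and missing == {"value"}:
        raw = raw.assign(value=np.nan)
        missing = set()
    if missing:
        raise ValueError(f"{path} lacks required columns {sorted(missing)}")
    if raw.empty:
        report.empty = True
        empty = pd.DataFrame(columns=columns)
        empty["timestamp"] = pd.to_datetime(empty["timestamp"])
        return empty, report
    if kind == "events":
        raw["value"] = pd.to_numeric(raw["value"], errors="coerce")
        out = _parse_events(raw, report)
    else:
        out = _parse_vitals(raw, report)
    report.n_parsed = len(out)
    return out, report


def write_records(frame: pd.DataFrame, path: str | Path, fmt: str = "csv") -> Path:
    """Write events/vitals/labels to CSV or JSON-lines with a stable text layout."""
    path = Path(path)
    out = frame.copy()
    if "timestamp" in out.columns:
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(_TS_FORMAT)
    if fmt == "csv":
        out.to_csv(path, index=False)
    elif fmt == "jsonl":
        out.to_json(path, orient="records", lines=True)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


def _default_rate_profiles() -> dict[str, list[float]]:
    """Per-viewpoint mean hourly firing rates for a single older adult at home.

    Chosen to reproduce the qualitative rhythm of a one-person household:
    activity concentrated 07:00-22:00 with meal-time kitchen peaks, twice-daily
    pill-box access, and near-silence at night apart from occasional bedroom /
    bathroom door triggers.  Units: expected activations per hour.
    """
    hallway = [0.05] * 24
    living = [0.05] * 24
    kitchen = [0.02] * 24
    pillbox = [0.0] * 24
    bedroom_door = [0.05] * 24
    bathroom_door = [0.05] * 24
    chair = [0.0] * 24
    front_door = [0.0] * 24
    for h in range(7, 23):
        hallway[h] = 7.0
        living[h] = 8.0
        kitchen[h] = 2.5
        bathroom_door[h] = 1.2
        chair[h] = 3.0
    for h in (8, 13, 18):  # meals
        kitchen[h] = 10.0
    for h in (9, 21):  # medication
        pillbox[h] = 2.0
    for h in (7, 22):  # bedroom transits morning / evening
        bedroom_door[h] = 3.0
    for h in (10, 15):  # errands
        front_door[h] = 0.4
    return {
        "hallway_pir": hallway,
        "living_room_pir": living,
        "kitchen_motion": kitchen,
        "pillbox_motion": pillbox,
        "bedroom_door_motion": bedroom_door,
        "bathroom_door_motion": bathroom_door,
        "chair_pressure": chair,
        "front_door": front_door,
    }


# Recurring behavioural variants per day-part.  Real routines are not a single
# homogeneous pattern but a small repertoire of recurring "views" (a kitchen
# morning vs. a lounge morning, an afternoon nap vs. pottering about, a TV
# evening vs. retiring early).  Each simulated day draws one variant per
# day-part; the multipliers scale the baseline hourly rates of that day-part.
DAYPART_HOURS = {"morning": range(6, 12), "afternoon": range(12, 18), "evening": range(18, 24)}

DAYPART_VARIANTS: dict[str, tuple[dict[str, float], dict[str, float]]] = {
    "morning": (
        {  # busy kitchen morning
            "kitchen_motion": 2.0,
            "hallway_pir": 1.4,
            "living_room_pir": 0.3,
            "chair_pressure": 0.2,
            "bathroom_door_motion": 1.4,
        },
        {  # slow lounge morning
            "kitchen_motion": 0.4,
            "hallway_pir": 0.6,
            "living_room_pir": 2.0,
            "chair_pressure": 2.0,
            "bathroom_door_motion": 0.5,
        },
    ),
    "afternoon": (
        {  # nap in the chair
            "chair_pressure": 2.4,
            "hallway_pir": 0.3,
            "kitchen_motion": 0.3,
            "living_room_pir": 0.5,
        },
        {  # pottering about the house
            "chair_pressure": 0.3,
            "hallway_pir": 1.9,
            "kitchen_motion": 1.8,
            "living_room_pir": 1.3,
        },
    ),
    "evening": (
        {  # television evening
            "living_room_pir": 2.0,
            "chair_pressure": 1.8,
            "kitchen_motion": 0.5,
            "hallway_pir": 0.5,
            "bedroom_door_motion": 0.4,
        },
        {  # retiring early
            "living_room_pir": 0.4,
            "chair_pressure": 0.3,
            "bedroom_door_motion": 2.4,
            "bathroom_door_motion": 1.8,
            "hallway_pir": 1.3,
        },
    ),
}


def _default_vitals_spec() -> dict[str, tuple[float, float]]:
    # (mean, SD) per parameter; units: mmHg, mmHg, bpm, °C, %, kg, a.u.
    return {
        "systolic_bp": (125.0, 8.0),
        "diastolic_bp": (75.0, 6.0),
        "pulse": (72.0, 6.0),
        "body_temperature": (36.7, 0.25),
        "spo2": (97.0, 1.0),
        "weight": (70.0, 0.4),
        "hydration": (50.0, 5.0),
    }


@dataclass
class UTIEpisodeSpec:
    """An injectable UTI symptom episode.

    Night-time bathroom frequency is multiplied, body temperature is elevated,
    and a small amount of night wandering is added (urinary infection in
    dementia commonly presents as nocturnal confusion and wandering, which is
    what makes the activity disturbance visible to shape-based profiling).
    """

    home_id: str
    start_day: int
    duration_days: int = 3
    bathroom_multiplier: float = 3.0
    temperature_c: float = 38.5
    wandering_bouts: int = 2

    def days(self) -> range:
        return range(self.start_day, self.start_day + self.duration_days)


@dataclass
class SleepDisturbanceSpec:
    """An injectable disturbed night: wandering bouts and shortened sleep."""

    home_id: str
    start_day: int
    duration_days: int = 1
    wandering_bouts: int = 3
    sleep_reduction_hours: float = 2.0

    def days(self) -> range:
        return range(self.start_day, self.start_day + self.duration_days)


@dataclass
class RoutineAnomalySpec:
    """An injectable grossly abnormal day: sustained all-sensor activity
    through the small hours at daytime-peak rates."""

    home_id: str
    day: int
    start_hour: int = 0
    end_hour: int = 6
    rate_per_hour: float = 15.0


@dataclass
class NuisanceSpec:
    """Multi-occupancy and data-quality nuisances present in real deployments."""

    guest_day_prob: float = 0.05
    guest_rate_multiplier: float = 2.0
    pet_rate_per_hour: float = 0.0
    missing_gap_prob: float = 0.02
    missing_gap_hours: int = 8
    # sleep disturbance is among the most common behavioural symptoms of
    # dementia; roughly one night in twenty is spontaneously disturbed
    spontaneous_disturbance_prob: float = 0.05


@dataclass
class BedScheduleSpec:
    """Nightly bed-occupancy behaviour of the simulated resident.

    Night-time bathroom excursions follow a circadian phase structure rather
    than falling uniformly through the night: nocturia episodes concentrate in
    an early-night phase (shortly after sleep onset), occasionally a
    mid-night phase, and a pre-dawn phase.  Each night draws one of a few
    recurring pattern types (no excursion / early / pre-dawn / both), which is
    what gives a resident's nights the repeated, discrete pattern structure
    that profiling exploits.  Mean excursions per night under the default
    type probabilities is about 1.2.
    """

    bed_entry_hour: float = 22.0
    bed_entry_sd_minutes: float = 30.0
    sleep_length_hours: float = 9.0
    sleep_length_sd_minutes: float = 40.0
    visit_phase_hours: tuple[float, float, float] = (1.5, 3.5, 4.4)
    visit_phase_sd_minutes: float = 15.0
    # probabilities of the recurring night types: no excursion, one excursion
    # in the early / middle / pre-dawn phase, or two excursions (early and
    # pre-dawn).  Nightly nocturia is near-universal at this age, so
    # excursion-free nights get zero weight by default.
    pattern_type_probs: tuple[float, float, float, float, float] = (
        0.0,
        1 / 3,
        1 / 3,
        1 / 3,
        0.0,
    )
    # Habitual behaviour is more regular than independent draws: with a
    # balanced rotation each run of three nights visits each habitual phase
    # once, in shuffled order (ignores pattern_type_probs).
    balanced_rotation: bool = True
    extra_visit_rate: float = 0.0  # occasional additional excursion
    visit_duration_minutes: tuple[float, float] = (5.0, 12.0)
    turnover_blip_rate: float = 1.2  # short (<2 min) bed gaps per night
    wandering_bout_minutes: tuple[float, float] = (35.0, 55.0)


@dataclass
class SimulationConfig:
    """Full description of a simulated cohort.

    The same config and seed always produce byte-identical output files.
    """

    n_homes: int = 1
    n_days: int = 30
    seed: int = 0
    start_date: str = "2024-01-01"
    rate_profiles: dict[str, list[float]] = field(default_factory=_default_rate_profiles)
    bed_schedule: BedScheduleSpec = field(default_factory=BedScheduleSpec)
    vitals_spec: dict[str, tuple[float, float]] = field(default_factory=_default_vitals_spec)
    sessions_per_day: int = 2
    session_hours: tuple[float, ...] = (8.5, 19.5)
    energy_base_watts: float = 200.0
    energy_day_watts: float = 400.0
    energy_noise_watts: float = 30.0
    uti_episodes: list[UTIEpisodeSpec] = field(default_factory=list)
    sleep_disturbances: list[SleepDisturbanceSpec] = field(default_factory=list)
    routine_anomalies: list[RoutineAnomalySpec] = field(default_factory=list)
    nuisance: NuisanceSpec = field(default_factory=NuisanceSpec)

    def validate(self) -> None:
        if self.n_homes < 1 or self.n_days < 1:
            raise ValueError("n_homes and n_days must be at least 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for vp, prof in self.rate_profiles.items():
            if len(prof) != 24:
                raise ValueError(f"rate profile for {vp} must have 24 entries")
            if min(prof) < 0:
                raise ValueError(f"negative rate in profile for {vp}")
        for name, (mu, sd) in self.vitals_spec.items():
            if sd < 0 or mu < 0:
                raise ValueError(f"negative mean/SD for vital {name}")
        for ep in self.uti_episodes:
            if ep.duration_days < 1 or ep.bathroom_multiplier < 0:
                raise ValueError("invalid UTI episode spec")

    def home_ids(self) -> list[str]:
        return [f"home{h:03d}" for h in range(1, self.n_homes + 1)]


# ---------------------------------------------------------------------------
# Simulator
# ---------------------------------------------------------------------------


def _hour_events(rng, home_id, day_start, hour, viewpoint, rate, events):
    n = rng.poisson(rate)
    if n == 0:
        return
    secs = np.sort(rng.uniform(0, 3600, size=n))
    for s in secs:
        ts = day_start + pd.Timedelta(hours=hour, seconds=float(round(s)))
        events.append((home_id, ts, viewpoint, "on", np.nan))


def _night_events(rng, home_id, day_start, sched: BedScheduleSpec, *,
                  bathroom_multiplier: float, wandering_bouts: int,
                  sleep_reduction_hours: float, events: list,
                  night_type: int | None = None) -> None:
    """Generate one night of bed-pressure epochs and associated excursions.

    The night belongs to the evening of ``day_start``: bed entry that evening,
    wake the next morning.  Bathroom excursions interrupt the occupancy with
    bathroom/bedroom door activity; turn-over blips create sub-minute bed gaps
    that downstream preprocessing is expected to merge; wandering bouts add
    long out-of-bed intervals with movement on several non-bedroom channels.
    """
    entry = day_start + pd.Timedelta(
        hours=sched.bed_entry_hour, minutes=float(rng.normal(0, sched.bed_entry_sd_minutes))
    )
    length_h = sched.sleep_length_hours - sleep_reduction_hours + float(
        rng.normal(0, sched.sleep_length_sd_minutes)
    ) / 60.0
    length_h = max(length_h, 3.5)
    wake = entry + pd.Timedelta(hours=length_h)

    def phase_time(phase_hour: float) -> pd.Timestamp:
        offset = phase_hour if phase_hour >= 18 else phase_hour + 24.0
        return day_start + pd.Timedelta(
            hours=offset, minutes=float(rng.normal(0, sched.visit_phase_sd_minutes))
        )

    # Bathroom excursions: one of a few recurring nightly patterns, scaled up
    # across all circadian phases when the bathroom multiplier is raised.
    early, mid, late = sched.visit_phase_hours
    # recurring night types: none / early / mid / pre-dawn excursion, or the
    # early-riser night (sleeps through, but up for the day before 06:00)
    type_phases = ((), (early,), (mid,), (late,), ())
    if night_type is None:
        probs = np.asarray(sched.pattern_type_probs, dtype=float)
        night_type = int(rng.choice(len(type_phases), p=probs / probs.sum()))
    early_rise = night_type == 4
    if early_rise:
        wake = day_start + pd.Timedelta(
            hours=29.25, minutes=float(rng.normal(0, 15.0))
        )  # 05:15 next day
    phases = list(type_phases[night_type])
    if rng.random() < sched.extra_visit_rate:
        phases.append(mid)
    if bathroom_multiplier > 1:
        target = max(int(round(bathroom_multiplier * max(len(phases), 1))), len(phases) + 1)
        cycle = [early, mid, late]
        i = 0
        while len(phases) < target:
            phases.append(cycle[i % 3])
            i += 1

    breaks: list[tuple[pd.Timestamp, pd.Timestamp, str]] = []
    lo, hi = sched.visit_duration_minutes
    for ph in phases:
        t0 = phase_time(ph)
        dur = pd.Timedelta(minutes=float(rng.uniform(lo, hi)))
        breaks.append((t0, t0 + dur, "bathroom"))
    # Wandering bouts recur at circadian-anchored times in the small hours
    # (agitated nights are repeated episodes of moving around the house, not
    # a single excursion).
    wlo, whi = sched.wandering_bout_minutes
    for j in range(wandering_bouts):
        t0 = day_start + pd.Timedelta(
            hours=24.75 + 1.5 * j, minutes=float(rng.normal(0, 10.0))
        )
        dur = pd.Timedelta(minutes=float(rng.uniform(wlo, whi)))
        breaks.append((t0, t0 + dur, "wander"))
    # Turn-over blips: very short bed gaps with no ambient activity.
    for _ in range(rng.poisson(sched.turnover_blip_rate)):
        t0 = entry + (wake - entry) * float(rng.uniform(0.05, 0.95))
        dur = pd.Timedelta(seconds=float(rng.uniform(20, 80)))
        breaks.append((t0, t0 + dur, "blip"))

    # Resolve overlaps by pushing a colliding break to just after the
    # previous one (dropping it only if it no longer fits in the night).
    breaks.sort(key=lambda b: b[0])
    resolved: list[tuple[pd.Timestamp, pd.Timestamp, str]] = []
    for b0, b1, kind in breaks:
        dur = b1 - b0
        if resolved and b0 < resolved[-1][1]:
            b0 = resolved[-1][1] + pd.Timedelta(minutes=2)
            b1 = b0 + dur
        if b1 >= wake or b0 <= entry:
            continue
        resolved.append((b0, b1, kind))

    # Emit the bed-pressure on/off sequence.
    t = entry
    for b0, b1, kind in resolved:
        events.append((home_id, t, "bed_pressure", "on", np.nan))
        events.append((home_id, b0, "bed_pressure", "off", np.nan))
        t = b1
        if kind == "bathroom":
            for _ in range(int(rng.integers(3, 7))):
                ts = b0 + (b1 - b0) * float(rng.uniform(0.1, 0.9))
                events.append((home_id, ts, "bathroom_door_motion", "on", np.nan))
            # door fires on the way out and back; the hallway is passed through
            for frac in (0.02, 0.98):
                events.append(
                    (home_id, b0 + (b1 - b0) * frac, "bedroom_door_motion", "on", np.nan)
                )
            for _ in range(int(rng.integers(1, 3))):
                ts = b0 + (b1 - b0) * float(rng.uniform(0.05, 0.95))
                events.append((home_id, ts, "hallway_pir", "on", np.nan))
        elif kind == "wander":
            # Night wandering is pacing: the hallway PIR re-triggers every
            # couple of minutes for the duration of the bout, the bedroom door
            # fires on each pass, and the kitchen/living room only sometimes.
            minutes = (b1 - b0).total_seconds() / 60.0
            rates = {
                "hallway_pir": minutes / 2.0,
                "bedroom_door_motion": minutes / 8.0,
                "kitchen_motion": minutes / 5.0,
                "living_room_pir": minutes / 8.0,
            }
            for vp, rate in rates.items():
                n = rng.poisson(max(rate, 0.0))
                for _ in range(n):
                    ts = b0 + (b1 - b0) * float(rng.uniform(0.05, 0.95))
                    events.append((home_id, ts, vp, "on", np.nan))
            for frac in (0.02, 0.98):
                events.append(
                    (home_id, b0 + (b1 - b0) * frac, "bedroom_door_motion", "on", np.nan)
                )
    events.append((home_id, t, "bed_pressure", "on", np.nan))
    events.append((home_id, wake, "bed_pressure", "off", np.nan))

    if early_rise:
        # up for the day before 06:00: kettle on, pottering in the kitchen
        six = day_start + pd.Timedelta(hours=30)
        span = max((six - wake).total_seconds(), 0.0)
        hours_up = span / 3600.0
        for vp, rate in (("kitchen_motion", 5.0), ("hallway_pir", 3.0), ("living_room_pir", 2.0)):
            for _ in range(rng.poisson(rate * hours_up)):
                ts = wake + pd.Timedelta(seconds=float(rng.uniform(60, span))) if span > 60 else wake
                events.append((home_id, ts, vp, "on", np.nan))
        events.append((home_id, wake + pd.Timedelta(seconds=30), "bedroom_door_motion", "on", np.nan))


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of homes and return (events, vitals, ground-truth labels).

    Determinism: a dedicated ``numpy`` generator is derived from
    ``(config.seed, home_index)`` so output is reproducible and independent of
    cohort composition order.
    """
    config.validate()
    start = pd.Timestamp(config.start_date).normalize()
    events: list = []
    vitals: list = []
    labels: list = []

    uti_by_home: dict[str, set[int]] = {}
    for ep in config.uti_episodes:
        uti_by_home.setdefault(ep.home_id, set()).update(ep.days())
    dist_by_home: dict[str, set[int]] = {}
    for ds in config.sleep_disturbances:
        dist_by_home.setdefault(ds.home_id, set()).update(ds.days())
    anom_by_home: dict[str, dict[int, RoutineAnomalySpec]] = {}
    for ra in config.routine_anomalies:
        anom_by_home.setdefault(ra.home_id, {})[ra.day] = ra

    for h_idx, home_id in enumerate(config.home_ids()):
        rng = np.random.default_rng([int(config.seed) % (2**31), h_idx])
        uti_days = uti_by_home.get(home_id, set())
        dist_days = set(dist_by_home.get(home_id, set()))
        anomalies = anom_by_home.get(home_id, {})
        uti_spec_by_day: dict[int, UTIEpisodeSpec] = {}
        for ep in config.uti_episodes:
            if ep.home_id == home_id:
                for d in ep.days():
                    uti_spec_by_day[d] = ep
        dist_spec_by_day: dict[int, SleepDisturbanceSpec] = {}
        for ds in config.sleep_disturbances:
            if ds.home_id == home_id:
                for d in ds.days():
                    dist_spec_by_day[d] = ds

        night_plan: list[int] | None = None
        if config.bed_schedule.balanced_rotation:
            night_plan = []
            while len(night_plan) < config.n_days:
                # one early, one mid and one pre-dawn excursion night per
                # three-night block, with occasional off-plan nights
                block = [1, 2, 3]
                rng.shuffle(block)
                night_plan.extend(block)
            night_plan = [
                int(rng.integers(1, 4)) if rng.random() < 0.05 else t
                for t in night_plan
            ]

        for day in range(config.n_days):
            day_start = start + pd.Timedelta(days=day)
            guest = rng.random() < config.nuisance.guest_day_prob
            spontaneous = rng.random() < config.nuisance.spontaneous_disturbance_prob
            gap = rng.random() < config.nuisance.missing_gap_prob
            gap_sensor = VIEWPOINTS[int(rng.integers(0, len(VIEWPOINTS)))]
            gap_start = int(rng.integers(0, 24 - config.nuisance.missing_gap_hours))

            is_uti = day in uti_days
            is_dist = day in dist_days or spontaneous

            mult = config.nuisance.guest_rate_multiplier if guest else 1.0
            # one recurring behavioural variant per day-part
            variant = {part: int(rng.integers(0, 2)) for part in DAYPART_HOURS}
            day_events: list = []
            for vp, profile in config.rate_profiles.items():
                for hour in range(24):
                    rate = profile[hour] * mult
                    for part, hours in DAYPART_HOURS.items():
                        if hour in hours:
                            rate *= DAYPART_VARIANTS[part][variant[part]].get(vp, 1.0)
                            break
                    if config.nuisance.pet_rate_per_hour > 0 and vp in (
                        "hallway_pir",
                        "living_room_pir",
                    ):
                        rate += config.nuisance.pet_rate_per_hour
                    _hour_events(rng, home_id, day_start, hour, vp, rate, day_events)
            if guest:
                for hour in (11, 12, 16):
                    _hour_events(rng, home_id, day_start, hour, "front_door", 2.0, day_events)

            # Energy monitor: one reading per hour (mean watts over the hour).
            for hour in range(24):
                base = config.energy_base_watts
                if 7 <= hour <= 22:
                    base += config.energy_day_watts
                watts = max(base + float(rng.normal(0, config.energy_noise_watts)), 0.0)
                day_events.append(
                    (
                        home_id,
                        day_start + pd.Timedelta(hours=hour, minutes=30),
                        "energy_monitor",
                        "value",
                        round(watts, 1),
                    )
                )

            # Injected grossly abnormal routine day: sustained multi-sensor
            # activity through the small hours.
            if day in anomalies:
                ra = anomalies[day]
                for vp in UTI_VIEWPOINTS[:6] + ("chair_pressure",):
                    for hour in range(ra.start_hour, ra.end_hour):
                        _hour_events(
                            rng, home_id, day_start, hour, vp, ra.rate_per_hour, day_events
                        )

            # Night starting this evening.
            bathroom_mult = 1.0
            wander = 0
            reduction = 0.0
            if is_uti:
                ep = uti_spec_by_day[day]
                bathroom_mult = ep.bathroom_multiplier
                wander = ep.wandering_bouts
            night_type = night_plan[day] if night_plan is not None else None
            if is_dist:
                ds = dist_spec_by_day.get(day)
                wander = max(wander, ds.wandering_bouts if ds else 3)
                reduction = ds.sleep_reduction_hours if ds else 2.0
                if not is_uti:
                    # a disturbed night displaces the routine pattern
                    night_type = 0
            _night_events(
                rng,
                home_id,
                day_start,
                config.bed_schedule,
                bathroom_multiplier=bathroom_mult,
                wandering_bouts=wander,
                sleep_reduction_hours=reduction,
                events=day_events,
                night_type=night_type,
            )

            # Whole-sensor outage gap ("technical issue" day).
            excluded = False
            if gap:
                g0 = day_start + pd.Timedelta(hours=gap_start)
                g1 = g0 + pd.Timedelta(hours=config.nuisance.missing_gap_hours)
                kept = [
                    e for e in day_events if not (e[2] == gap_sensor and g0 <= e[1] < g1)
                ]
                if gap_sensor == "bed_pressure":
                    excluded = True
                day_events = kept

            events.extend(day_events)

            # Vitals sessions.
            n_sessions = min(config.sessions_per_day, len(config.session_hours))
            for s in range(n_sessions):
                ts = day_start + pd.Timedelta(
                    hours=config.session_hours[s], minutes=float(rng.normal(0, 10))
                )
                for param, (mu, sd) in config.vitals_spec.items():
                    if param == "body_temperature" and is_uti:
                        mu = uti_spec_by_day[day].temperature_c
                    if param == "pulse" and is_uti:
                        # febrile tachycardia: ~10 bpm per degree of fever
                        mu += 10.0 * max(uti_spec_by_day[day].temperature_c - 37.0, 0.0)
                    value = float(rng.normal(mu, sd))
                    if param == "spo2":
                        value = min(value, 100.0)
                    vitals.append((home_id, ts, param, round(max(value, 0.0), 1)))

            labels.append(
                (
                    home_id,
                    day_start.date().isoformat(),
                    bool(is_uti),
                    bool(is_dist),
                    day in anomalies,
                    bool(excluded),
                )
            )

    events_df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    events_df["timestamp"] = pd.to_datetime(events_df["timestamp"]).dt.floor("s")
    events_df = events_df.sort_values(
        ["home_id", "timestamp", "viewpoint"], kind="stable"
    ).reset_index(drop=True)
    vitals_df = pd.DataFrame(vitals, columns=VITAL_COLUMNS)
    vitals_df["timestamp"] = pd.to_datetime(vitals_df["timestamp"]).dt.floor("s")
    vitals_df = vitals_df.sort_values(
        ["home_id", "timestamp", "parameter"], kind="stable"
    ).reset_index(drop=True)
    labels_df = pd.DataFrame(labels, columns=LABEL_COLUMNS)
    return events_df, vitals_df, labels_df
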