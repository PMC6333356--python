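"""Rule-based night-time sleep analysis from the bed-pressure sensor.

The night window runs from 18:00 to 12:00 the next day.  A first level of
rules cleans the raw bed-occupancy transitions: occupied epochs separated by
very short gaps (turning over in bed) are merged, and isolated sub-minute
occupancy blips are removed, leaving strictly alternating definitive in-bed /
out-of-bed epochs.  A second level labels those epochs using temporal
thresholds derived from the published AASM sleep-stage durations (N1 1-7 min,
N2 10-25 min, N3 20-40 min, cycle 90-100 min):

* sleep onset — first in-bed epoch longer than mean(N1_L+N2_L, N1_H+N2_H)
  = mean(11, 32) = 21.5 min;
* restless sleep — in-bed epoch shorter than N1_L+N2_L = 11 min;
* good sleep — in-bed epoch of at least one full cycle (90 min), otherwise
  moderate sleep;
* wandering — an out-of-bed epoch with movement on two or more non-bedroom
  channels, otherwise plain out-of-bed.

Per-person deviation boundaries (minimum sleep, maximum restlessness plus
wandering) are fitted on a 30-night history as mean +/- xi * SD, and nights
breaching them are reported as sleep disturbances.  Nights away, with under
three hours in bed, or with long technical outages are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SLEEP_GOOD = "sleep_good"
SLEEP_MODERATE = "sleep_moderate"
RESTLESS = "restless"
WANDERING = "wandering"
OUT_OF_BED = "out_of_bed"

VALID = "valid"
AWAY = "away"
SHORT_SLEEP = "short_sleep"
TECHNICAL = "technical"

#: Channels whose night activity indicates movement around the house.
NON_BEDROOM_VIEWPOINTS = (
    "hallway_pir",
    "living_room_pir",
    "kitchen_motion",
    "pillbox_motion",
    "bathroom_door_motion",
    "chair_pressure",
    "front_door",
)


@dataclass
class StageThresholds:
    """Temporal thresholds (minutes) from AASM stage duration ranges."""

    n1_low: float = 1.0
    n1_high: float = 7.0
    n2_low: float = 10.0
    n2_high: float = 25.0
    n3_low: float = 20.0
    n3_high: float = 40.0
    cycle_min: float = 90.0

    @property
    def onset_minutes(self) -> float:
        return float(np.mean([self.n1_low + self.n2_low, self.n1_high + self.n2_high]))

    @property
    def restless_minutes(self) -> float:
        return self.n1_low + self.n2_low


@dataclass
class BedEpoch:
    start: pd.Timestamp
    end: pd.Timestamp
    state: str  # "in" | "out"

    @property
    def minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


@dataclass
class SleepNight:
    date: pd.Timestamp  # calendar day the night starts on
    onset: pd.Timestamp | None
    offset: pd.Timestamp | None
    blocks: list[tuple[pd.Timestamp, pd.Timestamp, str]]
    validity: str = VALID

    def minutes_in(self, states: tuple[str, ...]) -> float:
        return sum(
            (b1 - b0).total_seconds() / 60.0 for b0, b1, s in self.blocks if s in states
        )

    @property
    def sleep_minutes(self) -> float:
        return self.minutes_in((SLEEP_GOOD, SLEEP_MODERATE))

    @property
    def restless_minutes(self) -> float:
        return self.minutes_in((RESTLESS,))

    @property
    def wandering_minutes(self) -> float:
        return self.minutes_in((WANDERING,))


@dataclass
class SleepBoundaries:
    min_sleep_minutes: float
    max_restless_wandering_minutes: float
    mu_sleep: float
    sigma_sleep: float
    mu_rw: float
    sigma_rw: float
    xi: float
    n_nights: int


def night_window(date) -> tuple[pd.Timestamp, pd.Timestamp]:
    """The analysis window of the night starting on ``date``: 18:00 -> 12:00+1d."""
    d = pd.Timestamp(date).normalize()
    return d + pd.Timedelta(hours=18), d + pd.Timedelta(hours=36)


def extract_raw_epochs(events: pd.DataFrame, date) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Raw occupied epochs (o_i, phi_i) of the bed sensor within one night window."""
    w0, w1 = night_window(date)
    bed = events[
        (events["viewpoint"] == "bed_pressure")
        & (events["timestamp"] >= w0)
        & (events["timestamp"] < w1)
    ].sort_values("timestamp")
    epochs = []
    on_time: pd.Timestamp | None = None
    for r in bed.itertuples(index=False):
        if r.state == "on":
            if on_time is None:
                on_time = pd.Timestamp(r.timestamp)
        else:
            if on_time is not None:
                off = pd.Timestamp(r.timestamp)
                if off > on_time:
                    epochs.append((on_time, off))
                on_time = None
    if on_time is not None:  # still in bed at window end
        epochs.append((on_time, w1))
    return epochs


def preprocess_bed_epochs(
    raw: list[tuple[pd.Timestamp, pd.Timestamp]],
    tau_min_minutes: float = 1.0,
    delta_merge_minutes: float = 2.0,
) -> list[BedEpoch]:
    """First-level rules: merge turn-over gaps, drop isolated blips.

    Occupied epochs separated by a gap shorter than ``delta_merge_minutes``
    are merged into one continuous in-bed epoch; occupied epochs shorter than
    ``tau_min_minutes`` (sitting on the bed in passing) are removed.  The
    result strictly alternates in-bed / out-of-bed with positive durations.
    """
    if not raw:
        return []
    merge = pd.Timedelta(minutes=delta_merge_minutes)
    merged: list[list[pd.Timestamp]] = []
    for o, phi in sorted(raw):
        if merged and o - merged[-1][1] < merge:
            merged[-1][1] = max(merged[-1][1], phi)
        else:
            merged.append([o, phi])
    keep = [
        (o, phi)
        for o, phi in merged
        if (phi - o) >= pd.Timedelta(minutes=tau_min_minutes)
    ]
    out: list[BedEpoch] = []
    for i, (o, phi) in enumerate(keep):
        out.append(BedEpoch(start=o, end=phi, state="in"))
        if i + 1 < len(keep):
            out.append(BedEpoch(start=phi, end=keep[i + 1][0], state="out"))
    return out


def _has_technical_gap(events: pd.DataFrame, date, min_gap_hours: float = 6.0) -> bool:
    """True when all sensors fall silent for >= ``min_gap_hours`` inside the night.

    A night with no ambient data at all is treated as an away night rather
    than an outage, so this returns False for a completely empty window.
    """
    w0, w1 = night_window(date)
    ts = events.loc[
        (events["timestamp"] >= w0) & (events["timestamp"] < w1), "timestamp"
    ].sort_values()
    if ts.empty:
        return False
    gap = pd.Timedelta(hours=min_gap_hours)
    prev = w0
    for t in ts:
        if t - prev >= gap:
            return True
        prev = t
    return (w1 - prev) >= gap


def label_sleep_states(
    clean: list[BedEpoch],
    ambient: pd.DataFrame,
    date,
    thresholds: StageThresholds | None = None,
    w_min: int = 3,
) -> SleepNight:
    """Second-level rules: label the night's epochs with semantic sleep states.

    ``ambient`` is the full event stream (used both for the wandering rule and
    for the technical-outage exclusion).  Nights with no bed occupancy are
    marked away; nights whose in-bed epochs never reach the onset threshold
    are excluded as away/short-sleep depending on the total time in bed.
    """
    thr = thresholds or StageThresholds()
    date = pd.Timestamp(date).normalize()
    if not clean:
        validity = TECHNICAL if _has_technical_gap(ambient, date) else AWAY
        return SleepNight(date=date, onset=None, offset=None, blocks=[], validity=validity)

    in_epochs = [e for e in clean if e.state == "in"]
    onset = None
    offset = None
    for e in in_epochs:
        if e.minutes > thr.onset_minutes:
            if onset is None:
                onset = e.start
            offset = e.end
    total_in_bed = sum(e.minutes for e in in_epochs)
    if onset is None:
        validity = SHORT_SLEEP if total_in_bed > 0 else AWAY
        return SleepNight(date=date, onset=None, offset=None, blocks=[], validity=validity)

    blocks: list[tuple[pd.Timestamp, pd.Timestamp, str]] = []
    for e in clean:
        if e.end <= onset or e.start >= offset:
            continue
        if e.state == "in":
            if e.minutes < thr.restless_minutes:
                state = RESTLESS
            elif e.minutes >= thr.cycle_min:
                state = SLEEP_GOOD
            else:
                state = SLEEP_MODERATE
        else:
            amb = ambient[
                (ambient["timestamp"] >= e.start)
                & (ambient["timestamp"] < e.end)
                & (ambient["viewpoint"].isin(NON_BEDROOM_VIEWPOINTS))
            ]
            n_viewpoints = amb["viewpoint"].nunique()
            state = WANDERING if (len(amb) >= w_min and n_viewpoints >= 2) else OUT_OF_BED
        blocks.append((e.start, e.end, state))

    night = SleepNight(date=date, onset=onset, offset=offset, blocks=blocks)
    if total_in_bed < 180.0:  # slept less than three hours
        night.validity = SHORT_SLEEP
    elif _has_technical_gap(ambient, date):
        night.validity = TECHNICAL
    return night


def analyse_night(
    events: pd.DataFrame,
    date,
    thresholds: StageThresholds | None = None,
    tau_min_minutes: float = 1.0,
    delta_merge_minutes: float = 2.0,
    w_min: int = 3,
) -> SleepNight:
    """Convenience: raw epochs -> first-level cleaning -> second-level labelling."""
    raw = extract_raw_epochs(events, date)
    clean = preprocess_bed_epochs(raw, tau_min_minutes, delta_merge_minutes)
    return label_sleep_states(clean, events, date, thresholds, w_min)


def adaptive_boundaries(
    history: list[SleepNight], xi: float = 2.0, min_history: int = 30
) -> SleepBoundaries:
    """Personal deviation boundaries from >= 30 valid nights.

    min sleep = mu_sleep - xi * sigma_sleep; max restless+wandering =
    mu_rw + xi * sigma_rw, with mean and sample SD over the valid history.
    """
    valid = [n for n in history if n.validity == VALID]
    if len(valid) < min_history:
        raise ValueError(
            f"need >= {min_history} valid nights to fit boundaries, got {len(valid)}"
        )
    sleep = np.array([n.sleep_minutes for n in valid])
    rw = np.array([n.restless_minutes + n.wandering_minutes for n in valid])
    mu_s, sd_s = float(sleep.mean()), float(sleep.std(ddof=1))
    mu_rw, sd_rw = float(rw.mean()), float(rw.std(ddof=1))
    return SleepBoundaries(
        min_sleep_minutes=mu_s - xi * sd_s,
        max_restless_wandering_minutes=mu_rw + xi * sd_rw,
        mu_sleep=mu_s,
        sigma_sleep=sd_s,
        mu_rw=mu_rw,
        sigma_rw=sd_rw,
        xi=xi,
        n_nights=len(valid),
    )


def detect_disturbance(night: SleepNight, bounds: SleepBoundaries) -> str:
    """Classify a night as ``normal``, ``disturbed`` or ``excluded``."""
    if night.validity != VALID:
        return "excluded"
    if night.sleep_minutes < bounds.min_sleep_minutes:
        return "disturbed"
    if night.restless_minutes + night.wandering_minutes > bounds.max_restless_wandering_minutes:
        return "disturbed"
    return "normal"
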