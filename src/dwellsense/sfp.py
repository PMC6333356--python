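"""Hourly sensor firing patterns (SFPs) and six-hour SFP data matrices.

Ambient activations are counted per hour and per viewpoint, then grouped into
six-hour windows aligned with four clock categories: morning [06:00, 12:00),
afternoon [12:00, 18:00), evening [18:00, 24:00) and night [00:00, 06:00).
Each window is a 6 (hours) x 8 (viewpoints) count matrix; flattened windows of
one category stack into the non-negative data matrix V (48 features x n
windows, columns in chronological order) that pattern profiling factorises.

Only the eight activity viewpoints enter SFPs; the front-door contact and the
energy monitor are excluded because they are dominated by multi-occupancy
effects rather than the resident's own routine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sensor_data import UTI_VIEWPOINTS

TIME_CATEGORIES: tuple[str, ...] = ("morning", "afternoon", "evening", "night")

_CATEGORY_START_HOUR = {"night": 0, "morning": 6, "afternoon": 12, "evening": 18}

N_HOURS = 6
N_VIEWPOINTS = len(UTI_VIEWPOINTS)
N_FEATURES = N_HOURS * N_VIEWPOINTS  # 48


def time_category_of(timestamp) -> str:
    """Map an instant to its six-hour clock category."""
    hour = pd.Timestamp(timestamp).hour
    if hour < 6:
        return "night"
    if hour < 12:
        return "morning"
    if hour < 18:
        return "afternoon"
    return "evening"


@dataclass
class SixHourSFP:
    """One six-hour sensor firing pattern window."""

    home_id: str
    window_start: pd.Timestamp
    category: str
    counts: np.ndarray  # 6 hours x 8 viewpoints, non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_HOURS, N_VIEWPOINTS):
            raise ValueError(f"counts must be {N_HOURS}x{N_VIEWPOINTS}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        expected = {0: "night", 6: "morning", 12: "afternoon", 18: "evening"}[
            pd.Timestamp(self.window_start).hour
        ]
        if expected != self.category:
            raise ValueError(
                f"window_start {self.window_start} inconsistent with category {self.category}"
            )

    @property
    def window_end(self) -> pd.Timestamp:
        return pd.Timestamp(self.window_start) + pd.Timedelta(hours=N_HOURS)

    def flatten(self) -> np.ndarray:
        return flatten_window(self.counts)


def flatten_window(counts: np.ndarray) -> np.ndarray:
    """Flatten a 6x8 window hour-major: feature index = hour*8 + viewpoint."""
    counts = np.asarray(counts)
    if counts.shape != (N_HOURS, N_VIEWPOINTS):
        raise ValueError(f"expected shape {(N_HOURS, N_VIEWPOINTS)}, got {counts.shape}")
    return counts.reshape(N_FEATURES)


def unflatten_window(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten_window`."""
    vector = np.asarray(vector)
    if vector.shape != (N_FEATURES,):
        raise ValueError(f"expected shape ({N_FEATURES},), got {vector.shape}")
    return vector.reshape(N_HOURS, N_VIEWPOINTS)


@dataclass
class DataMatrixV:
    """Stacked flattened windows of one time category (features x windows)."""

    category: str
    matrix: np.ndarray  # 48 x n, chronological columns
    window_starts: list[pd.Timestamp]

    @property
    def n_windows(self) -> int:
        return self.matrix.shape[1]


def build_sfp_windows(
    events: pd.DataFrame,
    period_start,
    period_end,
    categories: tuple[str, ...] | None = None,
) -> tuple[dict[str, list[SixHourSFP]], dict[str, DataMatrixV], int]:
    """Aggregate events into six-hour SFP windows and per-category data matrices.

    Parameters
    ----------
    events:
        Time-sorted event frame for a single home.
    period_start, period_end:
        Half-open date range [start, end); windows are aligned to
        00:00/06:00/12:00/18:00.  Windows with no events are retained as zero
        matrices so that quiet periods count as (highly repeatable) patterns.
    categories:
        Restrict output to these categories (default: all four).

    Returns
    -------
    (windows_by_category, V_by_category, n_ignored):
        ``n_ignored`` counts events outside the period or on excluded
        viewpoints.
    """
    period_start = pd.Timestamp(period_start).normalize()
    period_end = pd.Timestamp(period_end).normalize()
    if period_end <= period_start:
        raise ValueError("empty period")
    categories = tuple(categories) if categories else TIME_CATEGORIES
    for c in categories:
        if c not in TIME_CATEGORIES:
            raise ValueError(f"unknown category {c!r}")

    home_ids = events["home_id"].unique() if len(events) else []
    if len(home_ids) > 1:
        raise ValueError("build_sfp_windows expects events from a single home")
    home_id = str(home_ids[0]) if len(home_ids) else "unknown"

    vp_index = {vp: j for j, vp in enumerate(UTI_VIEWPOINTS)}
    # Only activations count as firings: pressure sensors report on/off levels
    # and their releases ("off") are not activity.
    mask_vp = events["viewpoint"].isin(UTI_VIEWPOINTS) & (events["state"] == "on")
    mask_period = (events["timestamp"] >= period_start) & (events["timestamp"] < period_end)
    n_ignored = int(len(events) - (mask_vp & mask_period).sum())
    sel = events.loc[mask_vp & mask_period]

    counts_by_window: dict[pd.Timestamp, np.ndarray] = {}
    if len(sel):
        hours = sel["timestamp"].dt.floor("h")
        window_starts = hours.dt.floor("6h")
        hour_offsets = ((hours - window_starts).dt.total_seconds() // 3600).astype(int)
        cols = sel["viewpoint"].map(vp_index).astype(int)
        grouped = (
            pd.DataFrame({"w": window_starts, "h": hour_offsets, "c": cols})
            .groupby(["w", "h", "c"])
            .size()
        )
        for (w, h, c), n in grouped.items():
            counts_by_window.setdefault(w, np.zeros((N_HOURS, N_VIEWPOINTS), dtype=int))[
                h, c
            ] = n

    windows_by_category: dict[str, list[SixHourSFP]] = {c: [] for c in categories}
    for c in categories:
        start_hour = _CATEGORY_START_HOUR[c]
        w = period_start + pd.Timedelta(hours=start_hour)
        while w < period_end:
            counts = counts_by_window.get(w, np.zeros((N_HOURS, N_VIEWPOINTS), dtype=int))
            windows_by_category[c].append(
                SixHourSFP(home_id=home_id, window_start=w, category=c, counts=counts)
            )
            w += pd.Timedelta(days=1)

    V_by_category = {
        c: DataMatrixV(
            category=c,
            matrix=np.column_stack([w.flatten() for w in ws])
            if ws
            else np.zeros((N_FEATURES, 0), dtype=int),
            window_starts=[w.window_start for w in ws],
        )
        for c, ws in windows_by_category.items()
    }
    return windows_by_category, V_by_category, n_ignored
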