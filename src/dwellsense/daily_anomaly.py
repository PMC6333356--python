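"""Daily-routine anomaly detection with an isolation forest.

Each day is summarised as a 24 (hours) x 10 (sensors) matrix of hourly
activity — activation counts for the binary channels, mean watts for the
energy monitor — min-max scaled per sensor to [0, 1] using the training
period's extremes.  A per-participant isolation forest is trained on 30 such
days (flattened to 240-dimensional vectors) and scores test days; days whose
normalised path-length anomaly score reaches the threshold are labelled
abnormal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest

from .sensor_data import VIEWPOINTS

N_SENSORS = len(VIEWPOINTS)


@dataclass
class DailyActivityMatrix:
    home_id: str
    date: pd.Timestamp
    matrix: np.ndarray  # 24 x 10, entries in [0, 1] once scaled
    missing_hours: np.ndarray  # 24 bools: no events at all that hour

    def flatten(self) -> np.ndarray:
        return self.matrix.reshape(-1)


@dataclass
class ScalingParams:
    """Per-sensor min-max extremes learned on the training period."""

    minima: np.ndarray  # length 10
    maxima: np.ndarray


@dataclass
class DayLabel:
    date: pd.Timestamp
    score: float
    label: str  # "normal" | "abnormal"
    threshold: float


def _raw_daily_matrices(
    events: pd.DataFrame, period_start: pd.Timestamp, period_end: pd.Timestamp
) -> list[DailyActivityMatrix]:
    home_ids = events["home_id"].unique() if len(events) else ["unknown"]
    home_id = str(home_ids[0])
    sel = events[(events["timestamp"] >= period_start) & (events["timestamp"] < period_end)]
    vp_index = {vp: j for j, vp in enumerate(VIEWPOINTS)}
    days = pd.date_range(period_start, period_end, freq="D", inclusive="left")
    out = []
    grouped: dict[pd.Timestamp, pd.DataFrame] = dict(tuple(sel.groupby(sel["timestamp"].dt.normalize()))) if len(sel) else {}
    for day in days:
        mat = np.zeros((24, N_SENSORS))
        missing = np.ones(24, dtype=bool)
        g = grouped.get(day)
        if g is not None and len(g):
            hours = g["timestamp"].dt.hour.to_numpy()
            missing[np.unique(hours)] = False
            for vp, j in vp_index.items():
                mask = (g["viewpoint"] == vp).to_numpy()
                if not mask.any():
                    continue
                if vp == "energy_monitor":
                    vals = pd.Series(g.loc[mask, "value"].to_numpy(), index=hours[mask])
                    means = vals.groupby(level=0).mean()
                    mat[means.index.to_numpy(), j] = means.to_numpy()
                else:
                    on = mask & (g["state"] == "on").to_numpy()
                    if not on.any():
                        continue
                    h, c = np.unique(hours[on], return_counts=True)
                    mat[h, j] = c
        out.append(
            DailyActivityMatrix(home_id=home_id, date=day, matrix=mat, missing_hours=missing)
        )
    return out


def build_daily_matrices(
    events: pd.DataFrame,
    period_start,
    period_end,
    scaling: ScalingParams | None = None,
) -> tuple[list[DailyActivityMatrix], ScalingParams]:
    """Build per-day 24x10 activity matrices, min-max scaled per sensor.

    When ``scaling`` is None the extremes are learned from this period
    (training mode); otherwise the given training extremes are applied and
    values are clipped to [0, 1].  A sensor with zero range over training maps
    to an all-zero column.  Hours without any event are imputed as zero and
    flagged missing.
    """
    period_start = pd.Timestamp(period_start).normalize()
    period_end = pd.Timestamp(period_end).normalize()
    if period_end <= period_start:
        raise ValueError("empty period")
    mats = _raw_daily_matrices(events, period_start, period_end)
    stacked = np.stack([m.matrix for m in mats])  # n_days x 24 x 10
    if scaling is None:
        minima = stacked.min(axis=(0, 1))
        maxima = stacked.max(axis=(0, 1))
        scaling = ScalingParams(minima=minima, maxima=maxima)
    rng_ = scaling.maxima - scaling.minima
    safe = np.where(rng_ > 0, rng_, 1.0)
    for m in mats:
        scaled = (m.matrix - scaling.minima) / safe
        scaled[:, rng_ <= 0] = 0.0
        m.matrix = np.clip(scaled, 0.0, 1.0)
    return mats, scaling


def fit_and_label(
    train_days: list[DailyActivityMatrix],
    test_days: list[DailyActivityMatrix],
    n_estimators: int = 100,
    max_samples: int = 256,
    score_threshold: float = 0.5,
    seed: int | None = 0,
    allow_short: bool = False,
) -> tuple[IsolationForest, list[DayLabel]]:
    """Train a personal isolation forest on >= 30 days and label test days.

    Scores are the standard path-length normalisation ``s = 2^(-E[h]/c(n))``
    in [0, 1]; a test day is abnormal when ``s >= score_threshold``.
    Deterministic for a fixed seed.
    """
    if len(train_days) < 30 and not allow_short:
        raise ValueError(
            f"need >= 30 training days (got {len(train_days)}); pass allow_short to override"
        )
    X_train = np.stack([m.flatten() for m in train_days])
    forest = IsolationForest(
        n_estimators=n_estimators,
        max_samples=min(max_samples, len(train_days)),
        random_state=seed,
    )
    forest.fit(X_train)
    labels = []
    if test_days:
        X_test = np.stack([m.flatten() for m in test_days])
        # sklearn's score_samples returns -s, s being the canonical score.
        scores = -forest.score_samples(X_test)
        for m, s in zip(test_days, scores):
            labels.append(
                DayLabel(
                    date=m.date,
                    score=float(s),
                    label="abnormal" if s >= score_threshold else "normal",
                    threshold=score_threshold,
                )
            )
    return forest, labels
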