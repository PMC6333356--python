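"""Temperature change detection, RSFP alerting and decision fusion for UTI alerts.

A urinary-tract-infection alert is raised only when two independent strands of
evidence coincide: a body-temperature reading above the febrile threshold
(38 °C) and a six-hour activity window classified as a rarely-repetitive
pattern (RSFP), within a configurable fusion window (24 h by default).
Requiring both strands is what keeps the alert volume compatible with a human
monitoring team.

A one-class SVM trained on annotated UTI-positive (bathroom frequency, body
temperature) pairs is provided as the supervised baseline for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import OneClassSVM

from .categorise import ClusterProfile, CategoryProfile, RSFP, classify_window
from .sfp import SixHourSFP


@dataclass
class TempAlert:
    home_id: str
    timestamp: pd.Timestamp
    value: float  # °C


@dataclass
class RSFPAlert:
    home_id: str
    timestamp: pd.Timestamp  # window end
    window_start: pd.Timestamp
    category: str
    cluster: int


@dataclass
class UTIAlert:
    home_id: str
    timestamp: pd.Timestamp
    temp_alert: TempAlert
    rsfp_alert: RSFPAlert


def temperature_alerts(
    vitals: pd.DataFrame, threshold_c: float = 38.0
) -> list[TempAlert]:
    """One alert per body-temperature reading strictly above ``threshold_c``."""
    if vitals.empty:
        return []
    temps = vitals[vitals["parameter"] == "body_temperature"]
    out = [
        TempAlert(home_id=str(r.home_id), timestamp=pd.Timestamp(r.timestamp), value=float(r.value))
        for r in temps.itertuples(index=False)
        if float(r.value) > threshold_c
    ]
    out.sort(key=lambda a: a.timestamp)
    return out


def rsfp_alerts(
    windows: Iterable[SixHourSFP], profile: ClusterProfile | CategoryProfile
) -> list[RSFPAlert]:
    """One alert per window whose nearest profile cluster is RSFP."""
    out = []
    for w in windows:
        category, cluster = classify_window(w, profile)
        if category == RSFP:
            out.append(
                RSFPAlert(
                    home_id=w.home_id,
                    timestamp=w.window_end,
                    window_start=pd.Timestamp(w.window_start),
                    category=w.category,
                    cluster=cluster,
                )
            )
    out.sort(key=lambda a: a.timestamp)
    return out


def fuse_decisions(
    temp_alerts: Sequence[TempAlert],
    rsfp_alerts_: Sequence[RSFPAlert],
    window_hours: float = 24.0,
    dedup_hours: float = 24.0,
) -> list[UTIAlert]:
    """Fuse the two alert streams into UTI alerts.

    A UTI alert is emitted whenever a temperature alert and an RSFP alert from
    the same home lie within ``window_hours`` of each other, in either order.
    To avoid flooding the monitoring workflow, at most one UTI alert per home
    is emitted per rolling ``dedup_hours``; the alert timestamp is the later
    of the two evidence timestamps.
    """
    window = pd.Timedelta(hours=window_hours)
    candidates: list[UTIAlert] = []
    for t in temp_alerts:
        for r in rsfp_alerts_:
            if t.home_id != r.home_id:
                continue
            if abs(t.timestamp - r.timestamp) <= window:
                candidates.append(
                    UTIAlert(
                        home_id=t.home_id,
                        timestamp=max(t.timestamp, r.timestamp),
                        temp_alert=t,
                        rsfp_alert=r,
                    )
                )
    candidates.sort(key=lambda a: (a.home_id, a.timestamp))
    dedup = pd.Timedelta(hours=dedup_hours)
    out: list[UTIAlert] = []
    last: dict[str, pd.Timestamp] = {}
    for a in candidates:
        prev = last.get(a.home_id)
        if prev is not None and a.timestamp - prev < dedup:
            continue
        out.append(a)
        last[a.home_id] = a.timestamp
    return out


@dataclass
class OneClassConfig:
    """Radial-basis one-class SVM settings for the supervised baseline.

    ``gamma`` is the RBF kernel parameter in exp(-gamma * ||x - y||^2);
    ``nu`` bounds the fraction of training points outside the boundary.
    Features are the daily bathroom-visit frequency and body temperature,
    standardised with training statistics.
    """

    gamma: float = 1e-2
    nu: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.nu < 1:
            raise ValueError("nu must lie in (0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class OneClassBaseline:
    config: OneClassConfig
    mean_: np.ndarray
    scale_: np.ndarray
    svm_: OneClassSVM | None
    fallback_center_: np.ndarray | None = None

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def predict(self, X: np.ndarray) -> np.ndarray:
        """True where a test point falls inside the learned UTI-like region."""
        Z = self._transform(np.atleast_2d(X))
        if self.svm_ is None:
            d = np.linalg.norm(Z - self.fallback_center_, axis=1)
            return d < 1e-6
        return self.svm_.predict(Z) == 1


def one_class_baseline(
    train_features: np.ndarray,
    config: OneClassConfig | None = None,
) -> OneClassBaseline:
    """Fit the one-class SVM baseline on annotated UTI-positive feature pairs.

    ``train_features`` rows are (daily bathroom-visit count, body temperature)
    for days with a confirmed UTI.  Degenerate training sets (all points
    identical) fall back to an exact-match distance rule and are flagged by a
    ``svm_ is None`` model.
    """
    config = config or OneClassConfig()
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 5:
        raise ValueError("need at least 5 training feature pairs")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - mean) / scale
    if np.allclose(Z, Z[0], atol=1e-12):
        return OneClassBaseline(
            config=config, mean_=mean, scale_=scale, svm_=None, fallback_center_=Z[0]
        )
    svm = OneClassSVM(kernel="rbf", gamma=config.gamma, nu=config.nu)
    svm.fit(Z)
    return OneClassBaseline(config=config, mean_=mean, scale_=scale, svm_=svm)


def daily_uti_features(
    events: pd.DataFrame, vitals: pd.DataFrame
) -> pd.DataFrame:
    """Per-day (bathroom-visit frequency, max body temperature) feature pairs.

    Bathroom-visit frequency is the daily count of bathroom-door-motion
    activations; temperature is the day's maximum reading (absent days get the
    afebrile nominal 36.7 °C so the baseline can still be evaluated).
    """
    frames = []
    bath = events[events["viewpoint"] == "bathroom_door_motion"].copy()
    bath["date"] = bath["timestamp"].dt.normalize()
    counts = bath.groupby(["home_id", "date"]).size().rename("bathroom_count")
    temps = vitals[vitals["parameter"] == "body_temperature"].copy()
    temps["date"] = temps["timestamp"].dt.normalize()
    tmax = temps.groupby(["home_id", "date"])["value"].max().rename("max_temperature")
    out = pd.concat([counts, tmax], axis=1).reset_index()
    out["bathroom_count"] = out["bathroom_count"].fillna(0).astype(int)
    out["max_temperature"] = out["max_temperature"].fillna(36.7)
    return out.sort_values(["home_id", "date"]).reset_index(drop=True)
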