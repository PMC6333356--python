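"""Daily Health Score (DHS): a NEWS2-adapted vital-sign banding for home monitoring.

Four parameters are scored 0-3 per measurement session — systolic blood
pressure, pulse, body temperature and SpO2 — and summed to a session total in
[0, 12]; the day's DHS is the worst (maximum) session total.  Bands:

==================  =====  ======  =======  =======  ======  ========  =====
parameter               3      2        1        0       1        2       3
==================  =====  ======  =======  =======  ======  ========  =====
systolic BP (mmHg)  <=90   91-100  101-110  111-219                    >=220
pulse (/min)        <=40           41-50    51-90    91-110  111-130   >=131
temperature (degC)  <=35           35.1-36  36.1-38  38.1-39 >=39.1
SpO2 (%)            <=91   92-93   94-95    >=96
==================  =====  ======  =======  =======  ======  ========  =====

Values are rounded to the band grid first (0.1 degC for temperature, whole
units otherwise, half-up) so every value falls in exactly one printed band.

Each participant's DHS history yields an adaptive confidence interval
Delta = mu +/- xi * sigma over the trailing d days (d = 14 by default); a day
whose DHS exceeds the upper bound is flagged as a personal deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

SCORED_PARAMETERS = ("systolic_bp", "pulse", "body_temperature", "spo2")


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def score_parameter(parameter: str, value: float) -> int:
    """Band score in {0, 1, 2, 3} for one scored vital-sign value."""
    if parameter not in SCORED_PARAMETERS:
        raise ValueError(f"{parameter!r} is not a scored parameter")
    if not np.isfinite(value):
        raise ValueError("value must be finite")
    if parameter == "body_temperature":
        v = _round_half_up(value, 1)
        if v <= 35.0:
            return 3
        if v <= 36.0:
            return 1
        if v <= 38.0:
            return 0
        if v <= 39.0:
            return 1
        return 2
    v = int(_round_half_up(value, 0))
    if parameter == "systolic_bp":
        if v <= 90:
            return 3
        if v <= 100:
            return 2
        if v <= 110:
            return 1
        if v <= 219:
            return 0
        return 3
    if parameter == "pulse":
        if v <= 40:
            return 3
        if v <= 50:
            return 1
        if v <= 90:
            return 0
        if v <= 110:
            return 1
        if v <= 130:
            return 2
        return 3
    # spo2
    if v <= 91:
        return 3
    if v <= 93:
        return 2
    if v <= 95:
        return 1
    return 0


@dataclass
class DHSRecord:
    home_id: str
    date: pd.Timestamp
    scores: dict[str, int]  # per present scored parameter
    total: int
    missing: tuple[str, ...] = ()

    def as_row(self) -> dict:
        row = {"home_id": self.home_id, "date": self.date}
        for p in SCORED_PARAMETERS:
            row[f"score_{p}"] = self.scores.get(p)
        row["total"] = self.total
        row["missing"] = ";".join(self.missing)
        return row


def _split_sessions(day_vitals: pd.DataFrame, gap_minutes: float = 60.0):
    """Group a day's readings into measurement sessions by time proximity."""
    df = day_vitals.sort_values("timestamp")
    sessions = []
    current = []
    last = None
    for r in df.itertuples(index=False):
        t = pd.Timestamp(r.timestamp)
        if last is not None and (t - last) > pd.Timedelta(minutes=gap_minutes):
            sessions.append(pd.DataFrame(current))
            current = []
        current.append(r._asdict())
        last = t
    if current:
        sessions.append(pd.DataFrame(current))
    return sessions


def daily_health_score(day_vitals: pd.DataFrame) -> DHSRecord | None:
    """Score one day of vitals; the day's DHS is the worst session total.

    Missing scored parameters contribute 0 and are listed in the record's
    ``missing`` field (parameters never observed that day).  Returns None when
    no scored parameter was observed at all.
    """
    scored = day_vitals[day_vitals["parameter"].isin(SCORED_PARAMETERS)]
    if scored.empty:
        return None
    home_id = str(scored["home_id"].iloc[0])
    date = pd.Timestamp(scored["timestamp"].iloc[0]).normalize()
    best: tuple[int, dict[str, int]] | None = None
    for session in _split_sessions(scored):
        scores = {}
        for param in SCORED_PARAMETERS:
            vals = session.loc[session["parameter"] == param, "value"]
            if len(vals):
                scores[param] = score_parameter(param, float(vals.iloc[-1]))
        total = sum(scores.values())
        if best is None or total > best[0]:
            best = (total, scores)
    total, scores = best
    seen = set(scored["parameter"])
    missing = tuple(p for p in SCORED_PARAMETERS if p not in seen)
    return DHSRecord(home_id=home_id, date=date, scores=scores, total=total, missing=missing)


def dhs_series(vitals: pd.DataFrame) -> pd.DataFrame:
    """Daily DHS records for a (single-home) vitals stream as a frame."""
    rows = []
    v = vitals.copy()
    v["date"] = v["timestamp"].dt.normalize()
    for (home, date), day in v.groupby(["home_id", "date"]):
        rec = daily_health_score(day)
        if rec is not None:
            rows.append(rec.as_row())
    return pd.DataFrame(rows)


@dataclass
class AdaptiveInterval:
    mu: float
    sigma: float
    xi: float
    d: int
    lower: float
    upper: float


def adaptive_interval(history, d: int = 14, xi: float = 1.96) -> AdaptiveInterval:
    """Personal confidence interval Delta = mu +/- xi*sigma over the last d days."""
    values = np.asarray(history, dtype=float)
    if len(values) < d:
        raise ValueError(f"need >= {d} historical scores, got {len(values)}")
    window = values[-d:]
    mu = float(window.mean())
    sigma = float(window.std(ddof=1))
    return AdaptiveInterval(mu=mu, sigma=sigma, xi=xi, d=d, lower=mu - xi * sigma, upper=mu + xi * sigma)


def flag_exceedances(scores: pd.Series, d: int = 14, xi: float = 1.96) -> pd.Series:
    """Per-day flag: DHS above the upper bound of the trailing-d-day interval.

    The first d days carry no flag (insufficient history).
    """
    flags = pd.Series(False, index=scores.index)
    vals = scores.to_numpy(dtype=float)
    for i in range(d, len(vals)):
        interval = adaptive_interval(vals[i - d : i], d=d, xi=xi)
        flags.iloc[i] = vals[i] > interval.upper
    return flags
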