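"""End-to-end orchestration: simulate -> profile -> detect -> explain -> evaluate.

The pipeline mirrors the deployed architecture: three months of data profile a
home's activity patterns, the profile classifies later windows in (near) real
time, RSFP windows fuse with febrile temperature readings into UTI alerts, an
isolation forest screens whole days, and the sleep analyser plus daily health
score explain flagged days.  Every stage is seeded, and identical
configuration reproduces identical artefacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import daily_anomaly as da
from . import sleep as sl
from .categorise import ClusterProfile, categorise_clusters
from .evaluation import assemble_confusion, confusion_metrics
from .nmf import acls_nmf, cluster_feature_space, select_rank
from .sensor_data import (
    SimulationConfig,
    UTIEpisodeSpec,
    SleepDisturbanceSpec,
    RoutineAnomalySpec,
    simulate_cohort,
    write_records,
)
from .sfp import TIME_CATEGORIES, build_sfp_windows
from .uti import (
    OneClassConfig,
    daily_uti_features,
    fuse_decisions,
    one_class_baseline,
    rsfp_alerts,
    temperature_alerts,
)
from .health_score import dhs_series, flag_exceedances


def fit_profile(
    events: pd.DataFrame,
    profile_start,
    profile_end,
    seed: int = 0,
    rank: int | None = None,
    rank_range=range(1, 7),
    k_range=range(2, 11),
    n_init: int = 10,
    one_sided: bool = False,
) -> ClusterProfile:
    """Learn a per-time-category activity profile from a profiling period.

    For each of the four clock categories: build the six-hour SFP matrix,
    choose the factorisation rank from the residual curve (unless given),
    factorise with ACLS, cluster the feature-space coordinates with
    silhouette-selected k, and band the clusters into HSFP/LSFP/RSFP by the
    MAD of their sizes.
    """
    home_id = str(events["home_id"].iloc[0]) if len(events) else "unknown"
    _, V_by_cat, _ = build_sfp_windows(events, profile_start, profile_end)
    profile = ClusterProfile(home_id=home_id)
    for cat in TIME_CATEGORIES:
        V = V_by_cat[cat].matrix.astype(float)
        if V.shape[1] < 3:
            raise ValueError(f"too few windows in category {cat!r} to profile")
        r = rank
        if r is None:
            feasible = [x for x in rank_range if x < min(V.shape)]
            r, _ = select_rank(V, feasible, seed=seed, n_init=max(n_init // 2, 3))
        model = acls_nmf(V, r, n_init=n_init, seed=seed)
        assignment = cluster_feature_space(model, k_range=k_range, seed=seed)
        profile.categories[cat] = categorise_clusters(
            cat, model, assignment, one_sided=one_sided
        )
    return profile


def detect_uti(
    events: pd.DataFrame,
    vitals: pd.DataFrame,
    profile: ClusterProfile,
    test_start,
    test_end,
    fusion_window_hours: float = 24.0,
    temperature_threshold_c: float = 38.0,
):
    """Classify test-period windows, fuse with temperature alerts, return all three alert lists."""
    windows_by_cat, _, _ = build_sfp_windows(events, test_start, test_end)
    windows = [w for ws in windows_by_cat.values() for w in ws]
    windows.sort(key=lambda w: w.window_start)
    r_alerts = rsfp_alerts(windows, profile)
    t0, t1 = pd.Timestamp(test_start), pd.Timestamp(test_end)
    vit = vitals[(vitals["timestamp"] >= t0) & (vitals["timestamp"] < t1)]
    t_alerts = temperature_alerts(vit, threshold_c=temperature_threshold_c)
    fused = fuse_decisions(t_alerts, r_alerts, window_hours=fusion_window_hours)
    return t_alerts, r_alerts, fused


def _episode_spans(labels: pd.DataFrame, flag: str) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Contiguous runs of flagged days as (first_day, last_day) spans."""
    days = sorted(pd.Timestamp(d) for d in labels.loc[labels[flag], "date"])
    spans: list[list[pd.Timestamp]] = []
    for d in days:
        if spans and (d - spans[-1][1]).days == 1:
            spans[-1][1] = d
        else:
            spans.append([d, d])
    return [(a, b) for a, b in spans]


def uti_injection_recovery(fused_alerts, labels: pd.DataFrame) -> dict:
    """Score fused UTI alerts against the generator's episode ground truth.

    An episode counts as detected when any fused alert falls between its first
    day and the morning after its last day (night activity of day d lands in
    the small hours of d+1).  Alert days outside every such span are
    non-episode alert days.
    """
    labels = labels.copy()
    labels["date"] = pd.to_datetime(labels["date"])
    spans = _episode_spans(labels, "uti_episode")
    alert_days = sorted({a.timestamp.normalize() for a in fused_alerts})
    detected = 0
    for a, b in spans:
        hit = any(a <= d <= b + pd.Timedelta(days=1) for d in alert_days)
        detected += int(hit)
    non_episode = [
        d
        for d in alert_days
        if not any(a <= d <= b + pd.Timedelta(days=1) for a, b in spans)
    ]
    return {
        "episodes_total": len(spans),
        "episodes_detected": detected,
        "alert_days": len(alert_days),
        "non_episode_alert_days": len(non_episode),
    }


def baseline_injection_recovery(
    events: pd.DataFrame,
    vitals: pd.DataFrame,
    labels: pd.DataFrame,
    config: OneClassConfig | None = None,
) -> dict:
    """Evaluate the one-class baseline on the same episode-recovery terms.

    The baseline is trained on the (bathroom frequency, temperature) pairs of
    the annotated episode days — the supervised information the deployed
    baseline had — and applied to every day.
    """
    labels = labels.copy()
    labels["date"] = pd.to_datetime(labels["date"])
    feats = daily_uti_features(events, vitals)
    merged = feats.merge(
        labels[["home_id", "date", "uti_episode"]],
        left_on=["home_id", "date"],
        right_on=["home_id", "date"],
        how="left",
    )
    merged["uti_episode"] = merged["uti_episode"].astype("boolean").fillna(False).astype(bool)
    X = merged[["bathroom_count", "max_temperature"]].to_numpy(dtype=float)
    pos = merged["uti_episode"].to_numpy(dtype=bool)
    if pos.sum() < 5:
        raise ValueError("need >= 5 annotated episode days to train the baseline")
    model = one_class_baseline(X[pos], config)
    flagged = model.predict(X)
    spans = _episode_spans(labels, "uti_episode")
    alert_days = [pd.Timestamp(d) for d, f in zip(merged["date"], flagged) if f]
    detected = sum(
        int(any(a <= d <= b + pd.Timedelta(days=1) for d in alert_days)) for a, b in spans
    )
    non_episode = [
        d
        for d in alert_days
        if not any(a <= d <= b + pd.Timedelta(days=1) for a, b in spans)
    ]
    return {
        "episodes_total": len(spans),
        "episodes_detected": detected,
        "alert_days": len(alert_days),
        "non_episode_alert_days": len(non_episode),
    }


def sleep_injection_recovery(
    events: pd.DataFrame,
    labels: pd.DataFrame,
    train_nights: int = 30,
    xi: float = 2.0,
) -> dict:
    """Night-by-night disturbance detection scored against generator labels."""
    labels = labels.copy()
    labels["date"] = pd.to_datetime(labels["date"])
    dates = sorted(labels["date"])
    nights = {d: sl.analyse_night(events, d) for d in dates}
    history = []
    for d in dates:
        if len(history) >= train_nights:
            break
        if nights[d].validity == sl.VALID:
            history.append(nights[d])
    if len(history) < train_nights:
        raise ValueError("not enough valid nights to fit boundaries")
    bounds = sl.adaptive_boundaries(history, xi=xi, min_history=train_nights)
    predicted, reference = [], []
    cutoff = history[-1].date
    for d in dates:
        if d <= cutoff:
            continue
        verdict = sl.detect_disturbance(nights[d], bounds)
        if verdict == "excluded":
            continue
        predicted.append(verdict)
        truth = bool(labels.loc[labels["date"] == d, "sleep_disturbed"].iloc[0])
        reference.append("disturbed" if truth else "normal")
    counts = assemble_confusion(predicted, reference)
    metrics = confusion_metrics(counts)
    return {
        "counts": counts,
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "accuracy": metrics.accuracy,
        "n_test_nights": len(predicted),
        "bounds": bounds,
    }


def anomaly_injection_recovery(
    events: pd.DataFrame,
    labels: pd.DataFrame,
    train_days: int = 30,
    seed: int = 0,
) -> dict:
    """Rank injected routine-anomaly days among all scored days."""
    labels = labels.copy()
    labels["date"] = pd.to_datetime(labels["date"])
    dates = sorted(labels["date"])
    t0, t_split = dates[0], dates[0] + pd.Timedelta(days=train_days)
    t1 = dates[-1] + pd.Timedelta(days=1)
    train_mats, scaling = da.build_daily_matrices(events, t0, t_split)
    test_mats, _ = da.build_daily_matrices(events, t_split, t1, scaling=scaling)
    _, day_labels = da.fit_and_label(train_mats, test_mats, seed=seed)
    scores = pd.Series(
        {lab.date: lab.score for lab in day_labels}
    ).sort_values(ascending=False)
    ranks = {d: i + 1 for i, d in enumerate(scores.index)}
    injected = [
        d for d in labels.loc[labels["routine_anomaly"], "date"] if d in ranks
    ]
    return {
        "n_scored_days": len(scores),
        "injected_days": len(injected),
        "injected_ranks": [ranks[d] for d in injected],
        "worst_injected_rank": max((ranks[d] for d in injected), default=None),
        "labels": day_labels,
    }


def save_profile(profile: ClusterProfile, path: str | Path) -> Path:
    """Persist a learned profile (factors, clusters, categories) as JSON."""
    from .nmf import ClusterAssignment, NMFModel  # local to avoid cycle confusion

    data = {"home_id": profile.home_id, "categories": {}}
    for cat, cp in profile.categories.items():
        a = cp.assignment
        data["categories"][cat] = {
            "W": cp.model.W.tolist(),
            "H": cp.model.H.tolist(),
            "rank": cp.model.rank,
            "residual": cp.model.residual,
            "seed": cp.model.seed,
            "k": a.k,
            "labels": a.labels.tolist(),
            "centroids": a.centroids.tolist(),
            "silhouette": a.silhouette,
            "degenerate": a.degenerate,
            "member_counts": cp.member_counts.tolist(),
            "mad_scores": cp.mad_scores.tolist(),
            "cluster_categories": cp.cluster_categories,
            "d_low": cp.d_low,
            "d_high": cp.d_high,
            "normalise": cp.normalise,
        }
    path = Path(path)
    path.write_text(json.dumps(data))
    return path


def load_profile(path: str | Path) -> ClusterProfile:
    """Inverse of :func:`save_profile`."""
    from .categorise import CategoryProfile
    from .nmf import ClusterAssignment, NMFModel

    data = json.loads(Path(path).read_text())
    profile = ClusterProfile(home_id=data["home_id"])
    for cat, d in data["categories"].items():
        model = NMFModel(
            W=np.asarray(d["W"]),
            H=np.asarray(d["H"]),
            rank=d["rank"],
            residual=d["residual"],
            converged=True,
            n_iter=0,
            n_init=0,
            seed=d["seed"],
        )
        assignment = ClusterAssignment(
            k=d["k"],
            labels=np.asarray(d["labels"]),
            centroids=np.asarray(d["centroids"]),
            silhouette=d["silhouette"],
            degenerate=d["degenerate"],
        )
        profile.categories[cat] = CategoryProfile(
            category=cat,
            model=model,
            assignment=assignment,
            member_counts=np.asarray(d["member_counts"]),
            mad_scores=np.asarray(d["mad_scores"]),
            cluster_categories=list(d["cluster_categories"]),
            d_low=d["d_low"],
            d_high=d["d_high"],
            normalise=d["normalise"],
        )
    return profile


@dataclass
class PipelineConfig:
    """Single-home end-to-end run configuration (YAML round-trippable)."""

    out_dir: str = "run"
    seed: int = 1
    n_days: int = 120
    profile_days: int = 90
    fusion_window_hours: float = 24.0
    temperature_threshold_c: float = 38.0
    xi_sleep: float = 2.0
    xi_dhs: float = 1.96
    dhs_window_days: int = 14
    iforest_train_days: int = 30
    uti_episode_starts: tuple[int, ...] = (95, 105, 114)
    uti_episode_days: int = 3
    disturbance_starts: tuple[int, ...] = ()
    anomaly_days: tuple[int, ...] = ()

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = dataclasses.asdict(self)
        data = {k: list(v) if isinstance(v, tuple) else v for k, v in data.items()}
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        for k in ("uti_episode_starts", "disturbance_starts", "anomaly_days"):
            if k in data:
                data[k] = tuple(data[k])
        return cls(**data)

    def simulation_config(self) -> SimulationConfig:
        home = "home001"
        return SimulationConfig(
            n_homes=1,
            n_days=self.n_days,
            seed=self.seed,
            uti_episodes=[
                UTIEpisodeSpec(home_id=home, start_day=s, duration_days=self.uti_episode_days)
                for s in self.uti_episode_starts
            ],
            sleep_disturbances=[
                SleepDisturbanceSpec(home_id=home, start_day=s)
                for s in self.disturbance_starts
            ],
            routine_anomalies=[
                RoutineAnomalySpec(home_id=home, day=d) for d in self.anomaly_days
            ],
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full single-home pipeline and write all artefacts to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation_config()
    events, vitals, labels = simulate_cohort(sim)
    write_records(events, out / "events.csv")
    write_records(vitals, out / "vitals.csv")
    labels.to_csv(out / "labels.csv", index=False)
    config.to_yaml(out / "config.yaml")

    start = pd.Timestamp(sim.start_date)
    split = start + pd.Timedelta(days=config.profile_days)
    end = start + pd.Timedelta(days=config.n_days)

    profile = fit_profile(events, start, split, seed=config.seed)
    profile_summary = {
        cat: {
            "rank": cp.model.rank,
            "k": cp.assignment.k,
            "member_counts": cp.member_counts.tolist(),
            "mad_scores": [round(float(s), 3) for s in cp.mad_scores],
            "categories": cp.cluster_categories,
        }
        for cat, cp in profile.categories.items()
    }

    t_alerts, r_alerts, fused = detect_uti(
        events,
        vitals,
        profile,
        split,
        end,
        fusion_window_hours=config.fusion_window_hours,
        temperature_threshold_c=config.temperature_threshold_c,
    )
    with open(out / "uti_alerts.jsonl", "w") as fh:
        for a in fused:
            fh.write(
                json.dumps(
                    {
                        "home_id": a.home_id,
                        "timestamp": str(a.timestamp),
                        "temperature": a.temp_alert.value,
                        "rsfp_window_start": str(a.rsfp_alert.window_start),
                        "rsfp_category": a.rsfp_alert.category,
                    }
                )
                + "\n"
            )

    uti_eval = uti_injection_recovery(fused, labels)
    baseline_eval = baseline_injection_recovery(events, vitals, labels)
    sleep_eval = sleep_injection_recovery(events, labels, xi=config.xi_sleep)
    anomaly_eval = anomaly_injection_recovery(
        events, labels, train_days=config.iforest_train_days, seed=config.seed
    )

    nights_rows = []
    for d in sorted(pd.to_datetime(labels["date"])):
        n = sl.analyse_night(events, d)
        verdict = (
            sl.detect_disturbance(n, sleep_eval["bounds"]) if n.validity == sl.VALID else "excluded"
        )
        nights_rows.append(
            {
                "date": d.date().isoformat(),
                "onset": str(n.onset) if n.onset is not None else "",
                "offset": str(n.offset) if n.offset is not None else "",
                "sleep_min": round(n.sleep_minutes, 1),
                "restless_min": round(n.restless_minutes, 1),
                "wandering_min": round(n.wandering_minutes, 1),
                "label": verdict,
                "exclusion": n.validity,
            }
        )
    pd.DataFrame(nights_rows).to_csv(out / "nights.csv", index=False)

    dhs = dhs_series(vitals)
    if len(dhs) > config.dhs_window_days:
        dhs = dhs.sort_values("date").reset_index(drop=True)
        dhs["flag"] = flag_exceedances(
            dhs["total"], d=config.dhs_window_days, xi=config.xi_dhs
        )
    dhs.to_csv(out / "dhs.csv", index=False)

    anomaly_df = pd.DataFrame(
        [
            {"date": l.date.date().isoformat(), "score": round(l.score, 4), "label": l.label}
            for l in anomaly_eval["labels"]
        ]
    )
    anomaly_df.to_csv(out / "daily_labels.csv", index=False)

    # Anomaly-explanation join: every screened day carries its same-day sleep
    # verdict and health-score flag so abnormal days can be interpreted.
    nights_df = pd.DataFrame(nights_rows)
    days = anomaly_df.merge(
        nights_df[["date", "label", "exclusion"]].rename(
            columns={"label": "sleep_label", "exclusion": "sleep_exclusion"}
        ),
        on="date",
        how="left",
    )
    dhs_join = dhs.copy()
    if len(dhs_join):
        dhs_join["date"] = pd.to_datetime(dhs_join["date"]).dt.date.astype(str)
        cols = ["date", "total"] + (["flag"] if "flag" in dhs_join.columns else [])
        days = days.merge(
            dhs_join[cols].rename(columns={"total": "dhs_total", "flag": "dhs_flag"}),
            on="date",
            how="left",
        )
    days.to_csv(out / "days.csv", index=False)

    report = {
        "seed": config.seed,
        "n_days": config.n_days,
        "profile": profile_summary,
        "n_temperature_alerts": len(t_alerts),
        "n_rsfp_alerts": len(r_alerts),
        "n_uti_alerts": len(fused),
        "uti_recovery": uti_eval,
        "baseline_recovery": baseline_eval,
        "sleep": {
            k: (round(v, 4) if isinstance(v, float) else v)
            for k, v in sleep_eval.items()
            if k in ("sensitivity", "specificity", "accuracy", "n_test_nights")
        },
        "daily_anomaly": {
            k: v for k, v in anomaly_eval.items() if k != "labels"
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
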