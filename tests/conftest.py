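import numpy as np
import pandas as pd
import pytest

import dwellsense as dw

HOME = "home001"


@pytest.fixture(scope="session")
def sim_small():
    """Ten quiet days: no injected episodes, no nuisances."""
    cfg = dw.SimulationConfig(
        n_homes=1,
        n_days=10,
        seed=1,
        nuisance=dw.NuisanceSpec(
            guest_day_prob=0.0, missing_gap_prob=0.0, spontaneous_disturbance_prob=0.0
        ),
    )
    return dw.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sim_uti():
    """120 days with three 3-day UTI episodes in the final month."""
    cfg = dw.SimulationConfig(
        n_homes=1,
        n_days=120,
        seed=1,
        uti_episodes=[dw.UTIEpisodeSpec(HOME, s) for s in (95, 105, 114)],
    )
    return dw.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def profile_uti(sim_uti):
    events, _, _ = sim_uti
    start = pd.Timestamp("2024-01-01")
    return dw.fit_profile(events, start, start + pd.Timedelta(days=90), seed=1)


@pytest.fixture(scope="session")
def sim_nights():
    """100 nights with injected sleep disturbances and gross routine anomalies."""
    cfg = dw.SimulationConfig(
        n_homes=1,
        n_days=100,
        seed=1,
        sleep_disturbances=[
            dw.SleepDisturbanceSpec(HOME, d) for d in (40, 52, 61, 70, 78, 85, 93)
        ],
        routine_anomalies=[dw.RoutineAnomalySpec(HOME, d) for d in (55, 72, 88)],
    )
    return dw.simulate_cohort(cfg)
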