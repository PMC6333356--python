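"""Daily Health Score (DHS) with a personal adaptive interval.

Systolic blood pressure, pulse, temperature and SpO2 are banded 0-3 per
measurement session and summed (0-12); the day's score is the worst session.
Each day is then compared against mu +/- xi*sigma of the trailing 14 days, so
a flag means "unusual for this person", not just "high".
"""

import pandas as pd

import dwellsense as dw
from dwellsense.health_score import dhs_series, flag_exceedances, score_parameter

# banding spot checks
for param, value in [("systolic_bp", 85), ("pulse", 120), ("body_temperature", 38.5), ("spo2", 97)]:
    print(f"{param} = {value} -> score {score_parameter(param, value)}")

cfg = dw.SimulationConfig(
    n_homes=1,
    n_days=30,
    seed=11,
    uti_episodes=[dw.UTIEpisodeSpec("home001", start_day=25)],
)
_, vitals, _ = dw.simulate_cohort(cfg)
dhs = dhs_series(vitals).sort_values("date").reset_index(drop=True)
dhs["flag"] = flag_exceedances(dhs["total"], d=14, xi=1.96)

print("\nlast ten days:")
print(dhs[["date", "total", "flag"]].tail(10).to_string(index=False))
# The febrile episode starting day 25 lifts the temperature (and, with the
# accompanying tachycardia, sometimes the pulse) band scores; the day whose
# total crosses the personal upper bound is flagged.
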