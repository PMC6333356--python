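"""Rule-based night-time sleep analysis with adaptive personal boundaries.

Bed-pressure transitions are cleaned into definitive in-bed / out-of-bed
epochs, labelled with AASM-derived temporal rules (onset > 21.5 min, restless
< 11 min, good sleep >= one 90-min cycle, wandering = out-of-bed with
movement on several channels), and each night is compared against personal
deviation boundaries fitted on a 30-night history.
"""

import pandas as pd

import dwellsense as dw
from dwellsense import sleep as sl

HOME = "home001"
cfg = dw.SimulationConfig(
    n_homes=1,
    n_days=45,
    seed=5,
    sleep_disturbances=[dw.SleepDisturbanceSpec(HOME, d) for d in (35, 40)],
)
events, _, labels = dw.simulate_cohort(cfg)

dates = pd.date_range(cfg.start_date, periods=cfg.n_days, freq="D")
nights = [sl.analyse_night(events, d) for d in dates]
history = [n for n in nights if n.validity == sl.VALID][:30]
bounds = sl.adaptive_boundaries(history, xi=2.0)
print(f"personal bounds: sleep >= {bounds.min_sleep_minutes:.0f} min, "
      f"restless+wandering <= {bounds.max_restless_wandering_minutes:.0f} min")

print(f"\n{'date':12s} {'sleep':>6s} {'restless':>9s} {'wander':>7s}  verdict")
for n in nights[30:]:
    verdict = sl.detect_disturbance(n, bounds)
    print(f"{n.date.date()!s:12s} {n.sleep_minutes:6.0f} {n.restless_minutes:9.0f} "
          f"{n.wandering_minutes:7.0f}  {verdict}")
# The injected disturbance nights (days 35 and 40) show long wandering and
# shortened sleep, breaching the personal boundaries.
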