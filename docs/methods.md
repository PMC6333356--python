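# Methods

This note documents the models implemented in `dwellsense`, the parameters
that matter, the design choices made where the design was genuinely open,
and what the bundled simulator does and does not emulate.

## Sensor data model

Ten ambient channels ("viewpoints") per household: hallway and living-room
PIR, kitchen / pill-box / bedroom-door / bathroom-door motion, bed and chair
pressure, a front-door contact and a whole-home energy monitor. PIR and
motion channels emit `on` events only; pressure channels emit `on`/`off`
level transitions; the energy monitor carries a numeric watt value. Only
activations (`on` rows) count as firings in any aggregation — a pressure
release is not activity. Timestamps are naive local wall-clock time,
consistent within a home; all windows are clock-aligned and half-open.

Vital signs (systolic/diastolic pressure mmHg, pulse min⁻¹, temperature °C,
SpO2 %, weight kg, hydration a.u.) arrive in at most two sessions per day.

## Pattern profiling (six-hour SFPs, NMF, MAD banding)

* **SFP construction.** Hourly activation counts on the eight activity
  channels (front door and energy monitor are excluded: both are dominated
  by multi-occupancy effects), grouped into six-hour windows at the four
  clock categories morning [06–12), afternoon [12–18), evening [18–24),
  night [00–06). A window flattens hour-major into a 48-vector; one matrix
  *V* per category stacks a profiling period's windows as columns. Windows
  with no events are kept as zero columns — a quiet window is itself a
  (highly repeatable) pattern.
* **ACLS solver.** Blockwise ridge least squares
  (`H = (WᵀW+λI)⁻¹WᵀV`, then clip at 0; symmetrically for W), λ = 1e-4,
  up to 500 iterations, stop at relative objective change < 1e-6, best of
  `n_init = 10` uniform random restarts. Clipping can transiently raise the
  objective (the unconstrained block solve may rely on cancelling negative
  entries), so iterates that do not improve the best objective are not
  accepted; after five consecutive non-improving iterations the solve stops
  at the best iterate. The reported descent history is therefore monotone by
  construction. λ was set to 1e-4 because the regularisation floor at 1e-3
  leaves an exactly low-rank matrix at a residual near 1e-5, which misreports
  exact structure. The solver lands within a fraction of a percent of a
  long-run multiplicative-update solver on generic data (cross-checked in
  the tests against an independent implementation).
* **Rank selection.** RMS residual for ranks 1–6; the chosen rank is the one
  at the elbow — the last rank before relative improvement drops below 5% —
  or immediately any rank whose residual is numerically zero relative to the
  RMS magnitude of *V*.
* **Clustering.** k-means (10 restarts, fixed seed) on the columns of *H*,
  L1-normalised so cluster geometry reflects the *shape* of a window's
  activity rather than its intensity; k maximises the mean silhouette over
  2–10 (2–12 inside the profiling pipeline, which leaves headroom for the
  richer structure of pooled routine variants). Identical coordinates
  degenerate to a single cluster with an undefined silhouette.
* **MAD banding.** Cluster sizes `n_i` score
  `|n_i − median| / (1.4826 · MAD)`; below 1 → HSFP, at or above 2.5 → RSFP,
  LSFP in between. A score of exactly 1 goes to LSFP (the conservative side:
  fewer windows declared fully routine). If the MAD denominator is zero the
  scores are all zero — the formula cannot rank deviations when more than
  half the clusters are tied. The rule is two-sided as stated, so an
  unusually *large* cluster can also be flagged; an optional one-sided mode
  (small clusters only) is available and off by default.
* **Classification.** A live window is projected onto *W* with non-negative
  least squares, normalised the same way as in training, assigned to the
  nearest centroid (Euclidean) and inherits its cluster's band.

The banding is an order statistic over a handful of cluster sizes, so it is
meaningful only when the routine behaviour genuinely consists of several
comparably frequent recurring patterns plus rare ones; with a single
dominant behavioural mode the median cluster size is uninformative and no
RSFP can be assigned correctly. This is a property of the method, not of the
implementation, and it drives the simulator design below.

## Decision fusion

One temperature alert per reading strictly above 38.0 °C (absolute
threshold; an optional personal-baseline mode exists but is off by default).
One activity alert per RSFP-classified window, timestamped at the window
end. A UTI alert requires one of each within 24 h (configurable — deployed
descriptions vary between 12 h and 24 h), deduplicated to at most one alert
per home per rolling 24 h so a three-day episode produces roughly one alert
per day, not one per window.

The supervised baseline is a one-class SVM trained on (daily bathroom-visit
count, body temperature) pairs from clinician-annotated UTI-positive days,
features standardised with training statistics. The RBF kernel parameter is
taken as γ in exp(−γ‖x−y‖²) with the study's grid-searched value 10⁻²;
reading it instead as a literal kernel *width* (γ = 1/2σ² = 5000) makes
every standardised training point an isolated island and rejects even the
training centroid, so the γ reading is the only self-consistent one.
ν = 0.05. A degenerate (all-identical) training set falls back to an
exact-match distance rule and is flagged.

## Daily-routine anomaly detection

24 × 10 hourly matrices over all ten channels (hourly mean watts for the
energy monitor), min–max scaled per sensor with the training period's
extremes; test values clipped to [0, 1]; a zero-range sensor maps to a zero
column; hours with no events anywhere are imputed zero and flagged missing
(a silent hour is indistinguishable from an inactive one at this
granularity). The isolation forest uses 100 trees, subsample
min(256, n_train), a fixed seed, and the standard anomaly score
`s = 2^(−E[h]/c(n))`; days with `s ≥ 0.5` are abnormal. Thirty training days
are required (override available). The threshold is a fixed score, not a
contamination quantile, so the abnormal rate is free to vary between people.

## Sleep analysis

Night window 18:00 → 12:00 next day. First-level rules on the bed-pressure
epochs: occupied epochs separated by gaps under δ_merge = 2 min are merged
(turning over in bed); occupied epochs under τ_min = 1 min are dropped
(sitting on the bed in passing). Neither constant is published; both follow
the shortest AASM stage (N1 ≥ 1 min) and are configurable. Second-level
rules use the AASM stage durations (N1 1–7, N2 10–25, N3 20–40 min, cycle ≥
90 min): onset = first in-bed epoch > 21.5 min; restless < 11 min; good
sleep ≥ 90 min, else moderate; offset = end of the last in-bed epoch over
the onset threshold. An out-of-bed epoch is wandering when it contains ≥ 3
activations on ≥ 2 non-bedroom channels (so a plain bathroom visit — one
channel — is just out-of-bed); this operationalisation of "movement around
the house at night" is a design choice. Nights are excluded when away (no
bed data), under three hours in bed, or when all sensors fall silent for
≥ 6 h inside the window (treated as a technical outage). Personal
boundaries: minimum sleep μ − ξσ and maximum restless+wandering μ + ξσ over
≥ 30 valid nights, sample SD, ξ = 2 by default.

## Daily Health Score

The four-parameter band table (systolic BP, pulse, temperature, SpO2 →
scores 0–3) is applied after rounding to the table's printed grid (0.1 °C
for temperature, whole units otherwise, half-up), which closes the printed
band gaps (e.g. 38.04 °C falls in the 36.1–38 band). Diastolic pressure,
weight and hydration are recorded but unscored. The day's DHS is the worst
session total — the conservative clinical convention; the alternative (mean
of sessions) under-reports transient deterioration. The adaptive interval is
μ ± ξσ over the trailing 14 days with the sample SD (the standard-error
reading of the interval would shrink it by √14 and flag ordinary
fluctuation); ξ defaults to 1.96. Days exceeding the upper bound are
flagged; the first 14 days carry no flag.

## Evaluation

ρ_val = TV/(TV+NV), prevalence = positives/population, and
sensitivity/specificity/accuracy from confusion counts. Unvalidated alerts
are *not* treated as false — they form a third label and are dropped from
confusion tables. Zero denominators flag the metric undefined instead of
raising. Report rounding is half-up to two decimals.

## The synthetic cohort simulator

The simulator is the package's stand-in for private trial data and defines
the conditions under which the detectors are validated:

* **Day structure.** Hourly Poisson rates per channel with waking hours
  07:00–23:00, kitchen meal peaks, twice-daily pill-box access, and firing
  rates in the range real PIR deployments show (up to ~15/h at peaks). Each
  day draws one of two recurring behavioural variants per day-part (busy
  kitchen morning vs lounge morning; chair nap vs pottering afternoon; TV
  evening vs retiring early) — real routines are a small repertoire of
  recurring "views", and the profiling method's cluster-size statistics are
  only meaningful over such a repertoire.
* **Nights.** Bed entry ~22:00, ~9 h in bed, sub-minute turn-over blips, and
  habitual nocturia: one excursion per night in one of three circadian
  phases (~01:30, ~03:30, ~04:25), following a balanced three-night rotation
  with 5% off-plan nights — nightly nocturia is near-universal at this age
  and its phase follows evening routine, which is considerably more regular
  than an independent draw per night. Each excursion fires the bathroom
  door several times, the bedroom door on the way out and back, and the
  hallway in passing.
* **Disturbed nights** (spontaneous at 5%/night, or injected): wandering
  bouts at circadian-anchored times in the small hours (~00:45, 02:15,
  03:45), each pacing the hallway every couple of minutes with kitchen and
  occasional living-room triggers, replacing the night's routine pattern and
  shortening sleep by ~2 h. Sleep disturbance is among the most common
  behavioural symptoms in dementia, so a disturbed-night *pattern* exists in
  any three-month profiling period — which is precisely what lets profiling
  learn a rare cluster for it.
* **UTI episodes** (injected, default 3 days): night bathroom frequency
  multiplied (default ×3) across all phases, body temperature elevated to
  38.5 °C with accompanying febrile tachycardia (~+10 bpm/°C), and two
  night-wandering bouts — urinary infection in dementia typically presents
  with nocturnal confusion and wandering, and a pure count increase would be
  invisible to shape-based pattern clustering by construction.
* **Nuisances.** Guest days (5%, daytime rates doubled, front-door
  activity), optional pet motion, whole-sensor outage gaps (2% of days,
  8 h), all labelled.
* **Gross routine-anomaly days** (injected): all activity channels firing at
  daytime-peak rates through 00:00–06:00.

Identical configuration and seed give byte-identical output files; every
injected condition is recorded in the ground-truth labels.

**What the simulator does not emulate:** multi-resident households beyond
guest-day bursts, sensor flutter and double-triggering, seasonal and
weekday/weekend drift, gradual behavioural change, medication effects on
vitals, or the annotation noise of human self-reports. Passing
injection-recovery tests therefore shows that the algorithms recover the
signals they are designed for under clean recurring-pattern conditions with
realistic count levels and nuisance rates — not that their operating points
transfer to any particular deployment.

## Validation experiment sizes

The bundled experiments are scaled to run in seconds: one home, 120 days
(90 profiling + 30 test) with three injected UTI episodes for the fusion
detector and baseline; 100 nights (30 boundary-fitting) with seven injected
disturbances for the sleep analyser; the same cohort's 70 post-training days
with three injected gross days for the isolation forest; 48 × 90 matrices
for the solver cross-check. The worked-example statistics are computed
directly from the published count tables they summarise.

## Known limitations

* The MAD banding degrades when cluster sizes tie exactly (zero MAD) or when
  the size distribution is bimodal; both occur occasionally at unlucky seeds
  and yield silent (no-alert) profiles rather than false alarms.
* RSFP classification assigns a *novel* pattern to its nearest learned
  cluster; a genuinely unprecedented anomaly is only flagged if it lands
  nearer a rare cluster than a routine one.
* The sleep analyser cannot resolve REM or distinguish quiet wakefulness in
  bed from sleep; "sleep" means sustained bed occupancy.
* The technical-outage exclusion (6 h all-sensor silence) cannot separate an
  outage from a genuinely empty house overnight.
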