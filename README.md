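# teftool

Estimation of the thermic effect of food (TEF) from minute-resolution
whole-room indirect-calorimetry sessions, including a NEAT-removal method
based on lag-optimized integrated physical activity, plus a synthetic
chamber-session simulator with exact ground truth for validating every
estimator.

## What it does

A chamber session is a complete 1-minute grid of energy expenditure
(kcal/min) and triaxial accelerometer activity (counts/min) over a single
stay, with a meal schedule. Four TEF estimators are provided:

- **`delta_ee`** — fed-minus-fasted EE over a clock-aligned period (the
  reference method; needs two sessions).
- **`schutz_rmr`** — intercept of EE regressed on raw minute activity (EE
  at zero activity) minus the seated pre-breakfast mean (0715–0745), times
  the period duration.
- **`schutz_smr`** — same intercept minus the sleeping metabolic rate
  (mean EE 2300–0700).
- **`neat_free`** — the original method: activity is integrated over a
  moving window (half-width 0–30 min) at a lag (−20 to +20 min); the
  (window, lag) pair maximizing the Pearson correlation with EE is found
  by exhaustive grid search per analysis period; NEAT is modelled as the
  fitted slope times the rise of integrated activity above its period
  minimum, subtracted from EE; TEF is the postprandial area of the
  NEAT-free series above the preprandial NEAT-free mean.

The simulator (`teftool.simulate`) emits 33-h sessions (2200 → 0700 two
days later, sleep 2300–0700, meals 0800/1200/1900) whose EE is an additive
mixture of circadian basal (with sleep dip), gamma-shaped per-meal thermic
responses, an activity-driven NEAT component built with a known
integration kernel, and Gaussian noise — and returns the exact latent
components, so estimator bias/RMSE can be measured (`recovery_experiment`).
Method agreement uses Bland–Altman limits (`teftool.compare`).

## CLI

```bash
# synthetic session with ground-truth components
teftool simulate --seed 42 --out session.csv --truth truth.csv

# estimate TEF (all methods) over the morning window
teftool estimate --session session.csv --meals meals.csv \
    --method all --period morning --out results.csv

# fed-vs-fasted reference needs the second session
teftool estimate --session fed.csv --fasted fasted.csv --meals meals.csv \
    --method delta

# Bland-Altman agreement between two methods across subjects
teftool compare --results results.csv --pair neat_free:delta_ee \
    --out ba.csv --plot ba.png
```

Session CSV: header `timestamp,ee_kcal_min,activity_counts` (ISO-8601
timestamps, strict 1-min grid), or `timestamp,vo2_l_min,vco2_l_min,
activity_counts`, in which case EE is computed from gas exchange with the
Weir coefficients (3.941, 1.106, −2.17; configurable). Meals CSV:
`time,energy_kcal,label`. Missing minutes are a hard error unless
`--fill-gaps linear --max-gap N` is given. EE is advanced by 2 min at load
time (calorimeter response; `--no-advance` or `[calorimetry].advance_min`
to change).

Configuration is TOML (`--config cfg.toml`) with sections `[periods]`,
`[integration]`, `[calorimetry]`, `[simulate]`; defaults encode the
protocol windows (pre-breakfast 0715–0745, morning 0800–1200, waking
0800–2300, two-meal waking 1200–2300, sleep 2300–0700). Unknown keys are
errors; grids wider than the validated ranges warn. Exit codes: 0 OK,
1 validation error, 2 degenerate fit under `--strict`.

## Library example

```python
from teftool import SimulationParams, simulate_session, tef_original

session, truth = simulate_session(SimulationParams(), seed=1)
result = tef_original(session)           # morning neat-free TEF
print(result.tef_percent, truth.true_tef_fraction["breakfast"] * 100)
```
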