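# phenowatch

Passive smartphone monitoring turns a phone into a continuous, objective
probe of social behavior: who a person calls and how often, which apps
they open, and where they go. In cognitive aging this matters because
social withdrawal is among the earliest symptoms of Alzheimer-type
decline, while questionnaires measuring it rely on recall and insight —
exactly what the disease erodes. `phenowatch` is a reusable implementation
of such an analysis for three-group cohorts of older adults (cognitively
normal **CN**, subjective cognitive decline **SCD**, cognitively impaired
**CI**): it validates raw event streams, computes a fixed catalogue of
42 behavioral outcomes in three families (calls, app use, location), and
runs the accompanying statistics. Because raw cohorts of this kind are not
publicly deposited, the package ships a synthetic cohort generator with
known ground truth, so every stage is testable by parameter recovery.

## What it computes

**Features.** From per-participant streams of call events, app-foreground
sessions and GPS fixes: per-day call counts, talk durations, distinct and
single-use contacts per direction, the repeated-contact ratio
(total calls / distinct contacts); per-day app openings (overall, at
night, per category) and mean session lengths; and stay-point mobility —
a *stay point* is an episode in which consecutive fixes remain within
350 m of the episode's first fix for ≥ 60 min, stay points merge into
*places*, *home* is the place with the most 00:00–06:00 dwell, and
*trajectories* connect consecutive stay points, yielding counts of places,
nightly and outside-office-hours visits, travel distance/time, distance
from home, and percent time at home.

**Statistics.** Each outcome x is log-transformed and standardized to the
control group, z = (log(x + δ) − μ_CN) / σ_CN, so effects are in
control-SD units. Group differences come from OLS per outcome,

    z ~ group + age + sex + education

with the three pairwise contrasts (SCD−CN, CI−CN, CI−SCD) read off
re-leveled fits, and NPI (Neuropsychiatric Inventory) associations from
`z ~ NPI_total + age + sex + education`. P-values are Bonferroni-corrected
by the fixed factor 3 (the three correlated outcome families) and rendered
as tiers: `**` p<.01, `*` p<.05, `.` p<.10. A nonparametric demographic
screen (Mann-Whitney U for sex, Spearman rho for age/education) runs in
controls. See `docs/methods.md` for every definition and default.

## Worked example

```python
from phenowatch import (SimConfig, simulate_cohort, extract_features,
                        standardize, group_contrasts)

cfg = SimConfig(n_per_group={"CN": 60, "SCD": 20, "CI": 20}, seed=7,
                duration_days=(7, 21))
cohort, truth = simulate_cohort(cfg)          # raw streams + ground truth
table = extract_features(cohort)              # participants x outcomes
z, est = standardize(table, table.index[table.group == "CN"])
res = group_contrasts(z, table[["group", "age", "sex", "education_years"]])
print(res[(res.contrast == "CI-CN")
          & res.outcome.isin(["calls_outgoing_unique_contacts",
                              "calls_mean_repeated_contacts",
                              "apps_all_times_opened"])])
```

prints (seed 7):

```
                       outcome contrast   beta    se  p_raw  p_adj
calls_outgoing_unique_contacts    CI-CN -1.091 0.290   0.00  0.001
  calls_mean_repeated_contacts    CI-CN  0.105 0.293   0.72  1.000
         apps_all_times_opened    CI-CN -0.625 0.264   0.02  0.059
```

The impaired arm of this simulated cohort calls about one control-SD fewer
distinct contacts (p_adj ≈ .001 after the family correction) and opens
apps ≈ 0.6 SD less often (a trend, p_adj ≈ .06); the repeated-contact
ratio, whose injected shift is modest and whose CI arm is only n = 20,
lands near zero in this particular draw — at these group sizes single
draws of weaker effects are noisy, which is exactly what the package's
replicate-based recovery tests quantify. In the same run, the control
group's median repeated-contact ratio is 1.87 and its median 81.5 app
opens/day reflect the generator's control profile.

The same pipeline runs from the shell:

```bash
phenowatch simulate --out data/ --seed 7       # CSV streams + ground_truth.json
phenowatch validate --data data/
phenowatch extract  --data data/ --out features.csv
phenowatch analyze  --features features.csv --out report/
```

`report/` then holds `contrasts.csv` (one row per outcome, β (SE) and
adjusted p per contrast), `npi.csv`, `demographic_screen.csv` and effect
heat maps.

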