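# Methods

`phenowatch` implements a passive-monitoring analysis pipeline for
smartphone-derived social behavior in three diagnostic groups of older
adults — cognitively normal (CN), subjective cognitive decline (SCD) and
cognitively impaired (CI) — together with a synthetic cohort generator that
stands in for raw data of this kind, which is never publicly deposited.
This note documents the models, the defaults and why, the numerical
choices, and what the tests do and do not establish.

## Outcome definitions

All outcomes are computed per participant over a 7–42-day observation
window and fall into three families (the unit of the multiple-comparison
correction): **calls**, **app use**, **location**.

*Per-day normalization.* A "per day" outcome is the study total divided by
the number of days of participation. We use the nominal window length
(`last_day − first_day + 1`), not the count of days with data: the
monitoring app records continuously, so a day without events is an
informative zero, not a hole.

*Calls.* Counts, talk durations, distinct contacts and single-use contacts
(contacts appearing exactly once over the whole window) are computed within
direction (incoming / outgoing / missed). A *non-response call* is an
outgoing call with zero talk duration; missed calls always have duration
zero. The *repeated-contact ratio* ("mean repeated contacts") pools all
directions: total calls divided by the number of distinct contacts over all
calls; it is ≥ 1 whenever defined and missing when there are no calls.
Because the catalogue lists "number of nonzero-duration calls" only for
incoming calls, both the all-events count and the nonzero-duration count
are computed for that direction.

*App use.* An "open" is a foreground-session start; a session is "at
night" iff its start instant lies in [00:00, 06:00) — openings are
instants, so the window membership of the start decides. Per-category mean
session length is a study-level ratio (total category foreground time over
total category opens) and is missing, not zero, for a never-opened
category. Sessions of one participant may never overlap (one app in the
foreground at a time); overlap is a validation error, not a warning.

*Location.* A **stay point** opens at a fix and extends while subsequent
fixes remain within 350 m of that *first* fix; it is emitted if the dwell
(last inside fix minus first fix) reaches 60 min, and scanning resumes at
the first outside fix whether or not it was emitted. A fix-to-fix gap
longer than 30 min closes any open candidate under the same emission rule,
so data holes cannot fabricate dwells. Stay points are merged into
**places** greedily in time order at the same 350 m radius between a stay
point's center and a place's founding center — the merge rule is not pinned
down by the outcome definitions, so re-using the stay-point radius is the
least-surprising choice and is configurable. **Home** is the place with the
most dwell time between 00:00 and 06:00 over the study (ties: earliest
first visit); with no night dwell there is no home and every home-relative
outcome is missing. "Nightly" and "outside office hours" (weekdays after
19:00, any time on weekends) stay points use *window-intersection*
semantics — a dwell qualifies if its interval overlaps the window — because
dwells are intervals and only clock boundaries are given; arrival-instant
semantics is available via `semantics="arrival"`. Both the nightly count
and the nightly unique-place count exclude home. Distance traveled sums
haversine hop lengths over the fixes of each **trajectory** (the segment
between consecutive stay points), is aggregated per calendar day (of the
departure) and summarized as mean and SD across days that contain at least
one trajectory; a participant with no trajectories has 0 trajectories/day
and missing travel summaries (an SD needs repeated units, and absence of a
trajectory may reflect missing fixes rather than immobility). Distances
from home use place centers, not raw fixes, for robustness to GPS jitter.
Percentage of time at home is normalized by total stay-point dwell time;
the window-normalized variant is also reported
(`loc_pct_time_at_home_window`), giving an 18-column location block.

*Missingness.* Undefined-by-zero outcomes propagate as missing values into
the cohort table and are counted in the per-variable completeness report;
nothing is imputed. Analysis is complete-case per outcome.

## Statistical procedure

Each outcome is log-transformed and standardized to the control group:
z = (log(x + δ) − μ_CN) / σ_CN with the sample SD (ddof = 1). The offset δ
is applied only to outcomes containing zeros; the default policy takes the
smallest positive observed value of that outcome (δ = 1 and δ = half the
minimum are available). Outcomes with all-missing or zero-variance control
values are dropped with a recorded reason. On strictly positive outcomes
(δ = 0) the whole pipeline is invariant to affine rescaling of the raw
units (km vs m), which the tests assert exactly.

Group differences come from one OLS model per outcome,
`z ~ group + age + sex + education`, with the three pairwise contrasts read
off a re-leveled reference (CN reference: SCD−CN, CI−CN; SCD reference:
CI−SCD) — equivalent to the single-model formulation and immune to
subgroup-fit inconsistencies. NPI associations fit
`z ~ NPI_total + age + sex + education` on the participants with an NPI
score (optionally also adjusting for diagnostic group, and optionally per
NPI domain). All p-values are two-sided coefficient t-tests, Bonferroni-
corrected by the **fixed factor 3** — the number of correlated outcome
families — not by the number of outcomes. Significance tiers on adjusted
p: `**` < .01, `*` < .05, `.` < .10. Rank-deficient designs and subgroups
with fewer than 3 complete cases are flagged in the results table, never
silently dropped; NPI fits with fewer than 10 complete cases are flagged
`low_n`, and a constant score yields no estimate.

The demographic screen (controls only) uses a two-sided Mann-Whitney U for
sex and Spearman rho for age and education on the raw outcomes, with a
Shapiro-Wilk normality check reported per outcome; outcomes with fewer
than 3 non-missing control values are skipped.

## Synthetic cohort generator

The generator's defaults are the study conditions: group sizes
(209, 55, 24); windows uniform on [7, 42] days; ages normal per group
(63±8, 61±7, 68±8) truncated to [46, 83]; female proportions
(.584, .618, .333); education 11±2, 10±2, 13±5 years; NPI totals for
SCD/CI drawn from a gamma-Poisson (negative-binomial) mixture matched to
means/SDs 7.7±11 and 5±5.6, split over the 12 symptom domains (so the
total always equals the domain sum) and available for 35% of SCD and 92%
of CI participants. Control behavioral rates are anchored to the
control-group medians of the catalogue (≈1.25 calls/day, ≈86 app
opens/day of which ≈2% at night, ≈0.4 distinct places/day, ≈78% of dwell
time at home).

*Calls.* Daily counts are Poisson with participant rate
`group rate × frailty × exp(−0.02·(age−63))`; the frailty is lognormal with
mean one (σ = 0.6 between participants), so closed-form expected rates are
exact. Contacts are drawn from a participant-level categorical whose
weights are a symmetric Dirichlet draw over the contact pool; the
concentration parameter interpolates between "nearly all calls to one
contact" (→ 0) and "uniform over the pool" (→ ∞, the classical occupancy
regime m(1−(1−1/m)^k)). The CI profile has a smaller pool (11 vs 15),
lower outgoing share and lower concentration (0.5 vs 1.0), producing the
impaired-group pattern: fewer distinct outgoing contacts and a higher
repeated-contact ratio. Stated fractions of outgoing calls are
non-response (15%) and of incoming pickups zero-duration (10%).

*App use.* Per-category Poisson counts with the same frailty/age
structure; lognormal durations; overlapping draws are truncated at the
next start so the foreground invariant holds by construction. The CI
profile scales open rates down (overall ≈ 0.55×, communication and
news/magazines more strongly).

*Mobility.* Each participant has a home anchor and habitual places kept
≥ 1.5 km apart; days contain Poisson-many outings (≤ 3), novel-place
visits with daily probability `p_travel`, and overnight stays away with
weekly rate `night_out_rate`. Every itinerary boundary is snapped to the
5-min fix grid and every intended dwell lasts ≥ 70 min, so the true
stay-point set is exact by construction: an arrival coincides with a grid
fix at the anchor, and the nearest commute fix is always far outside the
350 m radius (commutes run at 30 km/h ⇒ 2.5 km between fixes). Optional
noise visits (15–40 min, inserted mid-commute, ≥ 450 m from any anchor)
exercise the detector's rejection rule. Fixes carry Gaussian jitter with
σ = 15 m ≪ 350 m, keeping truth unambiguous while still exercising the
clustering. An NPI-mobility coupling (+0.025 per point on the log travel
scale) gives the association stage something real to recover.

*Feature-level simulator.* For statistical calibration
(`simulate_feature_cohort`) outcomes are drawn directly as lognormal
values with group shifts specified in exact control-SD units (the residual
and age-effect variance components are known, so the standardized truth is
exact). This is the tool for type-I-error and effect-recovery studies of
the inference stage, where the raw-stream generator cannot provide an
analytically exact standardized truth (distinct-contact counts are a
nonlinear occupancy functional of pool size and call volume).

*What the generator does not emulate.* Street networks and transport
modes, irregular GPS sampling and dropouts (beyond what the gap rule is
tested with directly), within-day rate rhythms beyond a waking-hours bump,
contact networks shared between participants, SMS/message content, and
partner co-mobility. Passing tests therefore show that the pipeline
measures what it defines and recovers what is injected — not that real
cohorts behave like the generator.

## Numerical choices and degenerate inputs

- Haversine distances on the IUGG mean sphere (6371.0088 km); the test
  oracles use the independent atan2 great-circle formulation.
- Fewer than 2 fixes ⇒ empty stay-point list; a GPS-less participant gets
  an all-missing location block.
- Latitude translation is not an exact isometry of great-circle distance
  (east-west scales change by cos φ), so exact translation invariance is
  asserted for longitude shifts and approximate invariance for latitude.
- The time-accounting identity dwell + travel + explicit gaps = window
  length holds exactly by construction and is asserted in tests.
- Control SDs use ddof = 1; the standardization contract (control z mean 0,
  SD 1) is asserted to 1e-10.
- Problem sizes in the test suite are scaled to keep the full run fast:
  ground-truth recovery uses 200 participants at 7–14-day windows,
  feature-oracle comparison 100 participants at 7–10 days, raw-stream
  effect-recovery replicates 160 participants at 7–21 days; statistical
  calibration uses 100 replicates throughout. The acceptance script runs
  the full default conditions (288 participants, 7–42 days).

## Known limitations

- The place-merge radius and the "unique nightly excludes home" choice are
  conventions where the outcome catalogue is silent; both are configurable.
- Travel-day summaries condition on days with an observed trajectory;
  cohorts with very sparse GPS will overstate per-day travel relative to a
  zero-filled convention.
- The raw-stream generator's standardized effect sizes are emergent (from
  pool/rate/concentration shifts), so raw-pipeline recovery is asserted on
  sign and direction, with exact-magnitude recovery delegated to the
  feature-level simulator.
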