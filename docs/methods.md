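# Methods

## Model structure

The model is a discrete-time Markov cohort recursion over six health states
— Healthy, breast cancer Stage I, II, III, IV, and Dead — with one-year
cycles from age 35 to age 74 inclusive (40 cycles; `t = 0` at entry). The
cohort starts 100% Healthy. Women diagnosed with breast cancer move to the
stage-specific state at diagnosis and remain there: treatment, remission and
stage progression after diagnosis are deliberately not modelled, so the
number and stage of detected cancers proxies for longer-term outcomes.
Attendance is 100% by assumption.

Transitions out of Healthy are diagnosis (per stage) and background death.
The per-cycle diagnosis probability is the product

    ASIR(age) × stage proportion × test sensitivity × risk multiplier

with the *screened* stage distribution and a sensitivity of 0.8 at imaging
screens, and the *unscreened* stage distribution without a sensitivity
factor when a cancer presents clinically. The risk multiplier (0.5 / 1 / 2
for the low / intermediate / high PRS groups) scales incidence only — never
mortality, costs or utilities. Diagnosed women die at the stage-specific
annual breast-cancer rate plus the flat all-cause rate (summed, clamped at
1); Dead is absorbing. Rows of every transition matrix sum to 1 to 1e-12,
and the engine raises an error if a state's exit mass would exceed 1.

## Detection-timing conventions

When can a cancer surface? Three conventions are implemented
(`ModelConfig.detection_mode`):

* `screen_only` — detection only at imaging screens.
* `screen_plus_interval` — additionally, clinical presentation at the
  unscreened stage mix in *every* non-screen cycle.
* `screen_plus_preentry` (default) — clinical presentation only in cycles
  *before* the arm's screening coverage begins; once a woman is inside a
  programme capable of detection, cancers surface at screens only.

The default needs justification, because it is the crux of the whole
comparison. In this model detection is the only event that generates disease
cost and breast-cancer mortality — an undetected cancer is, mechanically,
not there. Under `screen_only` the current programme (ten mammograms)
detects far less than the tailored programme (13–40 screens per group), so
screening less is always cheaper and never worse: the tailored programme is
dominated by construction and the unscreened stage distribution is never
used, which cannot be the intended reading of a model that tabulates one.
Under `screen_plus_interval` both arms detect essentially every incident
cancer and the arms differ only in stage mix, inflating lifetime case counts
to ~46–58 per 1000. The pre-entry convention sits between the two: women in
the current arm present clinically (unscreened stage mix) at ages 35–49,
before their first mammogram at 50, while tailored-arm women are covered
from their first imaging screen at 40 (self-examination detects nothing and
does not start coverage, so ages 35–39 are clinical-presentation years in
every group). This is the only convention under which the published
qualitative result — tailored screening cheaper *and* more effective — is
structurally possible, and it reproduces both published lifetime case counts
(our 31.3 vs 31.2 per 1000 in the mammogram arm; 24.0 vs 25.5 in the
tailored arm). Coverage is per-protocol: it starts at the arm's first
imaging screen and, once started, never lapses (no clinical detection after
the last screen).

## Reward accounting

Rewards are accrued on start-of-cycle occupancy and discounted by
`(1 + r)^-t` with r = 0.03 per year; a full survivor therefore accrues
Σ 1.03^-t ≈ 23.81 discounted life years. QALYs weight occupancy by state
utility (Healthy 1.000; stages 0.731 / 0.731 / 0.599 / 0.352; Dead 0).
Half-cycle correction is off by default and available as a flag.

Costs comprise:

* screening test costs (mammogram 110 SGD, ultrasound 230 SGD,
  self-examination free), charged to the healthy occupancy at each screen;
* genotyping entry costs (buccal swab 210 SGD + questionnaire 2 SGD),
  charged once at t = 0 in the tailored arm;
* stage-specific direct medical costs (63,983 / 78,226 / 91,129 / 110,136
  SGD for stages I–IV), charged per year spent in the diseased state
  (`stage_cost_mode="annual"`, the default) or once at diagnosis
  (`"once_at_diagnosis"`).

Annual accrual is the default because it is the standard state-reward
convention for spreadsheet Markov models and it is the only reading
consistent with the published lifetime cost levels: once-at-diagnosis
charging yields ~1.5–2.5k SGD per woman (an order of magnitude below the
published 20–24k SGD) and, because the tailored arm detects more cancers at
entry-adjacent ages, it also flips the sign of the incremental cost. Under
annual accrual the model reproduces the direction and rough size of the
published cost saving.

## What the model does and does not reproduce

With the default conventions the deterministic model reproduces the
published case counts, lifetime death probabilities (12.6% vs published
13.4% in the mammogram arm) and, under the interval-detection convention,
the incremental cost (−3,414 vs −3,671 SGD per woman). It does **not**
reproduce the published incremental life years (0.9720) and QALYs (0.9884),
and therefore none of the published ICER magnitudes. This is not a tuning
problem but an internal inconsistency of the reference results: with both
arms sharing the same all-cause mortality, the discounted life-year
difference is bounded by the largest interim gap in cumulative death
probability times Σ 1.03^-t. The published death probabilities differ by
0.4 percentage points (13.0% vs 13.4%) and the case counts cap breast-cancer
deaths near 2.5% of the cohort, so the life-year difference cannot exceed
roughly 0.5 even under the most extreme death-timing assumptions, and is
~0.06–0.12 under any realistic one. Our incremental QALYs (~0.085) sit in
that feasible range; an incremental QALY near 1 per woman would require an
order of magnitude more breast-cancer deaths than either model produces.
Consequently the ICER magnitudes here are a factor ~15 larger (same sign,
same quadrant, same dominance conclusion, in every scenario).

## Sensitivity analyses

*One-way:* every tabulated input is varied one at a time between its bounds
— the printed ranges for costs and utilities (the stage II utility maximum
is reconstructed as 0.83, mirroring stage I, because the printed range
collapses onto its minimum), and 80%/120% of baseline elsewhere. Utilities
and the imaging sensitivity are capped at 1; perturbing one proportion of a
stage simplex renormalizes the simplex; perturbed sets bypass the
cross-parameter monotonicity validation (a one-way excursion may break it).
Entries are sorted by ICER span with ties broken by parameter id, so the
tornado ordering is deterministic. Because our ICER denominator is ~12x
smaller than published, cost-side parameters (notably the stage II cost)
dominate our tornado, and the published top-four ranking (risk multipliers,
stage II cost, sensitivity) is only partially reproduced.

*Probabilistic:* only cost parameters (Gamma) and stage utilities (Beta)
vary; incidence, mortality, stage mixes, multipliers and sensitivity are
fixed. Distributions are moment-matched: the mean equals the baseline value
and the printed range (±30% for costs, ±0.1 for utilities) is treated as a
95% interval, sd = half-width / 1.96. If the implied Beta variance is
infeasible the sd is shrunk to the largest feasible value and logged. Each
parameter draws from its own substream spawned deterministically from the
master seed and the sorted parameter ids, so results are independent of
evaluation order and exactly reproducible. Because cost and utility draws
never alter transition probabilities, each arm's trace is computed once and
per-draw outcomes are exact linear functions of the draws; a test pins this
fast path to a full re-run of the accumulator. The CEAC reports
P(wtp · ΔQALY − ΔC ≥ 0) per threshold, and the certainty threshold is
computed exactly as max(0, max ΔC/ΔQALY) over draws (infinite if any draw
is dearer and no more effective).

## Scenarios

The percentile-cutoff scenarios rebuild the tailored arm with multipliers
fixed at 0.5/1/2. The base case (60L-35I-5H) uses the observed Asian
population proportions 0.51/0.41/0.08; for the alternative cutoffs no
observed proportions are available, so the nominal percentile widths are
used as proportions (0.60/0.30/0.10, 0.40/0.55/0.05, 0.40/0.50/0.10) — a
logged, configurable choice. The ending-age variant truncates the tailored
schedules at 69 while leaving the current arm and the 35–74 horizon
unchanged.

## Synthetic data and the microsimulation oracle

The generator emulates the *shape* of the input tables: an incidence curve
that rises with age and plateaus (scaled 0.7–1.4× with log-normal jitter),
stage simplexes from Dirichlet draws concentrated on the baseline mixes,
log-normal cost dispersion with stage costs kept increasing, utility jitter
(±0.05) kept non-increasing with stage, and risk-group proportions from a
Dirichlet around 0.51/0.41/0.08. Zero dispersion returns the baseline set
verbatim. It does not emulate correlated parameter errors, age-specific
all-cause mortality, or secular trends — passing tests on synthetic sets
demonstrate internal consistency of the engine, not calibration to any real
registry.

The microsimulation oracle simulates individual women with the *same*
transition matrices and reward conventions as the cohort engine (shared code
path), realizing transitions stochastically. Agreement within three
Monte-Carlo standard errors at n = 200,000 across ten random parameter sets
isolates errors in the cohort recursion and accounting; it cannot detect an
error common to both paths (e.g. a wrong parameter value).

## Numerical choices and edge cases

Diagnosis probabilities are clamped to [0,1]; stage death probabilities to
≤1. Simplex validation tolerance is 1e-9. Ages are integers; screens occur
at integer ages. ICERs are reported signed even when dominance makes the
ratio awkward to interpret, with the dominance label always attached; a zero
QALY difference yields an explicit undefined flag rather than a division.
Deterministic runs are seed-free; all stochastic entry points take an
explicit seed and re-running with the same seed is byte-identical.

## Known limitations

No tumour natural history, overdiagnosis, recall cascades or attendance
below 100%; a flat all-cause mortality rate rather than a life table (an
age-specific table can be supplied through the same age-rate format); plain
SGD with no inflation adjustment; risk-group membership fixed at entry (no
re-scoring); pairwise comparisons only, no efficiency frontier over more
than two strategies.
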