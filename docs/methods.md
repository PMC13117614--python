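# Methods

## Model structure

The package implements a cost-effectiveness model of a single round of
low-dose-CT (LDCT) lung cancer screening versus passive surveillance
(voluntary check-ups with chest X-ray, no recall) in a cohort aged 55–80
with past occupational asbestos exposure and at least 10 pack-years of
smoking.  The cohort is stratified into 12 subgroups (2 sexes × 6 age
groups: 55–59 … 75–79, 80), each entering the model at the band midpoint
(the open 80 group at exactly 80).

A **decision tree** splits each stratum at time zero.  In the screening arm
the screen-detectable prevalence p enters the *diagnosed* stage I–IV states
with the screening stage distribution; of the remaining 1 − p, an age-band-
specific fraction experiences an LDCT false positive, incurs its one-off
cost and disutility, and then behaves exactly like a person with no lung
cancer.  In the standard-care arm the *same* mass p enters the *undiagnosed*
states with the same stage distribution (false negatives are not modelled,
which makes the two arms structurally identical at baseline apart from
diagnosed/undiagnosed status), and check-up attenders (10% within the first
year) can have an X-ray false positive.

A **Markov cohort model** with 3-month cycles then follows each stratum to
extinction.  States: no lung cancer; undiagnosed stage I–IV (standard care
only); diagnosed stage I–IV with a years-since-diagnosis tunnel — 20
quarterly slots covering years 1–5 plus one absorbing 6+ slot, so
lung-cancer mortality can depend exactly on stage, year since diagnosis, sex
and age band; death from lung cancer; death from other causes.  Undiagnosed
disease can progress one stage per cycle (I→II→III→IV) or be diagnosed;
people cannot die of lung cancer before diagnosis.  Diagnosed people keep
their stage at diagnosis until death (no modelled relapse or remission; the
mortality probabilities implicitly blend cure and relapse).  Other-cause
mortality is asbestos-adjusted, sex- and single-year-of-age-specific, and
death is forced at age 100, which guarantees cohort extinction.

### Event order within a cycle

Competing events are applied in a fixed order: **other-cause death → lung-
cancer death (diagnosed) → diagnosis (undiagnosed) → progression**.  At this
cycle length the ordering materially affects results, so it is a documented
model constant, used identically by the cohort engine, the calibration
sub-chain, the overdiagnosis counterfactual and the microsimulation oracle
in the test suite.  Consequences worth noting: a person cannot be diagnosed
and die of lung cancer in the same cycle, and a newly progressed cancer can
first be diagnosed at its new stage one cycle later.

### Accrual, discounting, half-cycle correction

Life years and QALYs accrue per cycle as the trapezoidal average of the
start- and end-of-cycle state occupancies (half-cycle correction), times the
cycle length, times a discount factor (1+r)^(−t) evaluated at the cycle
midpoint; r = 3% per year.  One-off costs cannot be half-cycle corrected:
decision-tree costs and disutilities fall undiscounted at time zero, and the
stage-specific diagnosis + treatment cost is charged once to the newly
diagnosed mass, discounted to the start of the diagnosis cycle.  Standard-
care detection costs after the first year are limited to people being
diagnosed (one check-up visit per diagnosis).  With the discount rate set to
0 and half-cycle correction off, accrual reduces to a plain end-of-cycle
Riemann sum (a regression-guarded identity).

Age-dependent quantities are re-evaluated from the cohort's current age
every cycle: lung-cancer mortality bands 55–69 / 70–84 (ages above 84 carry
the 70–84 values forward), utility bands 55–64 / 65–74 / 75+, other-cause
mortality per single year of age (stepwise).  The LDCT false-positive band
(<65 / ≥65) is resolved once, at the screening age.

### Utilities

People without lung cancer (including undiagnosed lung cancer, which is
presymptomatic by construction) use a smoking-adjusted general-population
utility by sex and age band.  Diagnosed lung cancer uses a stage-I utility
times stage ratios (II, III, IV ≤ 1), declining with age by the same
relative profile as the sex-specific no-LC utility (ratio to the 55–64
band), capped at the concurrent no-LC utility.  One-off QALY decrements
apply to all screened participants (anxiety) and to false positives in
either arm.

## Calibration

The 3-month diagnosis probabilities from undiagnosed stages I–III are not
observable; they are calibrated so that the standard-care arm's distribution
of *stage at diagnosis* (simulated by running the undiagnosed sub-chain from
the screening stage distribution) matches the observed standard-care
distribution.  The stage-IV diagnosis probability and the progression
probabilities are fixed inputs.  The solver is a damped multiplicative
fixed-point iteration on stage shares, p_s ← p_s (target_s / simulated_s)^λ
with λ = 0.5, probabilities clipped to [10⁻⁶, 1], tolerance 10⁻⁴ per stage
(max absolute deviation), at most 500 iterations, with a bounded
least-squares fallback; non-convergence is always reported, never silent.
Calibration is pooled across strata (stratum-weighted distribution) by
default because mortality differs by stratum but a single probability set is
carried in the configuration; per-stratum calibration is available through
the same function for sensitivity work.

## Outcomes

Incremental results are screening minus standard care per screening
participant, aggregated over subgroups as ratio-of-weighted-averages (never
average-of-ratios), with dominance labels on the CE-plane quadrants.
**Overdiagnosis** is the proportion of screen-detected cancers whose
counterfactual standard-care history ends in other-cause death before
diagnosis; it is computed deterministically by running the undiagnosed
sub-chain on the screen-detected cohort and collecting the mass absorbed by
other-cause death, reported per 10,000 screened.  **False-positive
surgeries** are screened × mean LDCT false-positive probability × surgery-
given-false-positive probability (a count outcome; the surgery cost is part
of the bundled false-positive work-up cost).  Per-10,000 tables round half
away from zero; internal values are never rounded.

## Probabilistic sensitivity analysis

2000 iterations by default.  Families (unstated in the underlying study;
these are the conventional ones): Beta for probabilities and
utilities, method-of-moments around the base-case mean with coefficient of
variation 0.2 (variance capped below m(1−m)); Gamma for costs (CV 0.2);
Dirichlet with concentration 100 for the two stage distributions; point mass
for the discount rate, cycle length and the registry-derived other-cause
mortality.  Parameters are independent.  Each iteration re-calibrates the
diagnosis probabilities against its sampled stage distributions (warm-
started from the base-case solution); failed calibrations are excluded and
counted.  Summaries are means and 95% credible intervals defined as
empirical 2.5th/97.5th percentiles with linear interpolation between closest
ranks (so intervals are exactly reproducible).  The CEAC evaluates
P(λ·ΔQALY − Δcost ≥ 0) on a grid of λ from 0 to EUR 60,000 in steps of
1,000.  Scenario analyses reuse the base seed (common random numbers) to
suppress Monte-Carlo noise in between-scenario comparisons.

## Synthetic default parameters

The original parameterisation came from regional registries and an
unpublished appendix; only aggregates are public.  The synthetic defaults
reproduce those aggregates *by construction* — overall screen-detectable
prevalence 0.0253 (age profile rising from 55–59 to 75–79 and dipping at
80, scaled to the weighted mean), population-weighted LDCT false-positive
probability 0.180 (<65 band 25% below the ≥65 band), surgery-given-false-
positive 0.008, detection costs EUR 179 (screening) and EUR 14 (standard
care year 1 = 10% attendance × EUR 140 check-up), discount 3% — and use
values a health-economic modeller would call realistic everywhere else:

- stratum weights: older-skewed, 70% male (registry-inspired);
- stage distributions: screening (0.60, 0.12, 0.14, 0.14) versus standard
  care (0.17, 0.08, 0.25, 0.50), i.e. a strong stage shift;
- 3-month progression probabilities 0.22 / 0.33 / 0.45 for undiagnosed
  I→II / II→III / III→IV (sojourn times of a few months to a year);
- lung-cancer mortality: year-1 annual probabilities 0.07 / 0.22 / 0.50 /
  0.85 by stage, declining 30% per year since diagnosis, modified by sex
  (±5%) and age band (−10% / +15%); a flat 2%/year from year 6;
- other-cause mortality: stepwise 5-year bands from 1.0%/year (men 55–59)
  to 43%/year (95–99), women at 62% of male rates, certain death at 100;
- utilities: no-LC 0.84/0.80/0.75 (men) and 0.81/0.77/0.72 (women) by age
  band; stage-I utility 0.70 with ratios 0.95/0.87/0.75; disutilities
  0.0010 (screening) and 0.0080 (false positive) QALYs;
- diagnosis + treatment one-off costs 23,000 / 19,000 / 28,000 / 34,000 EUR
  for stages I–IV (stage IV highest, III second, I above II).

These defaults are labelled synthetic in emitted parameter files and make no
claim of equalling the unpublished source values; consequently the
stochastic headline numbers (credible intervals, CEAC values) are not
expected to replicate the originally reported ones, while the structural and
printed-arithmetic quantities (EUR 165 incremental first-year detection
cost, 14 false-positive surgeries per 10,000, the stage-shift direction of
every scenario) are reproduced exactly.  The random-parameter generator
draws from wide-but-plausible ranges while preserving the orderings the
comparative statics rely on (mortality non-decreasing and utility
non-increasing in stage, utilities non-increasing in age).

### What the synthetic data do and do not emulate

The generator emulates the *structure* of the decision problem — prevalence
and false-positive age profiles, a screening stage shift, tunnel-state
survival, asbestos-level background mortality — under independence
assumptions (sex × age weights factorise; prevalence is sex-independent;
PSA parameters are independent).  It does not emulate registry-level
correlation between parameters, secular trends in treatment, incidental
findings, repeat screening, or heterogeneity within strata.  Passing tests
therefore demonstrate the correctness of the machinery (conservation,
calibration, accounting, uncertainty propagation) and the direction of the
model's mechanisms, not the magnitude of benefit in any real population.

## Numerical choices

- Sum-to-one tolerances 10⁻⁹ (validation); weighted-prevalence consistency
  10⁻⁶; cohort extinction threshold 10⁻¹² alive mass; calibration sub-chain
  truncated when undiagnosed mass < 10⁻¹⁴.
- Annual↔cycle probability conversion by the constant-rate identity
  1 − (1 − p)^(1/n); parameter files may declare `scale: annual` per block.
- Degenerate inputs: a calibration target with no diagnosable mass is
  flagged (distribution collapses to stage IV) rather than raised; ICERs
  with zero incremental effect carry an `undefined` label; dominance is
  labelled instead of returning signed ratios.
- Reproducibility: every stochastic component takes an explicit seed; PSA
  draw i uses `default_rng([seed, i])`, so iterations are independent of
  execution order and results are bitwise reproducible.

## Problem sizes used in the automated analyses

The shipped test-and-analysis runs use 12 strata × 2 arms over ≤171 cycles;
PSA with 2000 iterations; calibration round-trip checks over 50 random
parameter sets; conservation checks over 100 random parameter sets; and a
10⁶-individual microsimulation cross-check of the cohort engine (3-standard-
error agreement on life years, QALYs and lung-cancer deaths).

## Known limitations

- One screening round only; no incidental findings; healthcare-sector
  perspective only; no equity analysis (all inherited from the modelled
  decision problem).
- A single diagnosis-probability set is calibrated for the whole population
  (pooled mode); stratum-specific stage-at-diagnosis distributions are only
  approximately matched.
- Utilities and mortality beyond year 5 since diagnosis are stage- and
  age-invariant by design (explored in the cure-after-year-5 scenario).
- The age decline applied to lung-cancer utilities is an assumption (no
  mechanism is reported for it); it is capped at the no-LC utility
  so it can only be conservative about the benefit of screening.
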