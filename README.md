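# lcs-cea

Cost-effectiveness model of a **single round of low-dose-CT (LDCT) lung
cancer screening versus passive surveillance** in a population aged 55–80
with past occupational asbestos exposure and ≥10 pack-years of smoking.

The package is aimed at health-economic modellers: it provides a decision
tree connected to a 3-month-cycle Markov cohort model with
years-since-diagnosis tunnel states, calibration of diagnosis
probabilities, probabilistic sensitivity analysis (PSA) and scenario
analyses, all driven by a single validated parameter configuration.

## The model in brief

Each sex × age stratum is split at baseline by a decision tree: with
screen-detectable prevalence *p*, the screening arm starts with *p* in
diagnosed stages I–IV (screening stage distribution) and the standard-care
arm starts with the same *p* in *undiagnosed* stages with the same
distribution — the benefit of screening then arises purely from the **stage
shift**: undiagnosed cancers progress (I→II→III→IV) before being diagnosed,
and later stages carry higher mortality, lower utility and different
one-off diagnosis/treatment costs.

The Markov engine evolves the cohort to extinction (death forced at age
100), applying per cycle, in order: other-cause death, lung-cancer death
(stage × year-since-diagnosis × sex × age band, via 21 tunnel slots),
diagnosis, progression.  Life years and QALYs are half-cycle corrected
(trapezoidal) and discounted at 3%/year at cycle midpoints.  Incremental
results per screening participant feed the usual estimands

- ΔC / ΔE: incremental cost per QALY gained (the primary ICER), per life
  year saved and per lung-cancer death averted, judged against a
  willingness-to-pay threshold of EUR 25,000/QALY;
- CEAC(λ) = P(λ·ΔQALY − ΔC ≥ 0) over λ ∈ [0, 60,000];
- overdiagnosis (screen-detected cancers whose counterfactual owner dies of
  other causes before clinical diagnosis) and surgeries in false positives.

The stage I–III diagnosis probabilities are **calibrated** (damped
fixed-point iteration) so the simulated standard-care stage distribution at
diagnosis matches observation.  The PSA samples Beta/Gamma/Dirichlet
distributions around the base case and re-calibrates each iteration.

Because the original registry-derived parameter tables are unpublished, the
package ships a **synthetic default parameterisation** that reproduces the
published aggregates by construction (overall screen-detectable prevalence
0.0253, mean LDCT false-positive probability 18.0%, detection costs EUR
179 vs EUR 14, surgery-in-false-positive probability 0.8%) and documented
plausible values elsewhere — see `docs/methods.md`.

## Worked example

```bash
lcs-cea synth --out params.yaml              # synthetic default parameters
lcs-cea calibrate --params params.yaml --out calibrated.yaml
lcs-cea run --params calibrated.yaml --out out/
```

which prints

```
wrote params.yaml
converged=True iterations=19 max_abs_dev=7.07e-05
ICER per QALY: 7845 EUR
wrote out/subgroups.csv and out/per_10k.csv
```

and `out/per_10k.csv` contains

```
outcome                  per_10000_screened
life_years_saved                        449
qalys_gained                            235
lc_deaths_averted                        62
incremental_total_cost              1842633
overdiagnosed_cancers                    17
fp_surgeries                             14
```

Reading: calibration matched the standard-care stage-at-diagnosis
distribution to within 7×10⁻⁵ per stage; under the synthetic defaults, one
screening round in 10,000 participants averts 62 lung-cancer deaths and
gains 235 QALYs for an extra EUR 1.84M, i.e. EUR 7,845 per QALY —
cost-effective against the EUR 25,000 threshold.  17 of the screen-detected
cancers would never have surfaced clinically and 14 false-positive benign
nodules would be operated on.

The same pipeline is available as a library:

```python
from lcs_cea import make_default_paramset, calibrate_paramset, run_deterministic, run_psa

params, record = calibrate_paramset(make_default_paramset())
det = run_deterministic(params, recalibrate=False)
print(float(det.pooled.icer_per_qaly))      # 7845.49...
psa = run_psa(params, n_iter=2000, seed=1)
print(psa.ceac_at(25_000))                  # probability cost-effective
```

`lcs-cea psa` and `lcs-cea scenarios` run the probabilistic analysis and
the seven scenario analyses (reduced prevalence, unfavourable stage
distribution, lower lung-cancer utilities, cure after year 5, higher
administrative costs, lower LDCT false-positive probability, alternative
stage II–IV treatment costs); `lcs-cea report` runs everything and writes
summary, subgroup, per-10k, scenario, CE-plane and CEAC CSVs.

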