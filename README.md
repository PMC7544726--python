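# radpoc

**Assigned share (probability of causation) of radiation for diagnosed
cancers, with full Monte Carlo uncertainty propagation.**

When a person with a history of radiation exposure is diagnosed with
cancer — typically in the context of an occupational compensation claim —
the scientific question is: *what is the probability that this cancer was
caused by that exposure?*  `radpoc` computes this **assigned share**

```
Z = h / (λ₀ + h)
```

where `λ₀` is the baseline incidence rate of the disease in the matching
unexposed target population and `h` is the radiation-attributed excess
rate inferred from radio-epidemiological risk models.  The package is a
library for radiation epidemiologists, dosimetrists and compensation-case
analysts, with a thin CLI on top.

## What it implements

- **Generic ERR/EAR risk models** `ERR or EAR = p(ρ|d,s) · r(ρ|s,a,e)`
  with linear, linear-quadratic, quadratic, power, quadratic-exponential
  and two-slope spline dose responses; log-linear baselines
  `λ₀ = f(β|s,a,b) · g`; full-covariance multivariate-normal parameter
  sampling.
- **Risk transfer** between the study cohort and the target population as
  a random additive/multiplicative mixture `h = h_m (1 − f + f·B)` with
  `f ~ U(0,1)` and per-exposure baseline ratios `B_i` evaluated at the
  cohort-equivalent calendar year (1945 + time since exposure); a
  log-uniform(1/3, 3) generic transfer for models without a usable
  cohort baseline.
- **Multi-model inference**: Akaike weights
  `w_i = e^{−ΔAIC_i/2} / Σ e^{−ΔAIC_k/2}`, hierarchical 50/50 weight
  trees, and stratified or random allocation of Monte Carlo realisations.
- **Risk adjustments**: an asymmetric S-shaped latency factor
  `F_L = [1 + exp(−η ln(t/t₀))]⁻¹`; a dose-rate effectiveness factor
  (DREF), lognormal with GM = 1 and
  `GSD(dr) = max(1.0, 1.1803 − 0.2317·log₁₀ dr)` below 6 mGy/h; cohort
  dosimetry (lognormal, GSD 1.1) and neutron-weighting (triangular
  5/10/30) factors; time-since-exposure caps (53 y solid, clamp [5, 56] y
  hematopoietic).
- **Multiple exposures** via `Z = [(1−f)Σh_m,i + fΣh_m,i B_i] /
  [λ₀ + …]`, with the max-of-twins rule for non-linear leukaemia models
  and a conservative max-ERR rule for lung-type model groups.
- **Poisson regression** of grouped cohort person-year tables by deviance
  minimisation, with AIC, likelihood-ratio tests, Wald p-values,
  significance pruning (dose coefficients protected) and city/in-city
  cohort-factor averaging.
- **Synthetic data**: population incidence tables, cohort cells from a
  known true model, a smoking-prevalence table, and an illustrative
  example model set built from published headline constants.

## Worked example

```python
import numpy as np
import radpoc as rp

model_set  = rp.example_model_set()
population = rp.generate_population_table(np.random.default_rng(42))

case = rp.CaseSpec(
    cancer_group="DIG", sex="m", birth_year=1950, diagnosis_year=2010,
    exposures=[rp.ExposureEvent(1980, {"type": "fixed", "value": 500.0})],
)
dist = rp.run_case(case, model_set, population,
                   rp.RunConfig(iterations=5000), seed=1)
print(dist.median, dist.mean, dist.summary["ci95"])
```

prints (examples/01_single_case_assigned_share.py):

```
median Z : 0.152
mean Z   : 0.294
68% CI   : [0.097, 0.702]
95% CI   : [0.058, 0.796]
model use: {'DIG-ERR': 3550, 'DIG-EAR': 1450}
```

A 500 mSv exposure thirty years before a digestive-tract cancer diagnosis
yields a median assigned share of about 15%: the cancer is more likely
spontaneous than radiation-induced, but the 95% interval is wide because
transfer-weight, model-choice, parameter and baseline uncertainties all
propagate into Z.  The median is the decision-relevant statistic: above
0.5, causation by radiation is more likely than not.

More narrative scripts live in `examples/` (multi-model inference,
cohort-table fitting, adjustment factors).

## Command line

```
radpoc compute --case case.json --models models.yaml --population pop.csv \
               --iterations 5000 --seed 1 --report out.json
radpoc fit --cells cells.csv --spec spec.yaml --out fitted.yaml
radpoc simulate --what population --out pop.csv --seed 3
```

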