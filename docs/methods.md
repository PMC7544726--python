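# Methods

This note documents the statistical model implemented by `radpoc`, the
conventions and numerical choices the implementation commits to, and what
the synthetic-data based test suite does and does not demonstrate.

## The assigned share

For a diagnosed primary malignancy the assigned share is
`Z = h / (λ₀ + h)`, where `λ₀` is the baseline incidence rate (per
person-year) of the disease in the unexposed target population matched on
sex, attained age and calendar year, and `h` is the excess rate
attributable to the exposure history.  For positive `h`, `Z ∈ (0, 1)`;
sampled negative excess (possible under Gaussian parameter uncertainty of
non-significant risk coefficients) is retained through the per-exposure
sums and `Z` is floored at 0 only at the end, preserving the correlation
structure of the draws.  A per-exposure clipping mode is available as a
config switch.

`Z` is always computed from `h` and `λ₀` directly rather than through the
ERR/(1+ERR) shortcut, because risk transfer (below) mixes baselines from
two populations and the model type (ERR vs EAR) is deliberately decoupled
from the transfer type.

## Risk models

Excess terms factorise as `ERR or EAR = p(d) · r(s, a, e)`:

- `p(d)`: linear `βd`, linear-quadratic `βd + αd²`, quadratic `αd²`,
  power `βd^γ` (γ > 0), quadratic-exponential `αd²e^{δd}`, or a
  continuous two-slope spline with a configurable knot (default 0.7 Gy,
  the dose where the myeloid-leukaemia response steepens).  `p(0) = 0`
  for every form.
- `r`: sex as `exp(σs)` with `s = −1` (male) / `+1` (female) (a `1 + σs`
  convention is selectable per model), attained age as `(a/70)^φ`, age at
  exposure as `exp(ψ(e − 30)/10)` (per decade), smoking intensity `x`
  (cigarettes/day, lung models) as `exp(θ₁x/10 + θ₂(x/10)²)`.  Centring
  constants are configurable; all modifiers off gives `r ≡ 1`.

Baselines are log-linear in sex, `ln(a/70)` and birth-year decades,
multiplied by a pre-averaged city/in-city cohort factor `g` (meaningless
outside the study cohort) and, where configured, a calendar-period
screening factor.  ERR is dimensionless; EAR is stored per 10⁴
person-years (the published convention) and converted internally.  Doses
are Gy internally; user input in mSv is divided by 1000 (model
coefficients are per Gy, and input equivalent doses are assumed already
weighted for radiation quality).

Parameter uncertainty is propagated by drawing the whole parameter vector
from a multivariate normal centred at the fit with the full covariance.
Covariances whose smallest eigenvalue is negative but within
`−10⁻¹⁰·trace` (round-tripped matrices) are clipped to PSD; anything
worse is rejected as a configuration error.

## Adjustments

- **Latency**: `F_L(t) = [1 + exp(−η ln(t/t₀))]⁻¹`, exactly 0 at `t = 0`
  and ½ at `t = t₀`.  Per iteration, `t₀ ~ U(3, 4)` y with `η = 6.25`
  for solid cancers and `t₀ ~ U(1.25, 1.75)` y with `η = 7.66` for
  hematopoietic malignancies; in practice only the first ~6 (solid) or
  ~2 (hematopoietic) years since exposure are affected.
- **DREF**: lognormal multiplier, geometric mean 1, with
  `GSD(dr) = max(1.0, 1.1803 − 0.2317·log₁₀ dr)` for dose rates below
  6 mGy/h and exactly 1.0 above.  One percentile `u ~ U(0,1)` is drawn
  per iteration and shared by all exposures; each exposure maps it
  through its own `GSD(dr)` with `dr` = sampled dose (mGy) / duration
  (h).  The excess is divided by the DREF draw, so the median risk is
  untouched while the bounds widen as the dose rate falls.  Without a
  duration the dose rate is unknown and the DREF is fixed at 1; radon
  exposures never receive a DREF.
- **Cohort factors** (study-cohort models only): a lognormal dosimetry
  factor (GM 1, GSD 1.1) divides the excess; a triangular(5, 10, 30)
  neutron weighting factor acts through a configurable linear sensitivity
  (default 0, i.e. inert, because the organ-specific response curves are
  external to this package).
- **Extrapolation caps**: time since exposure is capped at 53 y (solid)
  or clamped to [5, 56] y (hematopoietic) before evaluating the model —
  ages entering the excess are shifted consistently (`a_eff = e + t_eff`)
  — while the latency factor always uses the raw time.

## Transfer to the target population

`h = h_m (1 − f + fB)` mixes additive (`f = 0`) and multiplicative
(`f = 1`) transfer; `f ~ U(0, 1)` (maximum entropy) with a fixed
`f = 0.5` best-estimate mode, one draw per iteration shared by all
exposures.  The per-exposure baseline ratio is
`B_i = λ₀(target, diagnosis year) / λ₀m(cohort, year 1945 + t_i)` at the
same sex and attained age.  Models without a usable cohort baseline
(pooled breast, smoking-adjusted lung) use a generic
`ln B ~ U(ln ⅓, ln 3)` draw, one per iteration shared across exposures
(the ratio is a population-level quantity, sampled like `f`).

## Monte Carlo protocol

Default 5000 iterations (hard cap 50,000), all randomness from one seed.
Each iteration: select a model by MMI weight; draw parameters, latency,
`f`, the DREF percentile, the target baseline (Poisson-resampled case
count over person-years, mean floored at 0.5 cases so empty registry
cells cannot pin `Z`), cohort factors, and per-exposure doses (normal
draws truncated at 0 by rejection); evaluate the multi-exposure `Z`.
Dose draws are exposure-specific; every other sample is iteration-level
and shared — including by the linear twin when the max-of-twins rule
fires, which makes the twin comparison a common-random-numbers contrast.

Model allocation: flat AIC-weighted sets use exact largest-remainder
stratification (weights 0.6/0.4 at N = 10,000 give exactly 6000/4000);
hierarchical trees draw a branch at random per iteration by its fixed
weight (e.g. 50/50 sex-specific vs joint) and schedule leaves within the
branch by a largest-deficit rule.  Fully random selection is available as
a config mode.

The max-ERR rule for lung-type groups takes the pointwise maximum of ERR
across the group's models within the iteration and applies the selected
model's baseline; the group validator requires all members to be
ERR-type, which makes this equivalent to taking the maximum `Z`.

Summaries report the mean, median, a percentile table (linear
interpolation between order statistics) and the 16–84% / 2.5–97.5%
intervals.  Diagnosis years beyond the population table's coverage fall
back to its last year, mirroring registry lag.

## Fitting

Grouped cohort cells `(s, a, e, d, c, IC, n, PY)` are fitted by
minimising the Poisson deviance
`dev = 2Σ_{n>0}[n ln(n/μ) − (n − μ)] + 2Σ_{n=0} μ` with `μ = λ·PY`.
Numerics: BFGS (gradient tolerance 10⁻⁶) followed by a Nelder–Mead
polish (absolute tolerances 10⁻¹⁰), three jittered starts by default,
non-finite deviance mapped to a large finite penalty; the covariance is
`2·H⁻¹` of the deviance Hessian (central differences, relative step
10⁻⁴), i.e. the observed-information convention.  AIC = dev + 2·(number
of parameters).  Backward pruning removes the least significant modifier
by likelihood-ratio test while the dose-response coefficients and the
baseline intercept are protected even when their interval includes zero
— their uncertainty then flows into `Z` through the covariance.  Fitted
city/in-city factors are collapsed to a case- or person-year-weighted
average `g` for use outside the cohort.

Cells carry no birth year, so the fitter absorbs any birth-year trend
into the intercept; the baseline's birth-year coefficient is an
engine-side concept only.

## Synthetic data and what the tests show

The generators produce: registry-style population tables (5-year age
groups, Poisson cases on a log-linear age surface, person-years tapering
above age 60); cohort cells over a 0–4 Gy dose grid for both sexes and
all city strata with Poisson counts from a known true model; a
plausible-magnitude smoking prevalence table; and an example model set
assembled from published headline constants for eight grouped
solid-cancer sites plus a synthetic quadratic/linear twin pair.  The
example set's covariances are diagonal (back-computed from printed Wald
p-values, with "<0.001" read as 0.001), its AICs are reconstructed from
printed group weights via `AIC = −2 ln w`, and its baselines are
synthetic stand-ins — it exercises every code path with realistic
magnitudes but does not reproduce any cohort's fitted parameter sets,
and computed `Z` values for real cases should come from user-supplied
fitted configs.

Consequently the tests demonstrate internal correctness — closed-form
equivalence of the frozen engine, exact fractionation algebra, DREF
median invariance, near-nominal Wald coverage on simulated cells
(200 replicates of a 64-cell, ~2·10⁵ PY/cell design), correct selection
frequencies — not agreement with any cohort reanalysis.  Real cohort
data, real registry rates and the supplement-level model formulas of any
specific national implementation are outside scope.

## Known limitations

- Neutron-weighting uncertainty is sampled faithfully but inert by
  default; organ-specific response curves must be supplied.
- Smoking-radiation interaction is structural (configurable intensity
  modifier + max-ERR rule); no published lung-model coefficients ship.
- The hematopoietic clamp can evaluate models slightly above the attained
  age (`a_eff = e + 5` when `t < 5`), the documented price of holding the
  early-time risk at its 5-year value.
- Percentile interpolation, the 0.5-case Poisson floor and the per-decade
  modifier scalings are conventions; all are config-visible and
  documented above.
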