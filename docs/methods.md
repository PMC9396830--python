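# Methods

## Model structure

The simulation is an annual-step, individual-level model of an open
adult population. Each simulated person carries demographics (age,
sex, education), exposures (BMI, occupation group), chronic
back-problem status, an ordinal pain level 0–4 (defined only for
cases), intervention state (exercising, ergonomically protected), and
a constant survey weight mapping the sample to the represented
population. A year advances in a fixed order:

1. **demography** — mortality, emigration, aging, entries;
2. **onset** — back-problem incidence among non-cases;
3. **interventions** — BMI reduction, ergonomic protection top-up,
   exercise participation top-up;
4. **pain transitions** — one proportional-odds draw per case;
5. **census** — YLDs and exposure summaries for the year.

The order is a modelling convention, fixed for reproducibility;
interventions precede the pain draw so a year's intervention affects
that year's pain. Pain is updated annually because the pain model
conditions on the previous year's observed level; no continuous-time
event queue is used.

### Demography

Mortality follows a Gompertz preset `q(a) = min(1, α e^{0.095 a})` with
the sex-specific level α solved by bisection so period life expectancy
is 80 (male) / 84 (female) years. Entry and exit flows are calibrated:
target (year, sex, age) totals are built by projecting the baseline
forward with mortality and adding entrants so the total population
grows 0.4%/year (entrants: 60% aging in at 20, the rest immigrating at
21–49, split evenly by sex). The calibration solves each target cell
directly — a shortfall against the survivors becomes an entry count, an
excess an emigration probability — so the deterministic
cohort-component projection reproduces the targets exactly and the
procedure is idempotent. The 0.4%/year default reproduces the order of
growth implied by a burden rising from ~425k to ~460k YLDs over 20
years at roughly stable prevalence; the baseline age structure
(32.8% aged 60+) then ages into a 2040 structure near 40% aged 60+.
Entrant covariates are drawn from the baseline margins with age and sex
forced to the entry cell; entrant disease state is sampled from the
same conditional models as the baseline. No fertility, households or
geography are modelled.

### Disease layer

Chronic back problems are absorbing ("life-long duration").
Prevalence is logistic in centred age (−50 y), male sex, centred BMI
(−26 kg/m²) and college education. The BMI slope is `ln(1.14)/5` per
unit (published odds ratio 1.14 per 5 units); the remaining slopes are
presets (0.015/y age, −0.10 male, −0.20 college — prevalence rises with
age, is higher in women and at lower socio-economic status), and the
intercept is solved by Brent's method so the population-average
prevalence over a deterministic covariate quadrature equals the 20.7%
target. Incidence is backed out by the cohort recursion
`i(a) = (p(a+1) − p(a)) / (1 − p(a))` (floored at 0 with a warning if
the curve decreases), with `p(a)` averaged over BMI/education at each
age and sex; this assumes no differential mortality by case status.

Pain among cases follows an autoregressive proportional-odds model:
`P(level ≥ k) = expit(η − c_k)` with η containing age (0.008/y), sex
(−0.10 male), education (−0.15 college), BMI (`ln(1.14)/5` per unit),
occupational offsets `ln(RR)` (GBD ergonomic-exposure relative risks:
1.17, 1.08, 1.00 (reference), 1.37, 1.53, 3.78, 2.37 for groups 1–7;
no exposure outside the labour force) and previous-pain offsets
(0.5, 1.0, 1.5, 2.0 for previous levels 1–4). The previous-pain
offsets, linear in level, encode moderate year-to-year persistence
(odds ratio e^0.5 ≈ 1.65 per previous level); the longitudinal survey
coefficients behind the original model are unpublished, so this is a
package preset. New cases always enter with pain: the initial level is
drawn from the proportional-odds probabilities with level 0 removed.

### Calibration of the pain cutpoints

The cutpoints are tuned by damped fixed-point iteration (damping 0.6,
tolerance 0.1 percentage points per share, budget 200 iterations) so
the simulated census pain mix among cases matches the target mix
57.7/10.3/11.6/11.4/9.0%. Because the case pool is not closed — every
year ~3% of it consists of newly diagnosed cases who enter in pain —
the calibration targets the *turnover-adjusted* long-run distribution:
for each covariate profile the census mix solves
`π = (1−f) Tᵀ π + f ν`, with T the profile's 5×5 annual transition
matrix, ν its onset distribution, and `f = h(1−p)/p` its personal
inflow rate (onset hazard h, prevalence p). Profiles are a fixed
6,000-draw covariate sample weighted by case probability; the 5-state
systems are solved exactly (batched linear solves with one equation
replaced by the normalisation). The baseline roster and entrants
sample case pain from the same turnover-adjusted distributions, so the
simulated cross section starts on target rather than jumping in the
first year.

### Interventions

* **BMI reduction** (levels 0.1–5 units/year): everyone with BMI ≥ 25
  at the start of a year loses `level` units, floored at 18.5;
  eligibility is re-checked annually. The effect propagates through
  both the prevalence/onset and the pain linear predictors, since BMI
  appears in both.
* **Ergonomic** (coverage 0–100%, or whole occupational groups): a
  once-drawn, persistent random subset of workers has its occupational
  offset set to the clerical reference (0). Annual re-application tops
  the protected share up so later entrants are covered at the same
  rate; membership is never revoked.
* **Exercise** (coverage 0–100% of eligible patients: cases, age < 80,
  pain < 4): participants persist while eligible, drop out when not,
  and the pool is topped up each year to the target coverage. The
  effect is either an `ln(0.71)` offset to the pain linear predictor
  (RR mode) or, in VAS mode, a deterministic 0.4-level decrement on a
  continuous latent pain scale. The latent scale maps the logistic
  latent variable piecewise-linearly through the cutpoints (c_k ↦
  k − 0.5, end slopes extrapolated); rounding reproduces the ordinal
  discretisation exactly, and 10 points on a 0–100 VAS correspond to
  0.4 levels on the 0–4 scale.

Interventions run 2021–2040 with no ramp-up and do not alter
demography: person-years per scenario equal the base case exactly at a
common seed.

### Burden and analysis

Annual YLDs sum survey-weight × disability-weight over active cases,
using the GBD LBP severity weights 0.020/0.054/0.272/0.372 for levels
1–4 (level 1, "pain preventing no activities", is given the mild
weight by default; configurable to 0). YLDs averted are base-case
minus scenario, per year and cumulated 2021–2040.

Scenario results are smoothed by ordinary least squares (statsmodels):
averted YLDs against coverage for ergonomic and exercise families,
against `ln(level)` for BMI (the natural-log convention follows the
published "0.1 log-BMI unit ≈ 9.5% BMI change"). Per-unit effects use
the slope's t-based 95% CI. Equivalence levels invert the fitted line,
`(target − intercept)/slope`, exponentiated for the log form, with
delta-method CIs from the coefficient covariance. The CIs reflect
regression residual variance only, not replicate-to-replicate
Monte-Carlo variance.

## Randomness and reproducibility

One RNG stream per stage (population, demography, onset, pain,
interventions), spawned from the master seed via `SeedSequence`, so
scenario runs at a common seed share demographic and onset histories
with the base case (common random numbers). Runs are byte-identical
at a fixed configuration.

## What the synthetic generator does and does not emulate

The generator reproduces the *marginal* distributions of the published
2020 population (age bands, sex, education, BMI mean, occupation,
prevalence, pain mix) with independent covariates; correlations enter
only through the disease models conditioned on covariates. Real survey
data have a joint covariate structure (e.g. BMI–education–occupation
dependence), design effects, and non-constant survey weights that are
not emulated, and the occupation shares, BMI standard deviation (4.5),
and education split are presets, since only partial values are
published. Passing tests therefore demonstrate internal consistency
and correct mechanics under the stated margins — not fidelity to the
confidential microdata. Absolute national YLD trajectories agree with
the published ones only to the extent the margins determine them (the
static 2020 reconstruction is within a few percent); quantities that
depend on the unpublished fitted coefficients — notably the maximal
exercise effect, where the simulated ~23% of total YLDs averted falls
below the published 29.6% — are sensitive to the preset previous-pain
offsets and to entering the exercise relative risk 0.71 as a
cumulative-odds offset, which is conservative for an outcome as common
as pain (42% among cases).

## Numerical choices and degenerate inputs

Within-band ages are uniform; the open 80+ band tapers geometrically
(ratio 0.82/year) over 80–100. BMI is log-normal (mean 25.9, SD 4.5),
keeping it positive and right-skewed. Probability-vector sums are
enforced to 1e-12; cutpoints must be strictly increasing; share
vectors to 1e-9. Degenerate inputs are first-class: zero-prevalence
and all-level-0 bundles produce exactly zero YLDs, single-row rosters
summarise to point-mass margins, and infeasible calibration targets
raise errors naming the offending cell.

## Default problem sizes

Simulation-based checks use 100,000 individuals (matching the original
survey-sample scale) for dose–response and maximal-effect runs, and
20,000–50,000 for property tests; the full 39-scenario catalog at
n = 100,000 takes a few minutes on one CPU.

## Known limitations

No costs, no years of life lost/DALYs, no discounting; no pain model
for people without diagnosed back problems; exercise and ergonomic
effects are exchangeable across age and sex; incidence calibration
ignores differential mortality; entrant covariate distributions are
stationary over calendar time.
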