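# Methods

## The model

`tsce` implements the two-stage clonal expansion (TSCE) model of
carcinogenesis for lung cancer incidence under individual, time-varying
smoking exposure.  A pool of `X` normal stem cells acquires a first
(initiating) alteration at rate `mu0` per cell-year, so initiated clones are
founded at total rate `nu(t) = X * mu0(t)`.  Each initiated cell divides at
rate `alpha`, dies at rate `beta`, and acquires the malignant alteration at
rate `mu1` per cell-year; the appearance of the first malignant cell is
identified with cancer occurrence (an optional fixed diagnostic lag, default
0 years, shifts the observed age scale).  The net clonal growth, or
promotion, rate is `g = alpha - beta - mu1`, and `beta` is always derived
from `(alpha, g, mu1)` — it is never a free parameter.  Ages are in years
and all rates are per year.

Smoking enters through a multiplicative dose–response on any background
rate `theta`:

    theta_tobacco(d) = theta * (1 + theta_c * d ** theta_p)

with `d` the current cigarettes-per-day.  In the selected model smoking
acts on promotion (`g_c`, `g_p`) and malignant conversion (`mu1_c`,
`mu1_p`); an initiation effect (`mu0_c`) is supported but off by default,
matching the model-selection outcome that it does not improve fit.

### Exact solution under piecewise-constant rates

Let `Gamma(u; t)` be the probability that a clone founded at age `u`
produces no malignant cell by age `t`.  It satisfies the backward Riccati
equation

    dGamma/du = (alpha + beta + mu1) Gamma - alpha Gamma^2 - beta,
    Gamma(t; t) = 1,

and survival and hazard of the filtered process are

    S(t) = exp( -∫_0^t nu(u) (1 - Gamma(u; t)) du ),
    h(t) =      ∫_0^t nu(u) B(u; t) du,

with `B = -dGamma/dt` obeying a linear backward equation with terminal
value `mu1`.  On an interval with constant rates the Riccati factors
through the roots `y± = (A ± c) / 2 alpha`, `A = alpha + beta + mu1`,
`c = sqrt(A² - 4 alpha beta)`; the Möbius coordinate
`w = (Gamma - y+) / (Gamma - y-)` propagates as a pure exponential, and
`S`, `h` and `Gamma` all have closed forms per interval that are chained
backward across breakpoints.  No quadrature is involved; the solution is
exact up to floating point.

Numerical choices:

- The recursion runs in transformed variables — `Gamma - 1`, `log|1 - w|`,
  `log B`, and a log-accumulated hazard integral — because `y+ - 1` is of
  order `mu1 / g` (~1e-5 here) and `exp(c Δt)` can overflow on long
  intervals.  `y+ - 1` is computed by the cancellation-free identity
  `2 mu1 / (c + alpha - beta - mu1)`.
- When a rate jump leaves `Gamma` below the new interval's lower root
  (`w > 1`, which happens whenever dose drops backward in `u`, i.e. at a
  smoking-start breakpoint), the branch is tracked through the sign of
  `Gamma - y-`; both branches use the same closed forms on absolute values.
- Intervals with `mu1 = 0` and `beta >= alpha` inside an otherwise
  non-trivial schedule are rejected (they cannot arise from the model,
  where `beta = alpha - g_eff - mu1_eff < alpha`); schedules with
  `mu1 ≡ 0` or `nu ≡ 0` short-circuit to `S = 1, h = 0`.
- `ode_oracle` integrates the defining equations directly with LSODA at
  rtol 1e-11 and is used only for verification; the suite demands 1e-6
  relative agreement on randomized schedules, and a Gillespie simulation of
  the branching process (`tsce.branching`) independently reproduces
  `1 - S(t)` on fast toy rates.

## Likelihood

Each individual contributes a left-truncated term conditional on being
cancer-free at entry age `ae`: cases `log f(al) - log S(ae)` and non-cases
`log S(al) - log S(ae)`, with `al` the exit age; deaths and administrative
end of follow-up are non-case exits.  Entry conditioning is on being free
of lung cancer at `ae` only (no other-cause survival conditioning).  The
cohort log-likelihood is the sum over individuals; internally the cohort is
compiled into padded per-interval arrays so one likelihood evaluation is a
few vectorised sweeps (~milliseconds for 50,000 individuals), with the
hazard term evaluated only on case rows.

## Exposure histories

Questionnaire records carry age started, cigarettes per day (numeric or the
categories ≤6, 6–10, 11–20, 21–30, ≥31), age quit, assessment ages, and
optional relapse/dose-change episodes.  Bounded categories map to interval
means (8, 15.5, 25.5); the open-ended categories map to 3.5 and 40 by
convention (configurable).  Dose changes take effect at the age they are
reported (no interpolation).  Follow-up is censored `w` years after the
last smoking assessment (default `w = 10`; 5, 15, 30 used in sensitivity
sweeps); a case diagnosed beyond the censoring age becomes a non-case at
the truncated exit.  Records too incomplete to reconstruct raise an
exclusion signal rather than an error, mirroring cohort exclusions.

## Fitting, model selection, uncertainty

Four parameters are free in the reference configuration — `mu0 (= mu1)`,
`g`, `g_c`, `mu1_c` — each shareable across race/gender groups (shared, by
race, by gender, or group-specific).  Fixed: `X = 1e7`, `alpha = 3`,
`g_p = 0.4013`, `mu1_p = 0.4684` (both powers overridable).  The `mu0 =
mu1` tie reflects that the two are not separately identified from incidence
alone.  Optimisation is quasi-Newton (L-BFGS-B) on log-parameters with box
bounds and multistart (first start at canonical magnitudes or a supplied
point, the rest jittered ±50%); convergence is by gradient norm / relative
log-likelihood change.  Nested models are compared by LRT (chi-square, df =
difference in free-parameter count; negative statistics beyond a slack of
`1e-6 * |loglik|` flag a failed optimisation) and non-nested ones by AIC
with ties broken toward fewer parameters.

Interval estimates use random-walk Metropolis–Hastings on log-parameters
with a flat prior on the log-domain, so the target is the likelihood
surface; the isotropic Gaussian proposal scale is adapted toward ~30%
acceptance during burn-in (default 20% of steps) and then frozen.
Reported intervals are equal-tailed 95% percentile intervals of the
post-burn-in draws.  These are posterior percentile intervals under the
flat prior — the only coherent reading of MH-derived "confidence
intervals" — and Hessian-based standard errors are deliberately not the
primary uncertainty summary.

## Synthetic cohorts

The generator emulates the structure of the multiethnic cohort sample the
model was developed for, which is access-restricted: two race blocks (n =
33,067 and 48,519 by default), gender split 63.8% / 53.9% female, entry
ages truncated-normal on [45, 76] with the underlying location solved so
the truncated mean equals the published 61.8 / 59.5 (SD 9.08),
never/former/current mixes (39.0/38.1/22.8% and 39.3/43.9/16.7%), maximum
follow-up 24.7 years, assessments at entry and (with participation
probabilities 0.6 and 0.5) at entry+10 and entry+15, then the 10-year
post-assessment censoring rule.  Distributions the source tables do not
print are fixture conventions, not estimates: initiation age
truncated-normal(17.5, 4) on [10, 35]; CPD-category probabilities (0.15,
0.30, 0.35, 0.12, 0.08); former smokers quit uniformly between initiation+1
and entry.  Event ages are drawn exactly from each individual's TSCE model
conditional on no event by entry, by inverting `S(t)/S(ae) = U` with 50
vectorised bisection steps.

Not emulated (hence not demonstrated by passing tests): other-cause
mortality (administrative truncation stands in), dependence between
smoking behaviour and entry age or questionnaire participation, dose
changes after baseline, and real questionnaire timing variability.
Recovery experiments therefore show identifiability of the model from data
of this size and shape, not robustness to those real-world features.

## Reporting

Observed incidence uses 5-year age bins anchored at 45, person-years as
each individual's overlap with the bin, events assigned to the exit-age
bin, rates per 100,000 person-years, and exact (chi-square) Poisson
confidence intervals.  Scenario curves evaluate the model hazard on an age
grid (default 1–100 by 1 year) for never smokers, constant-CPD smokers
from a start age, and quitters; relative risks are pointwise hazard ratios
within a group and cross-group ratios are labelled hazard ratios.
Posterior bands are pointwise 2.5/97.5 percentiles across chain draws.

## Problem sizes used in validation

Chosen to keep the default suite and the reproduction script to desk
scale:

- Parameter recovery (suite and `scripts/acceptance.py`): n = 50,000 per
  single-group cohort, 5 seeds, medians reported; backgrounds recover
  within 15%, tobacco coefficients within 20%.
- MCMC coverage: 20 replicates at n = 6,000 with 3,000-step chains.
  Shorter/smaller configurations under-mix and under-cover; this size
  mixes adequately while staying a few minutes of runtime.
- Null-effect LRT calibration: 8 replicates at n = 4,000.
- Solver oracle: 100 random schedules; branching-process check: 1e5 runs.

## Known limitations

- Single lag-free diagnosis (lag configurable but defaulting to 0); no
  tumour-size or sojourn-time modelling, and no more than two stages.
- `mu0 = mu1` is assumed in fitting; the core solver accepts untied values
  but the fitting surface does not expose them.
- Cross-parameter proposal correlation is not modelled in the MH sampler;
  heavily correlated posteriors mix slowly and need longer chains.
- Pack-years are descriptive only; the model consumes CPD trajectories.
- The race/gender groups are those of the source analysis (non-Hispanic
  Black and non-Hispanic White, male and female); nothing in the code
  generalises biology across other groups.
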