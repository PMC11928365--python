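# tsce-lung

Two-stage clonal expansion (TSCE) modelling of lung cancer incidence under
individual, time-varying smoking histories.

Lung cancer incidence differs sharply by race/ethnicity and gender in ways
that crude smoking summaries do not explain: non-Hispanic Black (NHB) men
smoke fewer cigarettes per day than non-Hispanic White (NHW) men yet have
higher incidence.  Mechanistic multistage models can separate
smoking-related from background (non-smoking) carcinogenesis.  This package
provides the full analysis stack for that kind of study: an exact solver for
the TSCE hazard and survival under piecewise-constant exposure, a
left-truncated cohort likelihood, maximum-likelihood fitting with
group-structured parameters, likelihood-ratio / AIC model selection,
Metropolis–Hastings interval estimation, and a synthetic-cohort generator
emulating a large multiethnic cohort (the real data are access-restricted).

It is aimed at cancer epidemiologists and simulation modellers who want to
fit or extend multistage carcinogenesis models on cohort data with
reconstructed smoking histories.

## The model

Normal stem cells (`X = 1e7`) are **initiated** at rate `μ0` per cell-year;
initiated cells undergo a stochastic clonal expansion with division rate
`α = 3`, death rate `β`, and **malignant conversion** rate `μ1`; the first
malignant cell marks cancer.  The net **promotion** rate is
`g = α − β − μ1` (β is derived, never free).  Smoking dose `d` (cigarettes
per day) scales any background rate θ as

    θ_tobacco(d) = θ · (1 + θ_c · d^θ_p)

applied to promotion and malignant conversion (an initiation effect is
supported but deselected).  With piecewise-constant rates the survival
`S(t)` and hazard `h(t)` have closed forms obtained by factoring the
backward Riccati equation for the clone non-extinction probability
`Γ(u;t)` per interval and chaining across breakpoints; a numerical ODE
oracle and a direct branching-process simulation verify the solver in the
test suite.  Each individual contributes the left-truncated likelihood term
`f(al)/S(ae)` (cases) or `S(al)/S(ae)` (non-cases) for entry age `ae` and
exit age `al`.  See `docs/methods.md` for the details.

## Worked example

Generate a 10,000-person NHB-male synthetic cohort under the reference
fitted parameters, re-fit the four free parameters, and predict risk:

```python
from tsce.synthetic import single_group_config, generate_cohort
from tsce.validation import single_group_spec
from tsce.inference import fit_mle
from tsce.reporting import Scenario, predicted_hazard_curve, relative_risk_curve

cfg = single_group_config("NHB", "male", 10_000, seed=42)
cohort = generate_cohort(cfg)
print(f"cohort: {len(cohort)} individuals, {cohort.n_cases} lung cancer cases")

fit = fit_mle(cohort, single_group_spec(), seed=42, n_starts=2)
for name, value in fit.estimates.items():
    print(f"  {name:12s} = {value:.4g}")
print(f"loglik = {fit.loglik:.1f}   AIC = {fit.aic:.1f}")

params = fit.params_by_group()[("NHB", "male")]
never  = predicted_hazard_curve(params, Scenario.never(),   ages=[70.0])
smoker = predicted_hazard_curve(params, Scenario.smoker(20), ages=[70.0])
rr = relative_risk_curve(params, Scenario.smoker(20), Scenario.never(), ages=[70.0])
print(f"hazard at 70, never smoker : {never['hazard'][0]:6.1f} per 100,000/yr")
print(f"hazard at 70, 20 CPD from 20: {smoker['hazard'][0]:6.1f} per 100,000/yr")
print(f"relative risk at 70         : {rr['ratio'][0]:.1f}")
```

Output:

```
cohort: 10000 individuals, 829 lung cancer cases
  mu0[all]     = 3.414e-07
  g[all]       = 0.05035
  g_c[all]     = 0.3152
  mu1_c[all]   = 0.3833
loglik = -4404.1   AIC = 8816.1
hazard at 70, never smoker :   75.4 per 100,000/yr
hazard at 70, 20 CPD from 20: 1920.0 per 100,000/yr
relative risk at 70         : 25.5
```

The recovered estimates sit near the generating values (μ0 = 4.058e-7,
g = 0.0454, g_c = 0.3306, μ1_c = 0.4160) — at n = 10,000 the backgrounds
are within sampling error and the tobacco coefficients are the noisier
ones.  The never-smoker hazard at 70 (~75 per 100,000 person-years) and
the ~25-fold relative risk of a lifelong pack-a-day smoker are in the
range typical of cohort analyses of this kind.

A `tsce` command-line tool wraps the same stages
(`simulate | fit | select | mcmc | predict | report`) around a YAML config;
`tsce --config cfg.yaml --seed 1 --out out/ report` runs the whole
pipeline.

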