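"""Maximum-likelihood fitting with group-structured parameters, LRT and AIC.

A :class:`ModelSpec` says which TSCE parameters are free and how each is
shared across the four race/gender groups (shared, by race, by gender, or
fully group-specific), which values are fixed (stem-cell count, division
rate, the two dose-response powers by default), and whether smoking is
allowed to act on initiation.  Fitting maximises the left-truncated cohort
log-likelihood over log-transformed parameters with a quasi-Newton
(L-BFGS-B) optimiser and multistart jittering; nested specifications are
compared with likelihood-ratio tests and non-nested ones by AIC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .likelihood import Cohort, cohort_loglik
from .params import BiologicalParameters, GENDERS, RACES

__all__ = ["ModelSpec", "FitResult", "fit_mle", "lrt", "select_model"]

SHARINGS = ("shared", "by_race", "by_gender", "by_race_gender")
FREE_PARAMS = ("mu0", "g", "g_c", "mu1_c")

#: default log-scale starting magnitudes and box bounds per parameter kind
_DEFAULT_START = {"mu0": 2e-7, "g": 0.05, "g_c": 0.3, "mu1_c": 0.3, "mu0_c": 0.1}
_BOUNDS = {"mu0": (1e-10, 1e-4), "g": (1e-4, 0.8),
           "g_c": (1e-5, 20.0), "mu1_c": (1e-5, 20.0), "mu0_c": (1e-6, 20.0)}

# refinement partial order on sharing patterns
_REFINES = {"shared": {"shared"},
            "by_race": {"shared", "by_race"},
            "by_gender": {"shared", "by_gender"},
            "by_race_gender": set(SHARINGS)}


@dataclass(frozen=True)
class ModelSpec:
    """Free parameters, their group-sharing pattern, and fixed values."""

    sharing: Mapping[str, str] = field(
        default_factory=lambda: {p: "by_race_gender" for p in FREE_PARAMS})
    X: float = 1.0e7
    alpha: float = 3.0
    g_p: float = 0.4013
    mu1_p: float = 0.4684
    initiation_effect: bool = False
    mu0_p: float = 0.4013
    tie_mu0_mu1: bool = True
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sharing", dict(self.sharing))
        missing = [p for p in FREE_PARAMS if p not in self.sharing]
        if missing:
            raise ValueError(f"sharing pattern missing for {missing}")
        for p, s in self.sharing.items():
            if s not in SHARINGS:
                raise ValueError(f"unknown sharing pattern {s!r} for {p}")
        if self.X <= 0 or self.alpha <= 0 or self.g_p < 0 or self.mu1_p < 0:
            raise ValueError("fixed values must be positive")
        if not self.tie_mu0_mu1:
            raise NotImplementedError(
                "untied mu0/mu1 fitting is not exposed; the core model "
                "supports it but the cohort analysis constrains mu0 == mu1")

    def free_params(self) -> Tuple[str, ...]:
        extra = ("mu0_c",) if self.initiation_effect else ()
        return FREE_PARAMS + extra

    def _levels(self, param: str) -> List[str]:
        s = self.sharing.get(param, "shared")
        if s == "shared":
            return ["all"]
        if s == "by_race":
            return list(RACES)
        if s == "by_gender":
            return list(GENDERS)
        return [f"{r}:{g}" for r in RACES for g in GENDERS]

    def param_names(self) -> List[str]:
        return [f"{p}[{lvl}]" for p in self.free_params()
                for lvl in self._levels(p)]

    @property
    def k(self) -> int:
        return len(self.param_names())

    def _value_for(self, estimates: Mapping[str, float], param: str,
                   race: str, gender: str) -> float:
        s = self.sharing.get(param, "shared")
        lvl = {"shared": "all", "by_race": race, "by_gender": gender,
               "by_race_gender": f"{race}:{gender}"}[s]
        return estimates[f"{param}[{lvl}]"]

    def build_params(self, estimates: Mapping[str, float]
                     ) -> Dict[Tuple[str, str], BiologicalParameters]:
        """Per-group parameter sets from a named-estimate mapping."""
        out = {}
        for race in RACES:
            for gender in GENDERS:
                kw = {p: self._value_for(estimates, p, race, gender)
                      for p in self.free_params()}
                out[(race, gender)] = BiologicalParameters(
                    mu0=kw["mu0"], g=kw["g"], g_c=kw["g_c"], mu1_c=kw["mu1_c"],
                    mu0_c=kw.get("mu0_c", 0.0), g_p=self.g_p,
                    mu1_p=self.mu1_p, mu0_p=self.mu0_p,
                    X=self.X, alpha=self.alpha)
        return out

    def is_nested_in(self, other: "ModelSpec") -> bool:
        """True if this spec is a restriction of ``other``."""
        if (self.X, self.alpha, self.g_p, self.mu1_p) != \
                (other.X, other.alpha, other.g_p, other.mu1_p):
            return False
        if self.initiation_effect and not other.initiation_effect:
            return False
        return all(self.sharing[p] in _REFINES[other.sharing[p]]
                   for p in FREE_PARAMS)


@dataclass
class FitResult:
    """MLE output: named estimates, log-likelihood, AIC, diagnostics."""

    spec: ModelSpec
    estimates: Dict[str, float]
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    n_starts: int
    seed: int
    message: str = ""

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    def params_by_group(self) -> Dict[Tuple[str, str], BiologicalParameters]:
        return self.spec.build_params(self.estimates)

    def to_json(self) -> str:
        return json.dumps({
            "estimates": self.estimates, "loglik": self.loglik,
            "aic": self.aic, "k": self.k, "converged": self.converged,
            "n_iter": self.n_iter, "grad_norm": self.grad_norm,
            "seed": self.seed, "message": self.message,
            "spec": {"sharing": dict(self.spec.sharing),
                     "initiation_effect": self.spec.initiation_effect,
                     "fixed": {"X": self.spec.X, "alpha": self.spec.alpha,
                               "g_p": self.spec.g_p, "mu1_p": self.spec.mu1_p}},
        }, indent=2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": list(self.estimates),
                             "estimate": list(self.estimates.values())})


def _objective(cohort: Cohort, spec: ModelSpec, names: Sequence[str]):
    groups = cohort.groups()

    def negloglik(x: np.ndarray) -> float:
        est = dict(zip(names, np.exp(x)))
        try:
            by_group = spec.build_params(est)
            return -cohort_loglik(cohort, {g: by_group[g] for g in groups})
        except (ValueError, FloatingPointError):
            return 1e12
    return negloglik


def fit_mle(cohort: Cohort, spec: ModelSpec,
            start: Optional[Mapping[str, float]] = None,
            seed: int = 0, n_starts: int = 5,
            gtol: float = 1e-6, ftol: float = 1e-11,
            max_iter: int = 500) -> FitResult:
    """Maximise the cohort likelihood under ``spec``.

    Quasi-Newton (L-BFGS-B) on log-transformed parameters with box bounds;
    ``n_starts`` starts (the first at ``start`` or canonical magnitudes, the
    rest jittered by up to ±50% on the natural scale), best optimum wins.
    Deterministic given ``seed``.
    """
    names = spec.param_names()
    kinds = [n.split("[")[0] for n in names]
    base = np.log([(start or {}).get(n, _DEFAULT_START[k])
                   for n, k in zip(names, kinds)])
    lb = np.log([_BOUNDS[k][0] for k in kinds])
    ub = np.log([_BOUNDS[k][1] for k in kinds])
    rng = np.random.default_rng(seed)
    negloglik = _objective(cohort, spec, names)

    best = None
    n_iter_total = 0
    for s in range(n_starts):
        x0 = base if s == 0 else base + rng.uniform(np.log(0.5), np.log(1.5),
                                                    size=base.size)
        x0 = np.clip(x0, lb, ub)
        res = minimize(negloglik, x0, method="L-BFGS-B",
                       bounds=list(zip(lb, ub)),
                       options={"maxiter": max_iter, "ftol": ftol,
                                "gtol": gtol})
        n_iter_total += res.nit
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        return FitResult(spec=spec, estimates={}, loglik=-np.inf,
                         converged=False, n_iter=n_iter_total,
                         grad_norm=np.nan, n_starts=n_starts, seed=seed,
                         message="all starts failed")
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
    return FitResult(
        spec=spec,
        estimates=dict(zip(names, np.exp(best.x))),
        loglik=-float(best.fun),
        converged=bool(best.success or grad_norm < 1e-2),
        n_iter=n_iter_total,
        grad_norm=grad_norm,
        n_starts=n_starts,
        seed=seed,
        message=str(best.message),
    )


def lrt(nested: FitResult, full: FitResult) -> Tuple[float, int, float]:
    """Likelihood-ratio test of a nested against a fuller model.

    Returns ``(statistic, df, p)`` with the statistic
    ``2 * (loglik_full - loglik_nested)`` and a chi-square upper-tail p-value.
    """
    if not nested.spec.is_nested_in(full.spec):
        raise ValueError("specs are not nested")
    df = full.k - nested.k
    stat = 2.0 * (full.loglik - nested.loglik)
    # negative values beyond optimizer convergence slack (relative to the
    # loglik magnitude) indicate the full model's optimisation failed
    if stat < -1e-6 * max(1.0, abs(full.loglik)):
        raise ValueError(
            f"negative LRT statistic ({stat:.3g}): the full model fit "
            "failed to reach its optimum")
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 and stat == 0.0 else float(chi2.sf(stat, max(df, 1)))
    return stat, df, p


def select_model(cohort: Cohort, specs: Sequence[ModelSpec],
                 seed: int = 0, n_starts: int = 3,
                 **fit_kw) -> pd.DataFrame:
    """Fit all candidate specs and rank them by AIC (ties: fewer parameters).

    Returns a DataFrame with one row per candidate (best first) carrying the
    fit, AIC, and the LRT against the top-ranked model where nested.
    """
    if not specs:
        raise ValueError("no candidate specifications")
    fits = [fit_mle(cohort, sp, seed=seed, n_starts=n_starts, **fit_kw)
            for sp in specs]
    order = sorted(range(len(fits)),
                   key=lambda i: (fits[i].aic, fits[i].k))
    best_fit = fits[order[0]]
    rows = []
    for rank, i in enumerate(order):
        f = fits[i]
        row = {"name": f.spec.name or f"model_{i}", "k": f.k,
               "loglik": f.loglik, "aic": f.aic,
               "delta_aic": f.aic - best_fit.aic,
               "converged": f.converged, "fit": f,
               "lrt_stat": np.nan, "lrt_df": np.nan, "lrt_p": np.nan}
        if rank > 0 and f.spec.is_nested_in(best_fit.spec):
            stat, df, p = lrt(f, best_fit)
            row.update(lrt_stat=stat, lrt_df=df, lrt_p=p)
        rows.append(row)
    return pd.DataFrame(rows)
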