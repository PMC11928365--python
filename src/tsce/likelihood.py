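"""Left-truncated cohort likelihood for the TSCE incidence model.

Each individual contributes, conditional on being lung-cancer-free at study
entry age ``ae``:

    case:     log f(al) - log S(ae) = log h(al) + log S(al) - log S(ae)
    non-case: log S(al) - log S(ae)

where ``al`` is exit age and ``S``, ``h``, ``f`` come from the individual's
dose-specific rate schedule.  The cohort log-likelihood is the sum over
individuals.  Deaths and administrative end of follow-up are both non-case
exits.

For fitting speed the cohort is compiled once into padded per-interval
arrays (dose breakpoints are few per person) so that a full cohort
log-likelihood is a handful of vectorised backward-recursion sweeps; the
expensive hazard term is evaluated only on case rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np

from .core import piecewise_survival_hazard
from .exposure import DoseHistory, SmokingRecord
from .params import BiologicalParameters

__all__ = ["Individual", "Cohort", "individual_loglik", "cohort_loglik"]

Group = Tuple[str, str]  # (race_ethnicity, gender)
ParamsLike = Union[BiologicalParameters, Mapping[Group, BiologicalParameters]]


@dataclass
class Individual:
    """One cohort member: the likelihood's unit of data."""

    id: str
    race: str
    gender: str
    entry_age: float
    exit_age: float
    is_case: bool
    dose_history: DoseHistory = field(default_factory=DoseHistory)
    record: Optional[SmokingRecord] = None

    def __post_init__(self):
        if not 0 < self.entry_age <= self.exit_age:
            raise ValueError(f"individual {self.id}: need 0 < entry <= exit age")
        if not 45.0 <= self.entry_age < 90.0:
            raise ValueError(f"individual {self.id}: entry age outside [45, 90)")

    @property
    def group(self) -> Group:
        return (self.race, self.gender)


class Cohort:
    """A list of individuals plus metadata, with a compiled array cache."""

    def __init__(self, individuals: List[Individual], metadata: Optional[dict] = None):
        if not individuals:
            raise ValueError("cohort is empty")
        ids = [ind.id for ind in individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("individual ids are not unique")
        self.individuals = list(individuals)
        self.metadata = dict(metadata or {})
        self._compiled: Dict[Group, "_GroupArrays"] = {}

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def groups(self) -> List[Group]:
        seen: List[Group] = []
        for ind in self.individuals:
            if ind.group not in seen:
                seen.append(ind.group)
        return seen

    def subset(self, group: Group) -> "Cohort":
        subs = [ind for ind in self.individuals if ind.group == group]
        return Cohort(subs, self.metadata)

    def compiled(self, group: Group) -> "_GroupArrays":
        if group not in self._compiled:
            members = [ind for ind in self.individuals if ind.group == group]
            if not members:
                raise KeyError(f"no individuals in group {group}")
            self._compiled[group] = _GroupArrays(members)
        return self._compiled[group]

    @property
    def n_cases(self) -> int:
        return sum(ind.is_case for ind in self.individuals)


class _GroupArrays:
    """Padded per-interval arrays for one group (internal)."""

    def __init__(self, members: List[Individual]):
        m = len(members)
        K = max(len(ind.dose_history.edges) for ind in members)
        self.edges = np.full((m, K), np.inf)
        self.dose = np.zeros((m, K))
        for i, ind in enumerate(members):
            e = ind.dose_history.edges
            d = ind.dose_history.doses
            k = len(e)
            self.edges[i, :k] = e
            self.dose[i, :k] = d
            self.dose[i, k:] = d[-1]  # padded intervals repeat last real rates
        self.ae = np.array([ind.entry_age for ind in members])
        self.al = np.array([ind.exit_age for ind in members])
        self.case = np.array([ind.is_case for ind in members], dtype=bool)
        self.ids = [ind.id for ind in members]
        self._powers: Dict[Tuple[float, float, float], tuple] = {}

    def dose_powers(self, g_p: float, mu1_p: float, mu0_p: float):
        key = (g_p, mu1_p, mu0_p)
        if key not in self._powers:
            pos = self.dose > 0
            safe = np.where(pos, self.dose, 1.0)
            self._powers[key] = tuple(np.where(pos, safe ** p, 0.0)
                                      for p in key)
        return self._powers[key]

    def loglik(self, params: BiologicalParameters,
               per_individual: bool = False):
        dpg, dpm, dp0 = self.dose_powers(params.g_p, params.mu1_p, params.mu0_p)
        g_eff = params.g * (1.0 + params.g_c * dpg)
        mu1_eff = params.mu1_value * (1.0 + params.mu1_c * dpm)
        nu = params.X * params.mu0 * (1.0 + params.mu0_c * dp0)
        beta = params.alpha - g_eff - mu1_eff
        if np.any(beta < 0):
            raise ValueError("beta < 0 at some dose; parameters invalid")
        alpha = np.full_like(beta, params.alpha)

        lag = params.lag
        ae = np.maximum(self.ae - lag, 0.0)
        al = np.maximum(self.al - lag, 0.0)
        nls_ae, _ = piecewise_survival_hazard(self.edges, nu, alpha, beta,
                                              mu1_eff, ae, need_hazard=False)
        nls_al, _ = piecewise_survival_hazard(self.edges, nu, alpha, beta,
                                              mu1_eff, al, need_hazard=False)
        ll = nls_ae - nls_al  # log S(al) - log S(ae)
        if np.any(self.case):
            c = self.case
            _, h = piecewise_survival_hazard(self.edges[c], nu[c], alpha[c],
                                             beta[c], mu1_eff[c], al[c])
            if np.any(h <= 0):
                raise ValueError("zero hazard at a case's exit age; "
                                 "likelihood is degenerate for these parameters")
            ll[c] += np.log(h)
        return ll if per_individual else float(ll.sum())


def _params_for(params: ParamsLike, group: Group) -> BiologicalParameters:
    if isinstance(params, BiologicalParameters):
        return params
    try:
        return params[group]
    except KeyError:
        raise KeyError(f"no parameter set supplied for group {group}") from None


def individual_loglik(ind: Individual, params: BiologicalParameters) -> float:
    """Log-likelihood contribution of a single individual."""
    arrays = _GroupArrays([ind])
    return float(arrays.loglik(params, per_individual=True)[0])


def cohort_loglik(cohort: Cohort, params: ParamsLike,
                  by_group: bool = False):
    """Total cohort log-likelihood.

    Parameters
    ----------
    cohort : Cohort
    params : BiologicalParameters or mapping ``(race, gender) -> parameters``
    by_group : bool
        If True, return a dict of per-group sums instead of the total.
    """
    parts = {g: cohort.compiled(g).loglik(_params_for(params, g))
             for g in cohort.groups()}
    return parts if by_group else float(sum(parts.values()))
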