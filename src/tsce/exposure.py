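"""Smoking-history reconstruction and dose application.

Questionnaire records (age started, cigarettes per day — often categorical —
age quit, assessment ages) are turned into piecewise-constant dose
trajectories in cigarettes per day, which the dose-response equation maps
onto the TSCE process rates.  Follow-up is censored a configurable number of
years after the last smoking assessment to limit exposure misclassification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .core import RateSchedule, schedule_from_params
from .params import BiologicalParameters, apply_dose_response

__all__ = [
    "SmokingRecord", "DoseHistory", "IncompleteRecordError",
    "cpd_from_category", "build_dose_history", "apply_dose_response",
    "censor_after_last_assessment", "build_rate_schedule",
    "CPD_CATEGORY_MEANS",
]


class IncompleteRecordError(ValueError):
    """Smoking record lacks fields required to reconstruct a dose history.

    Individuals raising this are excluded from analysis rather than crashing
    cohort construction.
    """


#: Questionnaire cigarettes-per-day categories mapped to interval means.
#: The two open-ended categories have no defined mean; their values are
#: configurable conventions.
CPD_CATEGORY_MEANS = {
    "<=6": 3.5,
    "6-10": 8.0,
    "11-20": 15.5,
    "21-30": 25.5,
    ">=31": 40.0,
}

_CATEGORY_ALIASES = {
    "≤6": "<=6", "<= 6": "<=6", "le6": "<=6",
    "6–10": "6-10", "11–20": "11-20", "21–30": "21-30",
    "≥31": ">=31", ">= 31": ">=31", "ge31": ">=31", "31+": ">=31",
}


def cpd_from_category(category: Union[str, float],
                      open_low: float = 3.5, open_high: float = 40.0) -> float:
    """Continuous cigarettes/day from a questionnaire category.

    Bounded categories map to the arithmetic mean of their integer range
    ("11-20" -> 15.5); the open-ended "<=6" and ">=31" map to ``open_low``
    and ``open_high``.  A numeric input is returned unchanged.
    """
    if isinstance(category, (int, float)) and not isinstance(category, bool):
        if category < 0:
            raise ValueError("cigarettes per day must be non-negative")
        return float(category)
    key = _CATEGORY_ALIASES.get(str(category).strip(), str(category).strip())
    if key not in CPD_CATEGORY_MEANS:
        raise ValueError(f"unknown cigarettes-per-day category: {category!r}")
    if key == "<=6":
        return open_low
    if key == ">=31":
        return open_high
    return CPD_CATEGORY_MEANS[key]


@dataclass(frozen=True)
class SmokingRecord:
    """Questionnaire-style smoking history for one individual.

    ``episodes`` optionally lists additional ``(age, cpd)`` change points —
    e.g. relapse or a dose change reported at a later assessment; each takes
    effect at the stated age (no interpolation between assessments).
    """

    status: str  # never | former | current | missing
    age_started: Optional[float] = None
    cpd: Optional[Union[str, float]] = None
    age_quit: Optional[float] = None
    assessment_ages: Tuple[float, ...] = ()
    episodes: Tuple[Tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.status not in ("never", "former", "current", "missing"):
            raise ValueError(f"unknown smoking status: {self.status!r}")
        if self.assessment_ages and np.any(np.diff(self.assessment_ages) <= 0):
            raise ValueError("assessment ages must be increasing")
        if (self.age_started is not None and self.age_quit is not None
                and not self.age_started < self.age_quit):
            raise ValueError("age_started must precede age_quit")


@dataclass(frozen=True)
class DoseHistory:
    """Piecewise-constant cigarettes/day versus age.

    Interval ``j`` is ``[edges[j], edges[j+1])`` (last open-ended);
    ``edges[0] == 0``.
    """

    edges: Tuple[float, ...] = (0.0,)
    doses: Tuple[float, ...] = (0.0,)

    def __post_init__(self):
        if len(self.edges) != len(self.doses) or not self.edges:
            raise ValueError("edges and doses must have equal, positive length")
        if self.edges[0] != 0.0:
            raise ValueError("dose history must start at age 0")
        if len(self.edges) > 1 and np.any(np.diff(self.edges) <= 0):
            raise ValueError("dose breakpoints must be strictly increasing")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")

    def dose_at(self, age):
        """Dose at given age(s)."""
        idx = np.searchsorted(self.edges, np.asarray(age, float), side="right") - 1
        return np.asarray(self.doses)[np.clip(idx, 0, len(self.doses) - 1)]

    @property
    def is_never(self) -> bool:
        return all(d == 0 for d in self.doses)


def build_dose_history(record: SmokingRecord,
                       open_low: float = 3.5, open_high: float = 40.0) -> DoseHistory:
    """Reconstruct the dose trajectory implied by a questionnaire record.

    Never smokers get an identically-zero history; current smokers smoke
    ``cpd`` from ``age_started`` onward; former smokers on
    ``[age_started, age_quit)``.  ``episodes`` append further change points.

    Raises
    ------
    IncompleteRecordError
        If required fields are missing ("missing" status, a smoker without
        start age or amount, a former smoker without quit age) — the
        exclusion signal, mirroring cohort exclusions for unreconstructable
        histories.
    """
    if record.status == "missing":
        raise IncompleteRecordError("smoking status missing")
    if record.status == "never":
        base = [(0.0, 0.0)]
    else:
        if record.age_started is None or record.cpd is None:
            raise IncompleteRecordError("smoker without start age or amount")
        dose = cpd_from_category(record.cpd, open_low, open_high)
        base = [(0.0, 0.0), (float(record.age_started), dose)]
        if record.status == "former":
            if record.age_quit is None:
                raise IncompleteRecordError("former smoker without quit age")
            base.append((float(record.age_quit), 0.0))

    points = sorted(base + [(float(a), float(d)) for a, d in record.episodes])
    edges, doses = [], []
    for age, dose in points:
        if edges and age == edges[-1]:
            doses[-1] = dose
        else:
            edges.append(age)
            doses.append(dose)
    return DoseHistory(tuple(edges), tuple(doses))


def censor_after_last_assessment(exit_age: float,
                                 assessment_ages: Sequence[float],
                                 window_years: float = 10.0) -> float:
    """Exit age truncated to ``last assessment + window`` years.

    Never increases the exit age.  A case whose diagnosis falls beyond the
    censoring age becomes a non-case at the truncated exit; see
    :func:`censor_individual_exit`.
    """
    ages = list(assessment_ages)
    if not ages:
        raise ValueError("assessment age list is empty")
    if window_years <= 0:
        raise ValueError("censoring window must be positive")
    return min(float(exit_age), max(ages) + float(window_years))


def censor_individual_exit(exit_age: float, is_case: bool,
                           assessment_ages: Sequence[float],
                           window_years: float = 10.0) -> Tuple[float, bool]:
    """Apply assessment censoring to an (exit age, case flag) pair."""
    new_exit = censor_after_last_assessment(exit_age, assessment_ages, window_years)
    return new_exit, bool(is_case and exit_age <= new_exit)


def build_rate_schedule(params: BiologicalParameters,
                        dose: DoseHistory) -> RateSchedule:
    """TSCE rate schedule from biological parameters and a dose trajectory.

    Schedule breakpoints coincide with the dose breakpoints; per interval
    ``nu = X * mu0_eff``, ``g_eff`` and ``mu1_eff`` follow the dose-response,
    and ``beta = alpha - g_eff - mu1_eff`` (error if negative).
    """
    return schedule_from_params(params, np.asarray(dose.edges),
                                np.asarray(dose.doses))
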