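"""Biological parameters of the two-stage clonal expansion (TSCE) model.

The TSCE model describes carcinogenesis as initiation (normal stem cell ->
initiated cell, rate ``mu0`` per stem cell per year), clonal expansion of
initiated cells (division rate ``alpha``, death rate ``beta``, net promotion
``g = alpha - beta - mu1``), and malignant conversion (initiated -> malignant,
rate ``mu1`` per initiated cell per year).  The first malignant cell is
identified with cancer occurrence, optionally shifted by a fixed lag.

Smoking acts multiplicatively on a background rate ``theta`` through

    theta_tobacco = theta * (1 + theta_c * dose ** theta_p)

with ``dose`` in cigarettes per day.  In the reference analysis the tobacco
effect applies to promotion and malignant conversion only; an optional
initiation effect is supported for model-selection experiments.

All ages are in years and all rates are per year.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "BiologicalParameters",
    "RACES",
    "GENDERS",
    "GROUPS",
    "REFERENCE_PARAMS",
    "apply_dose_response",
]

RACES = ("NHB", "NHW")
GENDERS = ("male", "female")
GROUPS = tuple((r, s) for r in RACES for s in GENDERS)


def apply_dose_response(theta: float, theta_c: float, theta_p: float, dose):
    """Multiplicative tobacco dose-response: ``theta * (1 + theta_c * dose**theta_p)``.

    ``dose`` is cigarettes per day and may be a scalar or array.  A dose of
    zero returns ``theta`` exactly.

    Raises
    ------
    ValueError
        If ``dose`` (any element), ``theta`` or ``theta_c`` is negative.
    """
    import numpy as np

    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    if theta < 0 or theta_c < 0:
        raise ValueError("theta and theta_c must be non-negative")
    out = theta * (1.0 + theta_c * np.where(d > 0, d, 1.0) ** theta_p * (d > 0))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BiologicalParameters:
    """TSCE rate constants and tobacco coefficients for one population group.

    Parameters
    ----------
    mu0 : float
        Background initiation rate per stem cell per year.
    g : float
        Background net promotion rate (per year), ``g = alpha - beta - mu1``.
    mu1 : float, optional
        Background malignant conversion rate per initiated cell per year.
        ``None`` (default) ties ``mu1 = mu0``, the constraint used in the
        reference cohort analysis.
    g_c, g_p : float
        Tobacco promotion coefficient and power (dimensionless).
    mu1_c, mu1_p : float
        Tobacco malignant-conversion coefficient and power.
    mu0_c, mu0_p : float
        Tobacco initiation coefficient and power; 0 disables the effect
        (the selected reference model has no initiation effect).
    X : float
        Number of susceptible stem cells (fixed at 1e7).
    alpha : float
        Initiated-cell division rate per year (fixed at 3).
    lag : float
        Fixed delay (years) between first malignant cell and diagnosis.

    The cell death rate is derived, never free:
    ``beta(dose) = alpha - g_eff(dose) - mu1_eff(dose)`` and must stay
    non-negative at every dose used.
    """

    mu0: float
    g: float
    mu1: Optional[float] = None
    g_c: float = 0.0
    g_p: float = 0.4013
    mu1_c: float = 0.0
    mu1_p: float = 0.4684
    mu0_c: float = 0.0
    mu0_p: float = 0.4013
    X: float = 1.0e7
    alpha: float = 3.0
    lag: float = 0.0

    def __post_init__(self) -> None:
        if self.X <= 0 or self.alpha <= 0:
            raise ValueError("X and alpha must be positive")
        for name in ("mu0", "g", "g_c", "g_p", "mu1_c", "mu1_p", "mu0_c", "mu0_p", "lag"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mu1 is not None and self.mu1 < 0:
            raise ValueError("mu1 must be non-negative")
        self.beta_at_dose(0.0)  # raises if beta < 0 at zero dose

    @property
    def mu1_value(self) -> float:
        """Effective background malignant-conversion rate (``mu0`` when tied)."""
        return self.mu0 if self.mu1 is None else self.mu1

    @property
    def mu0_eq_mu1(self) -> bool:
        return self.mu1 is None

    def g_at_dose(self, dose):
        return apply_dose_response(self.g, self.g_c, self.g_p, dose)

    def mu1_at_dose(self, dose):
        return apply_dose_response(self.mu1_value, self.mu1_c, self.mu1_p, dose)

    def mu0_at_dose(self, dose):
        return apply_dose_response(self.mu0, self.mu0_c, self.mu0_p, dose)

    def nu_at_dose(self, dose):
        """Total initiation rate ``nu = X * mu0_eff`` (initiated cells per year)."""
        import numpy as np

        return np.asarray(self.X * self.mu0_at_dose(dose))

    def beta_at_dose(self, dose):
        """Derived death rate ``beta = alpha - g_eff - mu1_eff``; raises if negative."""
        import numpy as np

        beta = self.alpha - np.asarray(self.g_at_dose(dose)) - np.asarray(self.mu1_at_dose(dose))
        if np.any(beta < 0):
            raise ValueError(
                "derived death rate beta = alpha - g_eff - mu1_eff is negative "
                "at the requested dose; parameters are outside the valid domain"
            )
        return beta if beta.ndim else float(beta)

    def with_updates(self, **kwargs) -> "BiologicalParameters":
        return replace(self, **kwargs)


#: Fitted parameter sets from a multiethnic cohort analysis of lung cancer
#: incidence, by (race/ethnicity, gender).  Used as simulation defaults and
#: as generating truth in parameter-recovery experiments.
REFERENCE_PARAMS = {
    ("NHB", "male"): BiologicalParameters(mu0=4.058e-7, g=0.0454, g_c=0.3306, mu1_c=0.4160),
    ("NHB", "female"): BiologicalParameters(mu0=5.282e-7, g=0.0299, g_c=0.5646, mu1_c=0.2871),
    ("NHW", "male"): BiologicalParameters(mu0=8.836e-8, g=0.0803, g_c=0.2623, mu1_c=0.2691),
    ("NHW", "female"): BiologicalParameters(mu0=1.758e-7, g=0.0626, g_c=0.2837, mu1_c=0.2565),
}
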