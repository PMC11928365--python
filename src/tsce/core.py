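"""Exact survival and hazard of the two-stage clonal expansion process.

The process: ``X`` stem cells are initiated at total rate ``nu(u) = X*mu0(u)``;
each initiated cell founds a birth-death-mutation clone with division rate
``alpha``, death rate ``beta(u)`` and malignant-conversion rate ``mu1(u)``;
cancer occurs at the first malignant cell.  All rates are piecewise constant
on an age grid (left-closed, right-open intervals).

Let ``Gamma(u; t)`` be the probability that the clone founded by a single
initiated cell at age ``u`` produces no malignant cell by age ``t``.  It obeys
the backward Riccati equation

    dGamma/du = (alpha + beta + mu1) * Gamma - alpha * Gamma**2 - beta,
    Gamma(t; t) = 1,

so that survival (probability of no cancer by ``t``) and hazard are

    S(t) = exp( - int_0^t nu(u) * (1 - Gamma(u; t)) du ),
    h(t) =       int_0^t nu(u) * B(u; t) du,

where ``B = -dGamma/dt`` satisfies the linear backward equation
``dB/du = ((alpha+beta+mu1) - 2*alpha*Gamma) * B`` with ``B(t;t) = mu1``.

With constant rates on an interval the Riccati factors through the roots
``y± = ((A ± c) / (2*alpha))`` of ``alpha*y^2 - A*y + beta`` where
``A = alpha + beta + mu1`` and ``c = sqrt(A^2 - 4*alpha*beta)``; the Möbius
coordinate ``w = (Gamma - y+) / (Gamma - y-)`` propagates exponentially,
``w(u) = w(b) * exp(c * (b - u))`` backward from the interval's right end
``b``, and every integral above has a closed form.  :func:`solve_tsce`
chains these closed forms across breakpoints; :func:`ode_oracle` integrates
the defining equations numerically and is used for verification only.

Numerical notes: the recursion is carried in transformed variables
(``Gamma - 1``, ``log(1 - w)``, ``log B``) so that near-critical parameters
(``mu1`` of order 1e-7) and long intervals (``c * dt`` large) lose no
precision and cannot overflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import BiologicalParameters

__all__ = ["RateSchedule", "HazardSurvival", "solve_tsce", "ode_oracle",
           "piecewise_survival_hazard"]

_LOG_TINY = -745.0  # log of the smallest positive double


@dataclass(frozen=True)
class HazardSurvival:
    """Survival ``S``, hazard ``h`` and density ``f = h*S`` at age ``t``."""

    t: float
    S: float
    h: float

    @property
    def f(self) -> float:
        return self.h * self.S


class RateSchedule:
    """Piecewise-constant TSCE process rates on an age grid.

    Parameters
    ----------
    edges : array-like
        Strictly increasing interval left endpoints starting at 0; interval
        ``j`` spans ``[edges[j], edges[j+1])`` and the last is open-ended.
    nu, alpha, beta, mu1 : array-like
        Per-interval rates (per year), same length as ``edges``; ``nu`` is
        the total initiation rate ``X * mu0``.
    """

    __slots__ = ("edges", "nu", "alpha", "beta", "mu1")

    def __init__(self, edges, nu, alpha, beta, mu1):
        edges = np.atleast_1d(np.asarray(edges, dtype=float))
        rates = [np.broadcast_to(np.asarray(r, dtype=float), edges.shape).copy()
                 for r in (nu, alpha, beta, mu1)]
        if edges[0] != 0.0:
            raise ValueError("schedule must start at age 0")
        if edges.size > 1 and np.any(np.diff(edges) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        for name, r in zip(("nu", "alpha", "beta", "mu1"), rates):
            if not np.all(np.isfinite(r)) or np.any(r < 0):
                raise ValueError(f"{name} must be finite and non-negative")
        self.edges = edges
        self.nu, self.alpha, self.beta, self.mu1 = rates

    def __len__(self) -> int:
        return self.edges.size

    def __repr__(self) -> str:
        return f"RateSchedule({self.edges.size} intervals, edges={self.edges!r})"

    def refine(self, extra_points: Sequence[float]) -> "RateSchedule":
        """Insert breakpoints without changing the rate function."""
        pts = np.asarray(extra_points, dtype=float)
        new_edges = np.unique(np.concatenate([self.edges, pts]))
        idx = np.searchsorted(self.edges, new_edges, side="right") - 1
        return RateSchedule(new_edges, self.nu[idx], self.alpha[idx],
                           self.beta[idx], self.mu1[idx])

    def to_json(self) -> str:
        return json.dumps({k: getattr(self, k).tolist()
                           for k in ("edges", "nu", "alpha", "beta", "mu1")})

    @classmethod
    def from_json(cls, s: str) -> "RateSchedule":
        d = json.loads(s)
        return cls(d["edges"], d["nu"], d["alpha"], d["beta"], d["mu1"])


def piecewise_survival_hazard(edges, nu, alpha, beta, mu1, t, need_hazard=True):
    """Vectorised exact TSCE survival/hazard for a batch of schedules.

    Parameters
    ----------
    edges : (m, K) array
        Interval left endpoints per row; ``edges[:, 0] == 0``; rows may be
        padded on the right with ``inf`` (padded intervals must repeat the
        last real rates).
    nu, alpha, beta, mu1 : (m, K) arrays
        Per-interval rates.
    t : (m,) array
        Evaluation age per row.
    need_hazard : bool
        If False, only ``-log S`` is computed (cheaper).

    Returns
    -------
    neg_log_S, hazard : (m,) arrays
        ``-log S(t)`` and ``h(t)`` (hazard is None if not requested).
    """
    edges = np.asarray(edges, float)
    t = np.asarray(t, float)
    m, K = edges.shape
    if np.any(t < 0):
        raise ValueError("evaluation age must be non-negative")

    lo = np.minimum(edges, t[:, None])
    hi = np.empty_like(lo)
    hi[:, :-1] = lo[:, 1:]
    hi[:, -1] = t
    dt = hi - lo  # >= 0; zero for intervals beyond t

    active = dt > 0
    nontrivial = np.any(active & (mu1 > 0), axis=1)
    bad = active & (mu1 == 0) & (beta >= alpha)
    if np.any(bad & nontrivial[:, None]):
        raise ValueError(
            "interval with mu1 == 0 and beta >= alpha inside a schedule with "
            "malignant conversion elsewhere is not supported"
        )

    neg_logS = np.zeros(m)
    hazard = np.zeros(m) if need_hazard else None

    if not np.any(nontrivial):
        return neg_logS, hazard

    # terminal condition B(t; t) = mu1 of the interval containing t-
    if need_hazard:
        idx = np.clip((edges < t[:, None]).sum(axis=1) - 1, 0, K - 1)
        with np.errstate(divide="ignore"):
            logB = np.log(mu1[np.arange(m), idx])
        log_Ih = np.full(m, -np.inf)  # log of accumulated integral

    Gm1 = np.zeros(m)  # Gamma - 1 at the current right end

    # The Möbius coordinate w = (Gamma - y+)/(Gamma - y-) is <= 0 while
    # Gamma > y- and > 1 when a rate jump leaves Gamma below the new
    # interval's lower root; both branches are carried via log|w|, log|1-w|
    # and the sign of (Gamma - y-).
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for k in range(K - 1, -1, -1):
            a = alpha[:, k]
            b = beta[:, k]
            u = mu1[:, k]
            d = dt[:, k]
            s1 = a - b + u
            c = np.sqrt(s1 * s1 + 4.0 * b * u)
            q = a - b - u
            den = c + q                      # = 2*alpha*(1 - y-)  (>= 0)
            safe_den = np.where(den > 0, den, 1.0)
            yp_m1 = np.where(den > 0, 2.0 * u / safe_den, 0.0)  # y+ - 1
            om_ym = den / (2.0 * a)                              # 1 - y-

            gap = om_ym + Gm1                     # Gamma - y-  (any sign)
            sign_pos = gap >= 0                   # w_b <= 0 branch
            log_gap = np.log(np.abs(np.where(gap != 0, gap, 1.0)))
            log_abs_wb = np.log(np.maximum(yp_m1 - Gm1, 0.0)) - log_gap
            L_b = np.log(om_ym + yp_m1) - log_gap  # log|1 - w_b|

            cd = c * d
            # log|1 - w_a| with w_a = w_b * exp(c*d)
            L_a = np.where(
                sign_pos,
                cd + np.logaddexp(-cd, log_abs_wb),
                cd + log_abs_wb + np.log1p(-np.exp(-cd - log_abs_wb)))

            neg_logS += nu[:, k] * np.where(d > 0,
                                            -yp_m1 * d + (L_a - L_b) / a, 0.0)

            if need_hazard:
                # int nu*B du = nu * B_b * (1-w_b) * expm1(c*d) / (c*(1-w_a));
                # the signs of (1-w_b) and (1-w_a) agree, so logs of absolute
                # values suffice.
                log_em1 = np.where(cd < 50.0,
                                   np.log(np.maximum(np.expm1(cd), 0.0)), cd)
                piece = (np.log(nu[:, k]) + logB + L_b + log_em1
                         - np.log(np.where(c > 0, c, 1.0)) - L_a)
                log_Ih = np.logaddexp(log_Ih,
                                      np.where(d > 0, piece, -np.inf))
                logB = logB + np.where(d > 0, cd + 2.0 * (L_b - L_a), 0.0)

            # Gamma update: Gm1 <- yp_m1 * r + om_ym * (r - 1),
            # r = 1/(1-w_a) carries the branch sign
            r = np.where(sign_pos, 1.0, -1.0) * np.exp(-L_a)
            Gm1 = np.where(d > 0, yp_m1 * r + om_ym * (r - 1.0), Gm1)

    neg_logS = np.where(nontrivial, neg_logS, 0.0)
    if need_hazard:
        hazard = np.where(nontrivial, np.exp(log_Ih), 0.0)
    out = neg_logS, hazard
    if not np.all(np.isfinite(neg_logS)) or (
            need_hazard and not np.all(np.isfinite(hazard))):
        raise FloatingPointError("non-finite survival/hazard; invalid schedule "
                                 "or parameters outside the supported domain")
    return out


def _schedule_batch(schedule: RateSchedule, t: np.ndarray):
    m = t.size
    K = len(schedule)
    tile = lambda x: np.broadcast_to(x, (m, K))
    return (tile(schedule.edges), tile(schedule.nu), tile(schedule.alpha),
            tile(schedule.beta), tile(schedule.mu1))


def solve_tsce(schedule: RateSchedule, t, lag: float = 0.0):
    """Exact S(t), h(t), f(t) of the filtered TSCE process.

    Parameters
    ----------
    schedule : RateSchedule
    t : float or array of ages (years)
    lag : float
        Fixed lag between first malignant cell and diagnosis; the observed
        quantities at age ``t`` are those of the process at ``t - lag``.

    Returns
    -------
    HazardSurvival (scalar ``t``) or tuple of arrays ``(S, h, f)``.
    """
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(tt < 0):
        raise ValueError("age must be non-negative")
    te = np.maximum(tt - lag, 0.0)
    neg_logS, h = piecewise_survival_hazard(*_schedule_batch(schedule, te), te)
    S = np.exp(-neg_logS)
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return HazardSurvival(t=float(t), S=float(S[0]), h=float(h[0]))
    return S, h, h * S


def conditional_log_survival(schedule: RateSchedule, t, t0, lag: float = 0.0):
    """``log S(t) - log S(t0)`` computed without forming S (stable for tiny risks)."""
    tt = np.atleast_1d(np.asarray(t, float))
    t0 = np.maximum(np.atleast_1d(np.asarray(t0, float)) - lag, 0.0)
    te = np.maximum(tt - lag, 0.0)
    n1, _ = piecewise_survival_hazard(*_schedule_batch(schedule, te), te,
                                      need_hazard=False)
    n0, _ = piecewise_survival_hazard(*_schedule_batch(schedule, t0), t0,
                                      need_hazard=False)
    return n0 - n1


def ode_oracle(schedule: RateSchedule, t, lag: float = 0.0,
               rtol: float = 1e-11) -> HazardSurvival:
    """S, h, f by direct numerical integration of the defining backward ODEs.

    Slow but independent of the closed-form path; intended for verification.
    Integrates, per interval from ``t`` down to 0, the coupled system for
    ``Gamma``, ``B`` and the two integrals defining ``-log S`` and ``h``.
    """
    t = float(t)
    if t < 0:
        raise ValueError("age must be non-negative")
    te = max(t - lag, 0.0)
    if te == 0.0 or not np.any((schedule.mu1 > 0) & (schedule.edges < te)):
        return HazardSurvival(t=t, S=1.0, h=0.0)

    edges = schedule.edges
    j = int(np.searchsorted(edges, te, side="right") - 1)
    y = np.array([1.0, schedule.mu1[j], 0.0, 0.0])  # Gamma, B, IS, IH
    hi = te
    for k in range(j, -1, -1):
        lo = edges[k]
        nu_k, a, b, u = (schedule.nu[k], schedule.alpha[k],
                         schedule.beta[k], schedule.mu1[k])
        A = a + b + u

        def rhs(_, y):
            G, B, _, _ = y
            return [A * G - a * G * G - b,
                    (A - 2.0 * a * G) * B,
                    nu_k * (1.0 - G),
                    nu_k * B]

        sol = solve_ivp(rhs, (hi, lo), y, method="LSODA",
                        rtol=rtol, atol=1e-18, dense_output=False)
        if not sol.success:
            raise RuntimeError(f"ODE oracle failed on [{lo}, {hi}]: {sol.message}")
        y = sol.y[:, -1]
        hi = lo
    neg_logS = -y[2]   # integral accumulated backward carries a minus sign
    h = -y[3]
    return HazardSurvival(t=t, S=float(np.exp(-neg_logS)), h=float(h))


def schedule_from_params(params: BiologicalParameters,
                         dose_edges, doses) -> RateSchedule:
    """Rate schedule for a piecewise-constant dose trajectory.

    ``nu`` follows the (optional) initiation dose-response, promotion and
    malignant conversion follow theirs, and ``beta`` is derived as
    ``alpha - g_eff - mu1_eff`` per interval (raises if negative).
    """
    doses = np.asarray(doses, dtype=float)
    g_eff = np.asarray(params.g_at_dose(doses))
    mu1_eff = np.asarray(params.mu1_at_dose(doses))
    nu = np.asarray(params.nu_at_dose(doses))
    beta = params.alpha - g_eff - mu1_eff
    if np.any(beta < 0):
        raise ValueError("beta = alpha - g_eff - mu1_eff < 0 at some dose")
    alpha = np.full_like(beta, params.alpha)
    return RateSchedule(dose_edges, nu, alpha, beta, mu1_eff)
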