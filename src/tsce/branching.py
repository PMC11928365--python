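"""Direct stochastic simulation of the two-stage cell model.

An independent check on the analytic survival: initiations arrive as a
Poisson process of rate ``nu`` on ``[0, t]``; each initiated cell founds a
clone simulated event-by-event (Gillespie) with division rate ``alpha``,
death rate ``beta`` and malignant-conversion rate ``mu1`` per cell.  The
fraction of runs with at least one malignant cell by ``t`` estimates
``1 - S(t)`` without touching the Riccati machinery.  Constant rates only;
meant for fast toy parameters, not cohort-scale rates.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_cancer_probability"]


@njit(cache=False)
def _count_cancers(nu, alpha, beta, mu1, t_end, n_runs, seed):
    np.random.seed(seed)
    total = alpha + beta + mu1
    p_div = alpha / total
    p_death = (alpha + beta) / total
    cancers = 0
    for _ in range(n_runs):
        n_clones = np.random.poisson(nu * t_end)
        got_cancer = False
        for _ in range(n_clones):
            t = np.random.uniform(0.0, t_end)
            n_cells = 1
            while n_cells > 0 and t < t_end:
                t += np.random.exponential(1.0 / (n_cells * total))
                if t >= t_end:
                    break
                r = np.random.random()
                if r < p_div:
                    n_cells += 1
                elif r < p_death:
                    n_cells -= 1
                else:
                    got_cancer = True
                    break
            if got_cancer:
                break
        if got_cancer:
            cancers += 1
    return cancers


def simulate_cancer_probability(nu: float, alpha: float, beta: float,
                                mu1: float, t: float, n_runs: int = 100_000,
                                seed: int = 0) -> float:
    """Monte-Carlo estimate of ``1 - S(t)`` under constant rates.

    Standard error is about ``sqrt(p*(1-p)/n_runs)``.
    """
    if min(nu, alpha, beta, mu1) < 0 or t < 0:
        raise ValueError("rates and t must be non-negative")
    if n_runs < 1:
        raise ValueError("n_runs must be positive")
    return _count_cancers(nu, alpha, beta, mu1, t, n_runs, seed) / n_runs
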