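"""Simulation-based validation harnesses: parameter recovery and coverage.

These drive the whole stack end to end — generate a single-group cohort
from a known parameter set, fit it back by maximum likelihood, and (for
coverage) wrap the fit in a Metropolis–Hastings chain — and are used both
by the test suite and by the reproduction script.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np

from .inference import ModelSpec, fit_mle
from .params import REFERENCE_PARAMS, BiologicalParameters
from .synthetic import generate_cohort, single_group_config

__all__ = ["single_group_spec", "parameter_recovery", "mu0_coverage"]

RECOVERED = ("mu0", "g", "g_c", "mu1_c")


def single_group_spec() -> ModelSpec:
    """Four free parameters, no group structure — the one-group fit."""
    return ModelSpec(sharing={p: "shared" for p in RECOVERED},
                     name="single_group")


def parameter_recovery(race: str, gender: str, n: int,
                       seeds: Sequence[int],
                       truth: Optional[BiologicalParameters] = None,
                       n_starts: int = 3) -> Dict[str, Dict[str, float]]:
    """Generate-and-refit experiment for one group.

    For each seed, a cohort of size ``n`` is generated under ``truth``
    (default: the group's reference parameter set) and the four free
    parameters are re-estimated by MLE.  Returns, per parameter, the
    per-seed estimates, their median, the generating value, and the median's
    relative error.
    """
    truth = truth if truth is not None else REFERENCE_PARAMS[(race, gender)]
    spec = single_group_spec()
    spec = ModelSpec(sharing=spec.sharing, g_p=truth.g_p, mu1_p=truth.mu1_p,
                     X=truth.X, alpha=truth.alpha, name=spec.name)
    estimates: Dict[str, List[float]] = {p: [] for p in RECOVERED}
    for seed in seeds:
        cfg = single_group_config(race, gender, n, params=truth, seed=seed)
        cohort = generate_cohort(cfg)
        fit = fit_mle(cohort, spec, seed=seed, n_starts=n_starts)
        if not fit.converged:
            raise RuntimeError(f"recovery fit failed for seed {seed}")
        for p in RECOVERED:
            estimates[p].append(fit.estimates[f"{p}[all]"])
    truth_vals = {"mu0": truth.mu0, "g": truth.g,
                  "g_c": truth.g_c, "mu1_c": truth.mu1_c}
    out = {}
    for p in RECOVERED:
        med = float(np.median(estimates[p]))
        out[p] = {"median": med, "truth": truth_vals[p],
                  "rel_error": (med - truth_vals[p]) / truth_vals[p],
                  "per_seed": list(estimates[p])}
    return out


def mu0_coverage(race: str, gender: str, n: int, n_replicates: int,
                 n_steps: int = 4000, base_seed: int = 0,
                 level: float = 0.95) -> Dict[str, object]:
    """How often the MH percentile interval covers the generating ``mu0``.

    Each replicate generates a cohort, fits it, samples a chain and checks
    whether the equal-tailed interval for ``mu0`` brackets the truth.
    """
    from .uncertainty import mh_sample, percentile_ci

    truth = REFERENCE_PARAMS[(race, gender)]
    spec = single_group_spec()
    covered = []
    seeds = [int(s) for s in
             np.random.SeedSequence(base_seed).generate_state(n_replicates)
             % (2**31 - 1)]
    for seed in seeds:
        cfg = single_group_config(race, gender, n, params=truth, seed=seed)
        cohort = generate_cohort(cfg)
        fit = fit_mle(cohort, spec, seed=seed, n_starts=2)
        chain = mh_sample(cohort, spec, fit, n_steps=n_steps, seed=seed)
        ci = percentile_ci(chain, level=level)
        lo, hi = ci.loc["mu0[all]", ["lo", "hi"]]
        covered.append(bool(lo <= truth.mu0 <= hi))
    return {"covered": covered, "n_covered": int(sum(covered)),
            "n_replicates": n_replicates, "seeds": seeds}
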