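"""Metropolis–Hastings interval estimation for fitted TSCE models.

Interval estimates mirror the reference analysis: a random-walk
Metropolis–Hastings chain explores the likelihood surface (flat prior on the
log-parameter domain, so the target is the likelihood as a function of
position) and 95% equal-tailed percentile intervals of the post-burn-in
draws are reported.  The proposal is an isotropic Gaussian on log
parameters whose scale is adapted toward a 20–40% acceptance rate during
burn-in and then frozen, keeping the post-burn-in chain a valid MH sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .inference import FitResult, ModelSpec, _objective
from .likelihood import Cohort

__all__ = ["MCMCChain", "mh_sample", "percentile_ci", "gelman_rubin"]


@dataclass
class MCMCChain:
    """Posterior draws (natural scale) with sampler diagnostics."""

    draws: pd.DataFrame          # post-burn-in, thinned; one column per parameter
    log_post: np.ndarray
    acceptance_rate: float
    seed: int
    n_steps: int
    burn_in: int
    thin: int
    step_scale: float

    def __post_init__(self):
        if not 0.0 < self.acceptance_rate < 1.0:
            warnings.warn(f"acceptance rate {self.acceptance_rate:.3f} is "
                          "degenerate; chain is unlikely to be useful")

    def __len__(self) -> int:
        return len(self.draws)

    def to_csv(self, path) -> None:
        self.draws.to_csv(path, index=False)


def random_walk_mh(log_target: Callable[[np.ndarray], float],
                   x0: np.ndarray, n_steps: int, seed: int,
                   step_scale: float = 0.1, burn_in: int = 0,
                   adapt: bool = True, target_accept: float = 0.3,
                   ) -> Tuple[np.ndarray, np.ndarray, float, float]:
    """Generic random-walk MH core (also the analytic-target test hook).

    Returns (chain including burn-in, log-target trace, post-burn-in
    acceptance rate, final step scale).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    lp = log_target(x)
    if not np.isfinite(lp):
        raise ValueError("log target is not finite at the initial point")
    dim = x.size
    chain = np.empty((n_steps, dim))
    trace = np.empty(n_steps)
    scale = step_scale
    accepted_post = 0
    window_acc = 0
    for i in range(n_steps):
        prop = x + scale * rng.standard_normal(dim)
        lp_prop = log_target(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            window_acc += 1
            if i >= burn_in:
                accepted_post += 1
        chain[i] = x
        trace[i] = lp
        if adapt and i < burn_in and (i + 1) % 25 == 0:
            rate = window_acc / 25.0
            scale *= float(np.exp(0.6 * (rate - target_accept)))
            window_acc = 0
    n_post = max(n_steps - burn_in, 1)
    return chain, trace, accepted_post / n_post, scale


def mh_sample(cohort: Cohort, spec: ModelSpec, init: FitResult,
              n_steps: int = 5000, seed: int = 0,
              burn_in_fraction: float = 0.2, thin: int = 1,
              step_scale: float = 0.1) -> MCMCChain:
    """Sample the likelihood surface around a converged fit.

    ``init`` supplies both the starting point and the parameter names; the
    burn-in fraction (default 20%) is discarded after proposal adaptation.
    Fully reproducible given ``seed``.
    """
    if n_steps < 1000:
        raise ValueError("n_steps must be >= 1000")
    if not init.converged or not init.estimates:
        raise ValueError("initial fit has not converged")
    names = spec.param_names()
    x0 = np.log([init.estimates[n] for n in names])
    negll = _objective(cohort, spec, names)

    def log_target(x):
        v = -negll(x)
        return v if v > -1e11 else -np.inf

    burn = int(burn_in_fraction * n_steps)
    chain, trace, acc, scale = random_walk_mh(
        log_target, x0, n_steps, seed, step_scale=step_scale, burn_in=burn)
    kept = chain[burn::thin]
    draws = pd.DataFrame(np.exp(kept), columns=names)
    return MCMCChain(draws=draws, log_post=trace[burn::thin],
                     acceptance_rate=acc, seed=seed, n_steps=n_steps,
                     burn_in=burn, thin=thin, step_scale=scale)


def percentile_ci(chain: MCMCChain, level: float = 0.95,
                  point: Optional[Dict[str, float]] = None) -> pd.DataFrame:
    """Equal-tailed percentile interval per parameter.

    Warns if an interval has zero width or fails to bracket the supplied
    point estimate.
    """
    if len(chain) < 500:
        raise ValueError("need at least 500 post-burn-in draws")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    tail = 100.0 * (1.0 - level) / 2.0
    rows = []
    for name in chain.draws.columns:
        v = chain.draws[name].to_numpy()
        lo, hi = np.percentile(v, [tail, 100.0 - tail])
        if lo == hi:
            warnings.warn(f"degenerate (zero-width) interval for {name}")
        if point is not None and name in point and not lo < point[name] < hi:
            warnings.warn(f"point estimate for {name} outside the "
                          f"{level:.0%} interval")
        rows.append({"parameter": name, "lo": lo, "hi": hi,
                     "median": float(np.median(v)), "level": level})
    return pd.DataFrame(rows).set_index("parameter")


def gelman_rubin(chains) -> Dict[str, float]:
    """Potential scale reduction factor per parameter across chains."""
    names = chains[0].draws.columns
    out = {}
    for name in names:
        seqs = np.array([c.draws[name].to_numpy() for c in chains])
        n = seqs.shape[1]
        means = seqs.mean(axis=1)
        W = seqs.var(axis=1, ddof=1).mean()
        B = n * means.var(ddof=1)
        var_hat = (n - 1) / n * W + B / n
        out[name] = float(np.sqrt(var_hat / W))
    return out
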