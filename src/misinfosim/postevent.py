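"""Post-event engagement: zero-intercept Bayesian log-normal regression.

The generative model covers viral periods only, but the size of an
incident's largest event strongly predicts engagement after it. The bridge
is a through-the-origin log-log regression:

    ln(y) ~ Normal(beta * ln(x), sigma)
    beta  ~ Cauchy(0, 1)
    sigma ~ HalfCauchy(0, 1)

with y the post-event engagement and x the engagement during the largest
event. The predictor enters on the log scale: with raw x in the thousands
to millions a linear-scale mean would be astronomically large, and the
empirical relationship is log-log. The intercept is zero — an event with no
posts is not expected to produce subsequent posts — so projections map zero
simulated engagement to zero.

The posterior feeds projection: for each simulation run, a (beta, sigma)
draw converts each event's simulated (intervention-adjusted) total into a
log-normal draw of subsequent engagement, summed across events.
"""

from __future__ import annotations

from dataclasses import dataclass

import emcee
import numpy as np
import pandas as pd

from .experiment import ScenarioResult, summarize_quantiles


@dataclass
class RegressionPosterior:
    """Draws of (beta_reg, sigma) from the post-event regression."""

    draws: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        if self.draws.ndim != 2 or self.draws.shape[1] != 2:
            raise ValueError("draws must have shape (n, 2)")
        if np.any(self.draws[:, 1] <= 0):
            raise ValueError("sigma draws must be positive")

    @property
    def beta(self) -> np.ndarray:
        return self.draws[:, 0]

    @property
    def sigma(self) -> np.ndarray:
        return self.draws[:, 1]

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, name in enumerate(("beta_reg", "sigma")):
            med, lo, hi = summarize_quantiles(self.draws[:, i])
            rows.append(
                {
                    "param": name,
                    "mean": float(self.draws[:, i].mean()),
                    "sd": float(self.draws[:, i].std(ddof=1)),
                    "median": med,
                    "ci_lo": lo,
                    "ci_hi": hi,
                }
            )
        return pd.DataFrame(rows)


def fit_postevent(
    pairs,
    n_walkers: int = 16,
    n_steps: int = 2000,
    n_burn: int = 500,
    rng_seed: int = 0,
) -> RegressionPosterior:
    """Fit the regression to (event_engagement, post_event_engagement) pairs.

    ``pairs`` is an iterable of (x, y) or a DataFrame with columns
    ``event_engagement`` and ``post_event_engagement``. Pairs with
    non-positive x are invalid; pairs with y = 0 are excluded from fitting
    (log undefined) but handled as zeros at projection time.
    """
    if isinstance(pairs, pd.DataFrame):
        arr = pairs[["event_engagement", "post_event_engagement"]].to_numpy(float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
    if np.any(arr[:, 0] <= 0):
        raise ValueError("event engagement x must be positive")
    arr = arr[arr[:, 1] > 0]
    if len(arr) < 2:
        raise ValueError("need at least 2 pairs with positive y")
    lx = np.log(arr[:, 0])
    ly = np.log(arr[:, 1])
    n = len(lx)

    def log_prob(u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(u)
        beta, log_sigma = u[:, 0], np.clip(u[:, 1], -300.0, 300.0)
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            sigma = np.exp(log_sigma)
            # Cauchy(0,1) prior on beta; half-Cauchy on sigma + log Jacobian
            lp = -np.log1p(beta**2) - np.log1p(sigma**2) + log_sigma
            resid = ly[:, None] - beta[None, :] * lx[:, None]
            ll = -n * (log_sigma + 0.5 * np.log(2 * np.pi)) - 0.5 * (
                resid**2
            ).sum(axis=0) / sigma**2
            out = lp + ll
        return np.where(np.isfinite(out), out, -np.inf)

    rng = np.random.default_rng(rng_seed)
    beta0 = float(np.dot(lx, ly) / np.dot(lx, lx))
    sigma0 = float(np.std(ly - beta0 * lx) + 1e-3)
    p0 = np.column_stack(
        [
            beta0 + 0.05 * rng.standard_normal(n_walkers),
            np.log(sigma0) + 0.1 * rng.standard_normal(n_walkers),
        ]
    )
    sampler = emcee.EnsembleSampler(n_walkers, 2, log_prob, vectorize=True)
    sampler.random_state = np.random.RandomState(
        np.random.SeedSequence(rng_seed).generate_state(1)[0]
    ).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn).reshape(-1, 2)
    draws = np.column_stack(
        [chain[:, 0], np.exp(np.clip(chain[:, 1], -300.0, 300.0))]
    )
    return RegressionPosterior(draws=draws)


def project_postevent(
    scenario: ScenarioResult,
    posterior: RegressionPosterior,
    rng_seed: int = 0,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Project post-event engagement from a scenario's per-event totals.

    For each run, one (beta, sigma) posterior draw is applied to every
    event: events with positive simulated engagement x contribute a
    LogNormal(beta ln x, sigma) draw, events with zero engagement contribute
    zero. Returns the per-run projected totals and their
    (median, lo, hi) 89% summary.
    """
    rng = np.random.default_rng(rng_seed)
    totals = np.asarray(scenario.per_event_totals, dtype=float)
    n_runs, n_events = totals.shape
    idx = rng.integers(len(posterior.draws), size=n_runs)
    beta = posterior.beta[idx][:, None]
    sigma = posterior.sigma[idx][:, None]
    out = np.zeros_like(totals)
    positive = totals > 0
    noise = rng.standard_normal(totals.shape)
    with np.errstate(divide="ignore"):
        log_mu = beta * np.where(positive, np.log(np.where(positive, totals, 1.0)), 0.0)
    out[positive] = np.exp(log_mu + sigma * noise)[positive]
    projected = out.sum(axis=1)
    return projected, summarize_quantiles(projected)
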