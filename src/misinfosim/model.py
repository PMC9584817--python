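"""The generative core: latent-virality recursion and forward simulation.

Post volume during a viral event is modelled as a branching process with a
latent virality state ``v_t`` that tracks accumulated audience exposure:

    E[y_t]  = exp(alpha + beta * v_{t-1})
    v_t     = v_{t-1} * delta * exp(-lam * t) + x_{t-1}
    x_t     = log( sum_j (F_j + 1) )        over the bin-t posters
    y_t     ~ NegBin2(mu_t, phi)            (mean mu, Var = mu + mu^2/phi)

``alpha`` is the baseline log-rate of discussion, ``beta`` the effect of
virality, ``delta`` the per-step retention of virality, ``lam`` accelerates
decay over the lifetime of an event (network saturation, competing topics),
and ``phi`` the negative-binomial dispersion. ``F_j`` is poster j's follower
count (out-degree); one follower is added per user so a bin of zero-follower
posters still contributes. ``v_1 = x_1``.

Forward simulation seeds the model with the observed first bin and draws
follower counts for simulated posts from the event's empirical per-bin
poster pools, so time-varying account composition is carried into the
counterfactuals without an explicit network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .corpus import EventSeries

logger = logging.getLogger(__name__)

#: Cap on the linear predictor alpha + beta*v before exponentiation in
#: simulation. exp(21) ~ 1.3e9 expected posts per bin, far above any
#: realistic cap, so this is a numerical guard only.
EXP_CAP = 21.0


@dataclass
class ModelParams:
    """The five parameters of the engagement model."""

    alpha: float
    beta: float
    delta: float
    lam: float
    phi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.phi <= 0:
            raise ValueError(f"phi must be > 0, got {self.phi}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.delta, self.lam, self.phi])

    @classmethod
    def from_array(cls, a) -> "ModelParams":
        return cls(*(float(x) for x in a))


PARAM_NAMES = ("alpha", "beta", "delta", "lam", "phi")


@dataclass
class ViralityState:
    """Latent state at step t: virality v_t and the log-exposure x_t."""

    t: int
    v: float
    x: float

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("virality must be non-negative")


@dataclass
class PolicyPlan:
    """A per-run realized intervention plan consumed by the simulator.

    All times are 1-based bin indices; an operator acts on bins strictly
    greater than its activation bin. ``math.inf`` means "never". This is
    the resolved form of a declarative policy after per-run enforcement
    lotteries and ban-set resolution (see :mod:`misinfosim.interventions`).
    """

    removal_bin: float = math.inf
    cb_start_bin: float = math.inf
    cb_reduction: float = 0.0
    eta: float = 0.0
    banned: frozenset = field(default_factory=frozenset)

    def is_identity(self) -> bool:
        return (
            math.isinf(self.removal_bin)
            and (math.isinf(self.cb_start_bin) or self.cb_reduction == 0.0)
            and self.eta == 0.0
            and not self.banned
        )


@dataclass
class SimulationSpec:
    """Inputs for one forward simulation of one event."""

    event: EventSeries
    params: ModelParams
    cap_multiplier: float = 2.0
    rng_seed: int | np.random.Generator | None = None
    plan: PolicyPlan | None = None

    def __post_init__(self) -> None:
        if self.cap_multiplier <= 0:
            raise ValueError("cap_multiplier must be positive")


@dataclass
class Trajectory:
    """One simulated path: per-bin posts, virality and running engagement."""

    t: np.ndarray
    y_sim: np.ndarray
    v: np.ndarray
    cumulative: np.ndarray

    @property
    def total(self) -> float:
        return float(self.cumulative[-1]) if len(self.cumulative) else 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "y_sim": self.y_sim, "v": self.v,
             "cumulative": self.cumulative}
        )


def log_sum_followers(followers, plus_one: str = "per_user") -> float:
    """Log total exposure ``x`` of a bin's posters.

    ``per_user`` (default) adds one follower to each user before summing,
    ``x = ln(sum_j (F_j + 1))``; ``total`` adds a single one to the sum,
    ``x = ln(sum_j F_j + 1)``. An empty bin contributes ``x = 0``.
    """
    f = np.asarray(followers, dtype=float)
    if f.size == 0:
        return 0.0
    if np.any(f < 0):
        raise ValueError("negative follower count")
    if plus_one == "per_user":
        return float(np.log(np.sum(f + 1.0)))
    if plus_one == "total":
        return float(np.log(np.sum(f) + 1.0))
    raise ValueError(f"unknown plus_one mode {plus_one!r}")


def virality_update(state: ViralityState, x_prev: float, params: ModelParams) -> float:
    """One step of the latent recursion: v_t = v_{t-1} d e^{-lam t} + x_{t-1}.

    ``state`` holds v_{t-1}; ``state.t`` is the *current* 1-based step t
    whose virality is being computed.
    """
    return state.v * params.delta * math.exp(-params.lam * state.t) + x_prev


def expected_posts(params: ModelParams, v_prev: float) -> float:
    """Expected bin count mu = exp(alpha + beta * v_{t-1}), overflow-guarded."""
    eta = params.alpha + params.beta * v_prev
    if eta > EXP_CAP:
        logger.warning(
            "linear predictor %.2f exceeds cap %.1f; clamping", eta, EXP_CAP
        )
        eta = EXP_CAP
    return math.exp(eta)


def draw_posts(mu, phi, rng: np.random.Generator):
    """Draw from the mean/dispersion negative binomial (gamma-Poisson).

    E = mu, Var = mu + mu^2/phi: a Poisson whose rate is Gamma(shape=phi,
    scale=mu/phi). Accepts scalars or arrays.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or phi <= 0:
        raise ValueError("mu and phi must be positive")
    rate = rng.gamma(shape=phi, scale=mu / phi)
    out = rng.poisson(rate)
    return int(out) if np.isscalar(out) or out.shape == () else out


def prepare_event(
    event: EventSeries, banned: frozenset | set = frozenset()
) -> list[np.ndarray]:
    """Per-bin empirical follower pools, with banned accounts' posts removed.

    Returns one float array of follower counts per bin, in bin order. The
    observed-count caps used by the simulator are *not* recomputed after
    bans (the counterfactual keeps the factual cap).
    """
    pools = []
    for b in event.bins:
        if b.posters is None:
            raise ValueError(
                f"event {event.event_id!r}: bin {b.index} lacks poster detail"
            )
        pools.append(
            np.array(
                [f for aid, f in b.posters if aid not in banned], dtype=float
            )
        )
    return pools


def simulate_event(
    spec: SimulationSpec,
    follower_pools: list[np.ndarray] | None = None,
    plus_one: str = "per_user",
    cap_mode: str = "per_bin",
) -> Trajectory:
    """Simulate one event forward under the model and an intervention plan.

    Bin 1 is taken from the data: the (ban-filtered) observed seed posts and
    their exposure. For t >= 2, posts are drawn NegBin2(mu_t, phi) and
    clamped at ``cap_multiplier`` x the observed count for that bin (a guard
    against long-tail runaway; with ``cap_mode="event_max"`` the cap is
    ``cap_multiplier`` x the event's peak instead). Follower counts for
    simulated posts are resampled with replacement from the bin's empirical
    pool; if a bin's pool is empty (possible after bans) the event-wide pool
    is used, and if that is empty too the bin contributes no exposure.

    Interventions (all optional, via ``spec.plan``): removal zeroes all
    bins after its activation bin; a circuit breaker multiplies virality by
    ``(1 - c)`` at every step after activation; a nudge scales every
    follower count used in exposure by ``(1 - eta)``; bans are already
    reflected in the filtered pools.
    """
    event = spec.event
    if not event.bins:
        raise ValueError("empty event")
    plan = spec.plan or PolicyPlan()
    if follower_pools is None:
        follower_pools = prepare_event(event, plan.banned)
    T = len(event.bins)
    if len(follower_pools) != T:
        raise ValueError("follower_pools length does not match event length")
    rng = (
        spec.rng_seed
        if isinstance(spec.rng_seed, np.random.Generator)
        else np.random.default_rng(spec.rng_seed)
    )
    p = spec.params
    y_obs = np.asarray(event.counts)
    if cap_mode == "per_bin":
        caps = np.floor(spec.cap_multiplier * y_obs).astype(int)
    elif cap_mode == "event_max":
        caps = np.full(T, int(spec.cap_multiplier * y_obs.max()))
    else:
        raise ValueError(f"unknown cap_mode {cap_mode!r}")
    event_pool = (
        np.concatenate(follower_pools)
        if any(len(q) for q in follower_pools)
        else np.array([])
    )
    scale = 1.0 - plan.eta

    def exposure(drawn: np.ndarray) -> float:
        return log_sum_followers(drawn * scale, plus_one=plus_one)

    y_sim = np.zeros(T, dtype=int)
    v_path = np.zeros(T)
    # seed at the first bin with any (ban-filtered) posts; a fully banned
    # event never starts and contributes zero engagement
    seed_bin = next(
        (i + 1 for i, q in enumerate(follower_pools) if len(q)), None
    )
    if seed_bin is None:
        return Trajectory(
            t=np.arange(1, T + 1),
            y_sim=y_sim,
            v=v_path,
            cumulative=np.zeros(T),
        )
    y_sim[seed_bin - 1] = len(follower_pools[seed_bin - 1])
    x_prev = exposure(follower_pools[seed_bin - 1])
    v = x_prev  # virality initialized at the seed bin's exposure
    v_path[seed_bin - 1] = v
    for t in range(seed_bin + 1, T + 1):
        if t > plan.removal_bin:
            y_t = 0
            x_t = 0.0
        else:
            mu = expected_posts(p, v)
            y_t = min(draw_posts(max(mu, 1e-300), p.phi, rng), caps[t - 1])
            pool = follower_pools[t - 1]
            if len(pool) == 0:
                pool = event_pool
            if y_t > 0 and len(pool) > 0:
                drawn = rng.choice(pool, size=y_t, replace=True)
            else:
                drawn = np.array([])
            x_t = exposure(drawn)
        y_sim[t - 1] = y_t
        v = v * p.delta * math.exp(-p.lam * t) + x_prev
        if t > plan.cb_start_bin:
            v *= 1.0 - plan.cb_reduction
        v_path[t - 1] = v
        x_prev = x_t
    return Trajectory(
        t=np.arange(1, T + 1),
        y_sim=y_sim,
        v=v_path,
        cumulative=np.cumsum(y_sim),
    )


def observed_exposures(event: EventSeries, plus_one: str = "per_user") -> np.ndarray:
    """The observed per-bin log-exposures x_1..x_T from poster detail."""
    xs = np.zeros(len(event.bins))
    for i, b in enumerate(event.bins):
        if b.posters is None:
            raise ValueError(
                f"event {event.event_id!r}: bin {b.index} lacks poster detail"
            )
        xs[i] = log_sum_followers([f for _aid, f in b.posters], plus_one=plus_one)
    return xs
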