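"""Declarative intervention policies and the operators that realize them.

Four intervention families are modelled, alone or combined:

* **Removal** — all posts are zeroed after a delay (outright takedown),
  optionally enforced only for a fraction of events per run.
* **Virality circuit breaker** — latent virality is multiplied by
  ``(1 - c)`` at every step after a delay (suspended algorithmic
  amplification), optionally with a follow-on outright removal of a
  fraction of the circuit-broken content.
* **Nudge** — every follower count feeding the exposure term is scaled by
  ``(1 - eta)`` (accuracy prompts reducing individual sharing).
* **Account bans** — an explicit ban list and/or a three-strikes rule: an
  account in scope accrues one strike per *distinct incident* it posts in,
  regardless of post count, and is excluded from all events that start
  strictly after its third strike.

Delays are specified in minutes and converted to whole five-minute bins by
ceiling (interventions cannot act mid-bin). ``compose_policy`` performs the
per-run enforcement lotteries and emits the resolved
:class:`~misinfosim.model.PolicyPlan` the simulator consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .corpus import BIN_WIDTH, AccountRegistry, EventSeries, IncidentSeries
from .model import PolicyPlan, Trajectory


def minutes_to_bins(minutes: float) -> int:
    """Ceiling conversion of a delay in minutes to whole 5-minute bins."""
    if minutes < 0:
        raise ValueError("delay must be >= 0")
    return math.ceil(minutes / (BIN_WIDTH / 60.0))


def _check_frac(value: float, name: str) -> float:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")
    return value


@dataclass
class RemovalSpec:
    delay_minutes: float = 0.0
    enforcement_probability: float = 1.0

    def __post_init__(self) -> None:
        _check_frac(self.enforcement_probability, "enforcement_probability")
        minutes_to_bins(self.delay_minutes)


@dataclass
class FollowOnRemoval:
    delay_minutes: float
    probability: float

    def __post_init__(self) -> None:
        _check_frac(self.probability, "probability")
        minutes_to_bins(self.delay_minutes)


@dataclass
class CircuitBreakerSpec:
    delay_minutes: float = 0.0
    virality_reduction: float = 0.1
    enforcement_probability: float = 1.0
    follow_on_removal: FollowOnRemoval | None = None

    def __post_init__(self) -> None:
        _check_frac(self.virality_reduction, "virality_reduction")
        _check_frac(self.enforcement_probability, "enforcement_probability")
        minutes_to_bins(self.delay_minutes)


@dataclass
class NudgeSpec:
    eta: float

    def __post_init__(self) -> None:
        _check_frac(self.eta, "eta")


@dataclass
class ThreeStrikesSpec:
    """Scope of a three-strikes rule.

    An account is in scope if it is verified (when ``verified`` is set), or
    has strictly more followers than ``follower_threshold`` (when set), or
    unconditionally (``all_accounts``).
    """

    verified: bool = False
    follower_threshold: int | None = None
    all_accounts: bool = False
    strikes: int = 3

    def __post_init__(self) -> None:
        if self.strikes < 1:
            raise ValueError("strikes must be >= 1")

    def in_scope(self, followers: int, is_verified: bool) -> bool:
        if self.all_accounts:
            return True
        if self.verified and is_verified:
            return True
        if (
            self.follower_threshold is not None
            and followers > self.follower_threshold
        ):
            return True
        return False


@dataclass
class BanSpec:
    explicit: frozenset = field(default_factory=frozenset)
    three_strikes: ThreeStrikesSpec | None = None

    def __post_init__(self) -> None:
        self.explicit = frozenset(self.explicit)


@dataclass
class InterventionPolicy:
    """Declarative description of a (possibly combined) intervention."""

    policy_id: str = "policy"
    removal: RemovalSpec | None = None
    circuit_breaker: CircuitBreakerSpec | None = None
    nudge: NudgeSpec | None = None
    bans: BanSpec | None = None

    @classmethod
    def baseline(cls) -> "InterventionPolicy":
        return cls(policy_id="baseline")

    @classmethod
    def from_dict(cls, d: dict) -> "InterventionPolicy":
        policy = cls(policy_id=str(d.get("policy_id", "policy")))
        if "removal" in d and d["removal"] is not None:
            policy.removal = RemovalSpec(**d["removal"])
        if "circuit_breaker" in d and d["circuit_breaker"] is not None:
            cb = dict(d["circuit_breaker"])
            if cb.get("follow_on_removal") is not None:
                cb["follow_on_removal"] = FollowOnRemoval(**cb["follow_on_removal"])
            policy.circuit_breaker = CircuitBreakerSpec(**cb)
        if "nudge" in d and d["nudge"] is not None:
            policy.nudge = NudgeSpec(**d["nudge"])
        if "bans" in d and d["bans"] is not None:
            b = dict(d["bans"])
            if b.get("three_strikes") is not None:
                b["three_strikes"] = ThreeStrikesSpec(**b["three_strikes"])
            if "explicit" in b:
                b["explicit"] = frozenset(b["explicit"])
            policy.bans = BanSpec(**b)
        return policy

    def to_dict(self) -> dict:
        from dataclasses import asdict

        out: dict = {"policy_id": self.policy_id}
        for name in ("removal", "circuit_breaker", "nudge", "bans"):
            value = getattr(self, name)
            if value is not None:
                d = asdict(value)
                if name == "bans":
                    d["explicit"] = sorted(d["explicit"])
                out[name] = d
        return out


def modest_combined(
    ban_list: frozenset | set = frozenset(),
) -> InterventionPolicy:
    """Modest combined preset: circuit breakers for 5% of content (c = 0.10,
    120 min; 20% of circuit-broken content removed after 240 min), a 10%
    nudge, the prior ban list, and three strikes for verified accounts and
    accounts above 100K followers."""
    return InterventionPolicy(
        policy_id="modest_combined",
        circuit_breaker=CircuitBreakerSpec(
            delay_minutes=120,
            virality_reduction=0.10,
            enforcement_probability=0.05,
            follow_on_removal=FollowOnRemoval(delay_minutes=240, probability=0.20),
        ),
        nudge=NudgeSpec(eta=0.10),
        bans=BanSpec(
            explicit=frozenset(ban_list),
            three_strikes=ThreeStrikesSpec(verified=True, follower_threshold=100_000),
        ),
    )


def aggressive_combined(
    ban_list: frozenset | set = frozenset(),
) -> InterventionPolicy:
    """Aggressive combined preset: circuit breakers for 10% of content
    (c = 0.20) with response times halved (60/120 min), a 20% nudge, and the
    three-strikes follower threshold lowered to 50K."""
    return InterventionPolicy(
        policy_id="aggressive_combined",
        circuit_breaker=CircuitBreakerSpec(
            delay_minutes=60,
            virality_reduction=0.20,
            enforcement_probability=0.10,
            follow_on_removal=FollowOnRemoval(delay_minutes=120, probability=0.20),
        ),
        nudge=NudgeSpec(eta=0.20),
        bans=BanSpec(
            explicit=frozenset(ban_list),
            three_strikes=ThreeStrikesSpec(verified=True, follower_threshold=50_000),
        ),
    )


# ---------------------------------------------------------------------------
# Elementary operators
# ---------------------------------------------------------------------------


def apply_removal(trajectory: Trajectory, T_bins: int) -> Trajectory:
    """Zero all simulated posts after bin ``T_bins``; engagement freezes.

    Equivalent to running the simulation with removal active, since bins up
    to ``T_bins`` are unaffected by later ones.
    """
    if T_bins < 0:
        raise ValueError("T_bins must be >= 0")
    y = trajectory.y_sim.copy()
    keep = max(T_bins, 1)  # the observed seed bin is never removed
    y[keep:] = 0
    return Trajectory(
        t=trajectory.t.copy(),
        y_sim=y,
        v=trajectory.v.copy(),
        cumulative=np.cumsum(y),
    )


def apply_circuit_breaker(v_t: float, c: float, active: bool) -> float:
    """Reduced virality v_t * (1 - c) while the breaker is active."""
    _check_frac(c, "c")
    return v_t * (1.0 - c) if active else v_t


def apply_nudge(followers, eta: float):
    """Follower counts scaled by (1 - eta); non-integer results permitted."""
    _check_frac(eta, "eta")
    return np.asarray(followers, dtype=float) * (1.0 - eta)


# ---------------------------------------------------------------------------
# Bans and three-strikes
# ---------------------------------------------------------------------------


@dataclass
class StrikeLedger:
    """Per-account distinct-incident participation and resulting ban times.

    ``appearances`` maps account_id to its ordered (incident_id,
    first_post_time) list; ``ban_time`` holds the time of the first post in
    the account's third (n-th) distinct incident, for accounts that reach
    it. Bans are effective for events starting strictly later.
    """

    appearances: dict
    ban_time: dict

    def banned_for(self, event_start_time: float) -> frozenset:
        return frozenset(
            a for a, ts in self.ban_time.items() if event_start_time > ts
        )


def build_strike_ledger(
    corpus: list[IncidentSeries],
    scope: ThreeStrikesSpec,
    registry: AccountRegistry,
    width: float = BIN_WIDTH,
) -> StrikeLedger:
    """Accrue one strike per distinct incident for accounts in scope.

    The strike is timed at the account's first post within the incident;
    post counts within an incident are irrelevant (per-incident counting),
    so the ledger is invariant to within-incident post order.
    """
    for inc in corpus:
        if not np.isfinite(inc.start_time):
            raise ValueError(f"incident {inc.incident_id!r} has no orderable time")
    first_post: dict[str, dict[str, float]] = {}
    for inc in corpus:
        for b in inc.bins:
            t = inc.start_time + (b.index - 1) * width
            for aid, followers in b.posters or []:
                rec = registry.accounts.get(aid)
                is_verified = rec.verified if rec else False
                reg_followers = rec.followers if rec else followers
                if not scope.in_scope(reg_followers, is_verified):
                    continue
                seen = first_post.setdefault(aid, {})
                if inc.incident_id not in seen or t < seen[inc.incident_id]:
                    seen[inc.incident_id] = min(
                        t, seen.get(inc.incident_id, math.inf)
                    )
    appearances = {
        aid: sorted(
            ((iid, t) for iid, t in incs.items()), key=lambda p: (p[1], p[0])
        )
        for aid, incs in first_post.items()
    }
    ban_time = {
        aid: apps[scope.strikes - 1][1]
        for aid, apps in appearances.items()
        if len(apps) >= scope.strikes
    }
    return StrikeLedger(appearances=appearances, ban_time=ban_time)


def resolve_ban_set(
    policy: InterventionPolicy,
    event: EventSeries,
    ledger: StrikeLedger | None = None,
) -> frozenset:
    """The accounts excluded from this event under the policy's ban rules."""
    if policy.bans is None:
        return frozenset()
    banned = set(policy.bans.explicit)
    if policy.bans.three_strikes is not None:
        if ledger is None:
            raise ValueError("three-strikes policy requires a strike ledger")
        banned |= ledger.banned_for(event.start_time)
    return frozenset(banned)


def apply_bans(
    event: EventSeries, ban_set: frozenset | set
) -> tuple[list[np.ndarray], int]:
    """Filter banned accounts' posts out of every bin's poster pool.

    Returns the per-bin follower pools and the filtered seed count (the
    event's first-bin posts after ban removal). Observed-count caps are not
    recomputed (the counterfactual keeps the factual cap).
    """
    from .model import prepare_event

    pools = prepare_event(event, frozenset(ban_set))
    return pools, len(pools[0])


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def compose_policy(
    policy: InterventionPolicy | None,
    rng: np.random.Generator,
    ban_set: frozenset = frozenset(),
) -> PolicyPlan:
    """Realize a declarative policy into a per-run plan.

    Bernoulli lotteries (one per event per run) decide whether the removal
    and circuit-breaker components activate; follow-on removal is drawn
    only among circuit-broken events. Nudges and bans are always on when
    configured. Delays convert to bins by ceiling; an operator acts on bins
    strictly after its activation bin.
    """
    plan = PolicyPlan(banned=frozenset(ban_set))
    if policy is None:
        return plan
    removal_bin = math.inf
    if policy.removal is not None:
        if rng.random() < policy.removal.enforcement_probability:
            removal_bin = minutes_to_bins(policy.removal.delay_minutes)
    if policy.circuit_breaker is not None:
        cb = policy.circuit_breaker
        if rng.random() < cb.enforcement_probability:
            plan = replace(
                plan,
                cb_start_bin=minutes_to_bins(cb.delay_minutes),
                cb_reduction=cb.virality_reduction,
            )
            if cb.follow_on_removal is not None:
                if rng.random() < cb.follow_on_removal.probability:
                    removal_bin = min(
                        removal_bin,
                        minutes_to_bins(cb.follow_on_removal.delay_minutes),
                    )
    if policy.nudge is not None:
        plan = replace(plan, eta=policy.nudge.eta)
    return replace(plan, removal_bin=removal_bin)
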