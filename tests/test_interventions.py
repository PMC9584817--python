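import math

import numpy as np
import pytest

from misinfosim import (
    ModelParams,
    SimulationSpec,
    apply_bans,
    apply_circuit_breaker,
    apply_nudge,
    apply_removal,
    build_strike_ledger,
    compose_policy,
    simulate_event,
)
from misinfosim.corpus import AccountRecord, AccountRegistry, Bin, IncidentSeries
from misinfosim.interventions import (
    BanSpec,
    CircuitBreakerSpec,
    FollowOnRemoval,
    InterventionPolicy,
    NudgeSpec,
    RemovalSpec,
    ThreeStrikesSpec,
    minutes_to_bins,
    resolve_ban_set,
)
from misinfosim.model import PolicyPlan, log_sum_followers
from misinfosim.synthetic import SynthSpec, gen_event


@pytest.fixture(scope="module")
def event():
    rng = np.random.default_rng(17)
    from misinfosim.synthetic import gen_accounts

    registry, _ = gen_accounts(SynthSpec(n_accounts=900), rng)
    aids = np.array(sorted(registry.accounts))
    pool = (aids, np.array([registry[a].followers for a in aids]))
    params = ModelParams(alpha=-2.0, beta=0.3, delta=0.7, lam=0.05, phi=2.0)
    ev, _ = gen_event(params, pool, T_bins=36, seed_size=20, rng=rng)
    return ev, params


class TestElementaryOperators:
    def test_delay_converts_to_bins_by_ceiling(self):
        assert minutes_to_bins(0) == 0
        assert minutes_to_bins(30) == 6
        assert minutes_to_bins(31) == 7
        assert minutes_to_bins(120) == 24

    def test_removal_truncation(self, event):
        ev, params = event
        traj = simulate_event(SimulationSpec(event=ev, params=params, rng_seed=4))
        cut = apply_removal(traj, 6)
        assert np.array_equal(cut.y_sim[:6], traj.y_sim[:6])
        assert np.all(cut.y_sim[6:] == 0)
        assert cut.total == traj.cumulative[5]

    def test_removal_beyond_length_is_noop(self, event):
        ev, params = event
        traj = simulate_event(SimulationSpec(event=ev, params=params, rng_seed=4))
        same = apply_removal(traj, len(ev.bins))
        assert np.array_equal(same.y_sim, traj.y_sim)

    def test_circuit_breaker_identity_and_annihilation(self):
        assert apply_circuit_breaker(7.5, 0.0, active=True) == 7.5
        assert apply_circuit_breaker(7.5, 1.0, active=True) == 0.0
        assert apply_circuit_breaker(7.5, 0.4, active=False) == 7.5
        assert apply_circuit_breaker(10.0, 0.1, active=True) == pytest.approx(9.0)

    def test_nudge_scales_followers(self):
        out = apply_nudge([100, 0, 7], 0.1)
        assert np.allclose(out, [90.0, 0.0, 6.3])
        assert np.allclose(apply_nudge([5, 9], 0.0), [5, 9])

    def test_full_nudge_leaves_only_per_user_ones(self):
        # eta = 1: exposure collapses to ln(number of posters)
        f = apply_nudge([100, 200, 300], 1.0)
        assert log_sum_followers(f) == pytest.approx(math.log(3))


def incident_with(account_posts, incident_id, start_time):
    """account_posts: list of (bin_index, account_id, followers)."""
    n = max(b for b, _a, _f in account_posts)
    per_bin = {i: [] for i in range(1, n + 1)}
    for b, a, f in account_posts:
        per_bin[b].append((a, f))
    bins = [Bin(index=i, n_posts=len(per_bin[i]), posters=per_bin[i]) for i in per_bin]
    return IncidentSeries(incident_id=incident_id, start_time=start_time, bins=bins)


class TestStrikes:
    @pytest.fixture()
    def registry(self):
        reg = AccountRegistry()
        reg.add(AccountRecord("big", followers=200_000, verified=False))
        reg.add(AccountRecord("blue", followers=500, verified=True))
        reg.add(AccountRecord("small", followers=10, verified=False))
        return reg

    def make_corpus(self, poster):
        """One incident per day, the account posting in each of the first 4."""
        return [
            incident_with(
                [(1, poster, 100), (2, "small", 10)], f"i{d}", d * 86_400.0
            )
            for d in range(1, 5)
        ]

    def test_third_incident_sets_ban_time(self, registry):
        corpus = self.make_corpus("big")
        ledger = build_strike_ledger(
            corpus, ThreeStrikesSpec(follower_threshold=100_000), registry
        )
        assert ledger.ban_time == {"big": 3 * 86_400.0}
        # banned only for events starting strictly after the third strike
        assert "big" not in ledger.banned_for(3 * 86_400.0)
        assert "big" in ledger.banned_for(3 * 86_400.0 + 1)

    def test_many_posts_in_one_incident_are_one_strike(self, registry):
        inc = incident_with(
            [(t, "big", 100) for t in range(1, 11)], "solo", 0.0
        )
        ledger = build_strike_ledger(
            [inc], ThreeStrikesSpec(all_accounts=True), registry
        )
        assert len(ledger.appearances["big"]) == 1
        assert ledger.ban_time == {}

    def test_verified_scope_ignores_unverified_offender(self, registry):
        corpus = self.make_corpus("big")  # big is unverified
        ledger = build_strike_ledger(
            corpus, ThreeStrikesSpec(verified=True), registry
        )
        assert "big" not in ledger.ban_time

    def test_ledger_invariant_to_post_order(self, registry):
        posts = [(1, "big", 100), (1, "small", 10), (2, "big", 100)]
        a = incident_with(posts, "i1", 0.0)
        b = incident_with(list(reversed(posts)), "i1", 0.0)
        scope = ThreeStrikesSpec(all_accounts=True)
        la = build_strike_ledger([a], scope, registry)
        lb = build_strike_ledger([b], scope, registry)
        assert la.appearances == lb.appearances


class TestBans:
    def test_empty_ban_set_is_identity(self, event):
        ev, _ = event
        pools, seed = apply_bans(ev, frozenset())
        assert seed == ev.bins[0].n_posts
        assert all(
            len(p) == b.n_posts for p, b in zip(pools, ev.bins)
        )

    def test_banning_everyone_annihilates(self, event):
        ev, params = event
        everyone = frozenset(a for b in ev.bins for a, _f in b.posters or [])
        pools, seed = apply_bans(ev, everyone)
        assert seed == 0
        traj = simulate_event(
            SimulationSpec(
                event=ev, params=params, rng_seed=0,
                plan=PolicyPlan(banned=everyone),
            )
        )
        assert traj.total == 0


class TestComposition:
    def test_identity_policy_reproduces_baseline_totals(self, small_study):
        from misinfosim import run_scenario

        events, posteriors, *_ = small_study
        identity = InterventionPolicy(
            policy_id="identity",
            removal=RemovalSpec(delay_minutes=0, enforcement_probability=0.0),
            circuit_breaker=CircuitBreakerSpec(
                delay_minutes=0, virality_reduction=0.0, enforcement_probability=1.0
            ),
            nudge=NudgeSpec(eta=0.0),
            bans=BanSpec(explicit=frozenset()),
        )
        base = run_scenario(events, posteriors, None, n_runs=20, seed=12)
        same = run_scenario(events, posteriors, identity, n_runs=20, seed=12)
        assert np.array_equal(base.per_event_totals, same.per_event_totals)

    @pytest.mark.parametrize("p", [0.0, 1.0, 0.2])
    def test_enforcement_probability_calibrated(self, p):
        policy = InterventionPolicy(
            policy_id="cb",
            circuit_breaker=CircuitBreakerSpec(
                delay_minutes=60, virality_reduction=0.1, enforcement_probability=p
            ),
        )
        rng = np.random.default_rng(5)
        n = 10_000
        active = sum(
            not math.isinf(compose_policy(policy, rng).cb_start_bin)
            for _ in range(n)
        )
        se = math.sqrt(max(p * (1 - p), 1e-12) / n)
        assert abs(active / n - p) <= 3 * se + 1e-12

    def test_follow_on_removal_only_among_circuit_broken(self):
        policy = InterventionPolicy(
            policy_id="cb",
            circuit_breaker=CircuitBreakerSpec(
                delay_minutes=60,
                virality_reduction=0.1,
                enforcement_probability=0.3,
                follow_on_removal=FollowOnRemoval(delay_minutes=240, probability=1.0),
            ),
        )
        rng = np.random.default_rng(6)
        for _ in range(500):
            plan = compose_policy(policy, rng)
            if math.isinf(plan.cb_start_bin):
                assert math.isinf(plan.removal_bin)
            else:
                assert plan.removal_bin == 48

    def test_resolve_ban_set_merges_explicit_and_strikes(self, small_study):
        events, _post, _truth, incidents, registry, offenders = small_study
        from misinfosim.corpus import build_registry

        scope = ThreeStrikesSpec(all_accounts=True)
        ledger = build_strike_ledger(incidents, scope, registry)
        policy = InterventionPolicy(
            policy_id="bans",
            bans=BanSpec(explicit=frozenset({"zzz"}), three_strikes=scope),
        )
        late = max(events, key=lambda e: e.start_time)
        banned = resolve_ban_set(policy, late, ledger)
        assert "zzz" in banned
        assert banned - {"zzz"} == ledger.banned_for(late.start_time)
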