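import math

import numpy as np
import pytest

from misinfosim import (
    ModelParams,
    SimulationSpec,
    draw_posts,
    expected_posts,
    log_sum_followers,
    simulate_event,
    virality_update,
)
from misinfosim.model import PolicyPlan, ViralityState, observed_exposures
from misinfosim.synthetic import SynthSpec, gen_accounts, gen_event

RTOL = 1e-10


@pytest.fixture(scope="module")
def pool():
    rng = np.random.default_rng(3)
    registry, _ = gen_accounts(SynthSpec(n_accounts=800), rng)
    aids = np.array(sorted(registry.accounts))
    return aids, np.array([registry[a].followers for a in aids])


@pytest.fixture()
def event(pool):
    rng = np.random.default_rng(11)
    params = ModelParams(alpha=-2.0, beta=0.3, delta=0.7, lam=0.05, phi=2.0)
    ev, _prov = gen_event(params, pool, T_bins=36, seed_size=20, rng=rng)
    return ev, params


class TestExposure:
    def test_empty_bin_contributes_nothing(self):
        assert log_sum_followers([]) == 0.0

    def test_zero_follower_poster(self):
        # the per-user +1 makes a lone zero-follower poster ln(1) = 0
        assert log_sum_followers([0]) == 0.0

    def test_per_user_plus_one(self):
        assert math.isclose(
            log_sum_followers([9, 89]), math.log(100), rel_tol=RTOL
        )

    def test_single_plus_one_variant(self):
        assert math.isclose(
            log_sum_followers([9, 89], plus_one="total"),
            math.log(99),
            rel_tol=RTOL,
        )

    def test_negative_followers_rejected(self):
        with pytest.raises(ValueError):
            log_sum_followers([-1])


class TestRecursion:
    def test_memoryless_limit_delta_zero(self):
        p = ModelParams(alpha=0, beta=0, delta=0.0, lam=0.3, phi=1)
        for v, t, x in [(10, 2, 1.5), (0, 7, 0.0), (3.3, 100, 2.0)]:
            assert virality_update(ViralityState(t=t, v=v, x=0), x, p) == x

    def test_pure_accumulation_delta_one_lam_zero(self):
        p = ModelParams(alpha=0, beta=0, delta=1.0, lam=0.0, phi=1)
        assert math.isclose(
            virality_update(ViralityState(t=5, v=10, x=0), 1.5, p),
            11.5,
            rel_tol=RTOL,
        )

    def test_numeric_example(self):
        p = ModelParams(alpha=0, beta=0, delta=0.5, lam=0.1, phi=1)
        got = virality_update(ViralityState(t=2, v=10, x=0), 1.0, p)
        assert math.isclose(got, 10 * 0.5 * math.exp(-0.2) + 1, rel_tol=RTOL)


class TestLink:
    def test_no_virality_limit(self):
        p = ModelParams(alpha=-1.2, beta=0.0, delta=0.5, lam=0.1, phi=1)
        assert all(
            math.isclose(expected_posts(p, v), math.exp(-1.2), rel_tol=RTOL)
            for v in (0, 5, 50)
        )

    def test_identity_point(self):
        p = ModelParams(alpha=0.0, beta=0.7, delta=0.5, lam=0.1, phi=1)
        assert math.isclose(expected_posts(p, 0.0), 1.0, rel_tol=RTOL)

    def test_numeric_example(self):
        p = ModelParams(alpha=-3.0, beta=0.5, delta=0.5, lam=0.1, phi=1)
        assert math.isclose(expected_posts(p, 4.0), math.exp(-1.0), rel_tol=RTOL)

    def test_overflow_guarded(self):
        p = ModelParams(alpha=0.0, beta=1.0, delta=0.5, lam=0.1, phi=1)
        assert np.isfinite(expected_posts(p, 1e6))


class TestNegativeBinomial:
    def test_moments(self, rng):
        mu, phi, n = 5.0, 2.0, 200_000
        draws = draw_posts(np.full(n, mu), phi, rng)
        se_mean = math.sqrt((mu + mu**2 / phi) / n)
        assert abs(draws.mean() - mu) < 3 * se_mean
        var = draws.var(ddof=1)
        m4 = np.mean((draws - draws.mean()) ** 4)
        se_var = math.sqrt(max(m4 - var**2, 0) / n)
        assert abs(var - (mu + mu**2 / phi)) < 3 * se_var

    def test_poisson_limit(self, rng):
        draws = draw_posts(np.full(200_000, 5.0), 1e9, rng)
        assert abs(draws.var(ddof=1) - 5.0) < 0.1

    def test_invalid_args_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_posts(0.0, 1.0, rng)
        with pytest.raises(ValueError):
            draw_posts(1.0, 0.0, rng)


class TestSimulation:
    def test_same_seed_reproduces_bit_for_bit(self, event):
        ev, params = event
        runs = [
            simulate_event(SimulationSpec(event=ev, params=params, rng_seed=5))
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].y_sim, runs[1].y_sim)
        assert np.array_equal(runs[0].v, runs[1].v)

    def test_cap_respected_everywhere(self, event):
        ev, params = event
        hot = ModelParams(alpha=1.0, beta=0.5, delta=0.9, lam=0.0, phi=0.5)
        for seed in range(5):
            traj = simulate_event(SimulationSpec(event=ev, params=hot, rng_seed=seed))
            assert np.all(traj.y_sim[1:] <= 2 * np.asarray(ev.counts)[1:])

    def test_cumulative_monotone(self, event):
        ev, params = event
        traj = simulate_event(SimulationSpec(event=ev, params=params, rng_seed=1))
        assert np.all(np.diff(traj.cumulative) >= 0)

    def test_suppressed_growth_reduces_to_seed(self, event):
        ev, _ = event
        dead = ModelParams(alpha=-20.0, beta=0.0, delta=0.5, lam=0.1, phi=1.0)
        traj = simulate_event(SimulationSpec(event=ev, params=dead, rng_seed=2))
        assert traj.total == ev.bins[0].n_posts

    def test_removal_at_zero_freezes_at_seed(self, event):
        ev, params = event
        traj = simulate_event(
            SimulationSpec(
                event=ev, params=params, rng_seed=3,
                plan=PolicyPlan(removal_bin=0),
            )
        )
        assert traj.total == ev.bins[0].n_posts

    def test_beta_zero_total_matches_closed_form(self, pool):
        # with beta = 0 the mean total is y_1 + (T-1) exp(alpha); caps are
        # made non-binding by a huge multiplier
        rng = np.random.default_rng(8)
        params = ModelParams(alpha=1.0, beta=0.0, delta=0.5, lam=0.1, phi=5.0)
        ev, _ = gen_event(params, pool, T_bins=40, seed_size=15, rng=rng)
        T = len(ev.bins)
        expect = ev.bins[0].n_posts + (T - 1) * math.exp(1.0)
        n = 2000
        totals = [
            simulate_event(
                SimulationSpec(
                    event=ev, params=params, cap_multiplier=1e9, rng_seed=s
                ),
                cap_mode="event_max",
            ).total
            for s in range(n)
        ]
        mu = math.exp(1.0)
        se = math.sqrt((T - 1) * (mu + mu**2 / 5.0) / n)
        assert abs(np.mean(totals) - expect) < 3 * se

    def test_empty_poster_detail_rejected(self):
        from misinfosim.corpus import Bin, EventSeries

        ev = EventSeries(
            event_id="x/e1",
            incident_id="x",
            bins=[Bin(index=i + 1, n_posts=0, posters=None) for i in range(12)],
        )
        p = ModelParams(alpha=0, beta=0, delta=0.5, lam=0.1, phi=1)
        with pytest.raises(ValueError, match="poster detail"):
            simulate_event(SimulationSpec(event=ev, params=p, rng_seed=0))

    def test_observed_exposures_match_manual(self, event):
        ev, _ = event
        xs = observed_exposures(ev)
        manual = [
            log_sum_followers([f for _a, f in b.posters]) for b in ev.bins
        ]
        assert np.allclose(xs, manual, rtol=RTOL)
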