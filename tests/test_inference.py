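import numpy as np
import pytest

from misinfosim import ModelParams, check_inclusion, compute_rhat, fit_event
from misinfosim.inference import McmcConfig, posterior_predictive_totals
from misinfosim.model import PARAM_NAMES
from misinfosim.synthetic import SynthSpec, gen_accounts, gen_event

QUICK_MCMC = McmcConfig(n_walkers=24, n_steps=900, n_burn=300)


@pytest.fixture(scope="module")
def fitted():
    """One synthetic event at known parameters, fitted once for the module."""
    rng = np.random.default_rng(21)
    registry, _ = gen_accounts(SynthSpec(n_accounts=1200), rng)
    aids = np.array(sorted(registry.accounts))
    pool = (aids, np.array([registry[a].followers for a in aids]))
    true = ModelParams(alpha=-2.0, beta=0.3, delta=0.7, lam=0.05, phi=2.0)
    ev, _ = gen_event(true, pool, T_bins=144, seed_size=20, rng=rng)
    post = fit_event(ev, QUICK_MCMC, rng_seed=5)
    return ev, true, post


class TestRhat:
    def test_identical_chains_give_one(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal(500)
        # B = 0 leaves the (n-1)/n finite-sample factor: R-hat ~ 1 from below
        assert compute_rhat(np.tile(chain, (4, 1))) == pytest.approx(1.0, abs=5e-3)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack(
            [rng.normal(-10, 1, 500), rng.normal(10, 1, 500)]
        )
        assert compute_rhat(chains) > 5.0

    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((4, 20_000))
        assert compute_rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_single_chain_split_in_half(self):
        rng = np.random.default_rng(3)
        drifting = np.concatenate([rng.normal(0, 1, 400), rng.normal(8, 1, 400)])
        assert compute_rhat(drifting[None, :]) > 1.5

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(4)
        chains = rng.normal(0, 1, (4, 600)).cumsum(axis=1) * 0.01 + rng.standard_normal((4, 600))
        ours = compute_rhat(chains)
        theirs = float(az.rhat(chains[None].transpose(1, 2, 0)[:, :, 0]))
        # arviz default is rank-normalized; agreement is approximate
        assert ours == pytest.approx(theirs, abs=0.05)


class TestFit:
    def test_posterior_respects_supports(self, fitted):
        _, _, post = fitted
        flat = post.flat
        assert np.all((flat[:, 2] >= 0) & (flat[:, 2] <= 1))
        assert np.all(flat[:, 3] >= 0)
        assert np.all(flat[:, 4] > 0)

    def test_chains_converge_on_clean_event(self, fitted):
        _, _, post = fitted
        assert all(r < 1.1 for r in post.rhat.values())
        assert post.n_divergent == 0

    def test_true_parameters_inside_wide_posterior_interval(self, fitted):
        _, true, post = fitted
        flat = post.flat
        for i, name in enumerate(PARAM_NAMES):
            lo, hi = np.quantile(flat[:, i], [0.005, 0.995])
            assert lo <= getattr(true, name) <= hi, name

    def test_beta_zero_generation_recovers_null_effect(self):
        rng = np.random.default_rng(31)
        registry, _ = gen_accounts(SynthSpec(n_accounts=800), rng)
        aids = np.array(sorted(registry.accounts))
        pool = (aids, np.array([registry[a].followers for a in aids]))
        true = ModelParams(alpha=1.5, beta=0.0, delta=0.5, lam=0.05, phi=3.0)
        ev, _ = gen_event(true, pool, T_bins=96, seed_size=15, rng=rng)
        post = fit_event(ev, QUICK_MCMC, rng_seed=7)
        lo, hi = np.quantile(post.flat[:, 1], [0.055, 0.945])
        assert lo <= 0.0 <= hi

    def test_prior_predictive_totals_are_finite(self):
        # sampling the priors and simulating forward stays finite
        rng = np.random.default_rng(9)
        registry, _ = gen_accounts(SynthSpec(n_accounts=500), rng)
        aids = np.array(sorted(registry.accounts))
        pool = (aids, np.array([registry[a].followers for a in aids]))
        finite = 0
        n = 100
        for _ in range(n):
            params = ModelParams(
                alpha=rng.normal(-3, 3),
                beta=rng.normal(0, 3),
                delta=rng.beta(1, 1),
                lam=rng.exponential(1),
                phi=rng.exponential(1) + 1e-3,
            )
            ev, _ = gen_event(params, pool, T_bins=50, seed_size=10, rng=rng)
            finite += np.isfinite(ev.total_posts)
        assert finite >= 0.99 * n


class TestInclusion:
    def test_coverage_flag_from_predictive_interval(self, fitted):
        ev, _, post = fitted
        sims = np.full(100, float(ev.total_posts))
        assert check_inclusion(post, ev, sims).ci_covers_total

    def test_observed_outside_interval_excluded(self, fitted):
        ev, _, post = fitted
        sims = np.full(100, ev.total_posts * 10.0)
        report = check_inclusion(post, ev, sims)
        assert not report.ci_covers_total and not report.included

    def test_short_event_excluded(self, fitted):
        from misinfosim.corpus import Bin, EventSeries

        _, _, post = fitted
        short = EventSeries(
            event_id="s/e1",
            incident_id="s",
            bins=[Bin(index=i + 1, n_posts=1, posters=[("a", 1)]) for i in range(12)],
        )
        report = check_inclusion(post, short, np.full(50, 12.0))
        assert not report.long_enough and not report.included

    def test_posterior_predictive_covers_observed_total(self, fitted):
        ev, _, post = fitted
        sims = posterior_predictive_totals(post, ev, n_sims=150, rng_seed=3)
        report = check_inclusion(post, ev, sims)
        assert report.ci_covers_total
        assert report.included
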