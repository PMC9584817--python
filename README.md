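# misinfosim

Generative modelling of viral misinformation engagement and simulation of
platform interventions, alone and in combination.

When a false story goes viral on a microblogging platform, engagement (the
total posts — tweets, retweets, quote tweets, replies) grows explosively
for hours and then decays. Platforms and policymakers need to compare
candidate responses — removing content after a fact-checking delay,
suspending algorithmic amplification ("virality circuit breakers"),
accuracy nudges that make users share a little less, banning repeat
offenders — but experiments at platform scale are impractical and
ethically fraught. `misinfosim` is for computational social scientists and
trust-and-safety researchers who want to do this comparison with a
data-derived generative model: fit a branching-process model to observed
viral events, then re-simulate those events under counterfactual policies
and measure the reduction in total engagement.

## The model

Post counts in five-minute bins follow a latent-virality branching process
adapted from degree-based models of super-spreading in infectious disease:

```
E[y_t] = exp(α + β v_{t−1})                      t = 2…T
v_t    = v_{t−1} δ e^{−λt} + x_{t−1}             v_1 = x_1
x_t    = ln Σ_j (F_j + 1)                        over the bin-t posters
y_t    ~ NegBin2(μ_t, φ)                         Var = μ + μ²/φ
```

Virality `v_t` tracks accumulated audience exposure: every post adds the
log-sum of its author's followers `F_j` (out-degree), and decays through
the retention `δ` and lifetime decay `λ`. Counts are negative-binomial
(gamma–Poisson) with dispersion `φ`. There is no explicit network — the
empirical, time-varying follower-count distribution of each event's
posters carries the degree structure into the simulation.

The package provides the full pipeline around this model:

* `corpus` — data model and I/O for incidents, events, account registries
  (five-minute binning, delimited-text formats, YAML config);
* `segmentation` — peak/boundary/duration rules that cut viral events out
  of incident time series;
* `inference` — per-event Bayesian fitting (ensemble MCMC), split-R̂
  convergence diagnostics, and the four-part event inclusion rule;
* `model` — the recursion, the negative-binomial observation model, and
  the forward simulator with empirical follower resampling and a
  2×-observed runaway cap;
* `interventions` — declarative policies (removal, circuit breakers,
  nudges, ban lists, three-strikes rules) and their composition, with
  `modest_combined` / `aggressive_combined` presets;
* `experiment` — corpus-scale scenario runs: medians, equal-tailed 89%
  intervals, percent reductions versus baseline;
* `postevent` — a zero-intercept Bayesian log-normal regression linking
  event size to post-event engagement, and projection of
  intervention-adjusted post-event totals;
* `synthetic` — a generator of fully synthetic corpora (heavy-tailed
  follower counts, repeat offenders, planted events with ground truth) so
  everything is testable without platform data.

A `misinfosim` command-line tool exposes the stages as subcommands
(`synth`, `segment`, `fit`, `simulate`, `report`, `postevent`).

## Worked example

Generate a small synthetic corpus, segment it, fit each event, gate on the
inclusion rule, and compare two policies against baseline:

```python
from misinfosim import (SynthSpec, gen_corpus, segment_corpus, fit_event,
                        check_inclusion, run_scenario, percent_reduction)
from misinfosim.inference import McmcConfig, posterior_predictive_totals
from misinfosim.interventions import InterventionPolicy, RemovalSpec, NudgeSpec

spec = SynthSpec(n_incidents=6, events_per_incident=(1.0,), rng_seed=10)
incidents, registry, offenders, truth = gen_corpus(spec)
events, provenance = segment_corpus(incidents)
print(f"{len(events)} events from {len(incidents)} incidents")

mcmc = McmcConfig(n_walkers=24, n_steps=900, n_burn=300)
posteriors = {}
for i, ev in enumerate(events):
    post = fit_event(ev, mcmc, rng_seed=i)
    sims = posterior_predictive_totals(post, ev, n_sims=150, rng_seed=i)
    report = check_inclusion(post, ev, sims)
    print(f"{ev.event_id}: T={len(ev.bins)} observed={ev.total_posts} "
          f"included={report.included}")
    if report.included:
        posteriors[ev.event_id] = post

included = [ev for ev in events if ev.event_id in posteriors]
baseline = run_scenario(included, posteriors, None, n_runs=200, seed=0)
lo, hi = baseline.ci89
print(f"baseline: median={baseline.median:.0f} 89% CI=({lo:.0f}, {hi:.0f}) "
      f"observed={sum(e.total_posts for e in included)}")
for policy in [
    InterventionPolicy(policy_id="removal_30min", removal=RemovalSpec(delay_minutes=30)),
    InterventionPolicy(policy_id="nudge_10pct", nudge=NudgeSpec(eta=0.10)),
]:
    treated = run_scenario(included, posteriors, policy, n_runs=200, seed=0)
    red = percent_reduction(baseline, treated)
    print(f"{policy.policy_id}: median reduction {100*red.median_reduction:.1f}% "
          f"(89% CI {100*red.ci89[0]:.1f}% to {100*red.ci89[1]:.1f}%)")
```

Output (about two minutes on one CPU):

```
6 events from 6 incidents
inc000/e1: T=20 observed=52291 included=True
inc001/e1: T=13 observed=2442 included=True
inc002/e1: T=13 observed=421 included=True
inc003/e1: T=16 observed=42308 included=True
inc004/e1: T=19 observed=55137 included=True
inc005/e1: T=12 observed=753 included=False
baseline: median=114362 89% CI=(76621, 155563) observed=152599
removal_30min: median reduction 67.4% (89% CI 48.6% to 80.7%)
nudge_10pct: median reduction 2.7% (89% CI -31.0% to 35.2%)
```

Reading this: five of six events pass the inclusion rule (one lasts
exactly an hour and fails the duration criterion); the observed total of
the included events falls inside the 89% interval of the baseline
re-simulation (the retrodiction check); removing content 30 minutes into
each event cuts median engagement by two-thirds, while a 10% nudge alone
produces a small median reduction with a wide interval at this corpus
size — isolated weak interventions are noisy, which is what motivates the
combined presets.

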