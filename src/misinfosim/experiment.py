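"""Corpus-scale scenario simulation and aggregation.

A *scenario* runs the forward simulator over every included event many
times (500 by default) under one policy. Per run, one posterior sample is
drawn per event, each event is simulated, and cumulative engagement is
summed across events; medians and equal-tailed 89% intervals are taken over
the run totals. Percent reductions compare a treated scenario's run totals
against the baseline scenario's median.

Reproducibility contract: the master seed spawns per-(run, event) child
generators deterministically, with separate streams for policy enforcement
lotteries and for simulation noise, so results are independent of execution
order and identity-valued policies reproduce the baseline bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import EventSeries
from .inference import Posterior
from .interventions import (
    InterventionPolicy,
    StrikeLedger,
    compose_policy,
    resolve_ban_set,
)
from .model import SimulationSpec, prepare_event, simulate_event

logger = logging.getLogger(__name__)


@dataclass
class ScenarioResult:
    """Per-run corpus-total engagement distribution for one policy."""

    policy_id: str
    totals: np.ndarray  # (n_runs,)
    per_event_totals: np.ndarray  # (n_runs, n_events)
    event_ids: list[str]
    rng_seed: int
    skipped: list[str] = field(default_factory=list)

    @property
    def median(self) -> float:
        return float(np.median(self.totals))

    @property
    def ci89(self) -> tuple[float, float]:
        _, lo, hi = summarize_quantiles(self.totals)
        return (lo, hi)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_event_totals, columns=self.event_ids)
        df.insert(0, "run", np.arange(len(self.totals)))
        df.insert(1, "total", self.totals)
        return df


@dataclass
class ReductionSummary:
    """Median percent reduction of a treated scenario vs baseline."""

    policy_id: str
    median_reduction: float
    ci89: tuple[float, float]

    def __post_init__(self) -> None:
        if self.median_reduction > 1:
            raise ValueError("reduction cannot exceed 1")


def summarize_quantiles(values, level: float = 0.89) -> tuple[float, float, float]:
    """Median and equal-tailed percentile interval (linear interpolation)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    lo, med, hi = np.quantile(values, [tail, 0.5, 1.0 - tail])
    return float(med), float(lo), float(hi)


def run_scenario(
    events: list[EventSeries],
    posteriors: dict[str, Posterior],
    policy: InterventionPolicy | None = None,
    n_runs: int = 500,
    seed: int = 0,
    strike_ledger: StrikeLedger | None = None,
    cap_multiplier: float = 2.0,
    plus_one: str = "per_user",
) -> ScenarioResult:
    """Simulate the corpus ``n_runs`` times under one policy.

    Events without a usable posterior are skipped with a warning and listed
    in the result. Ban sets are resolved once per event (they depend on the
    event's start time, not on the run).
    """
    policy_id = policy.policy_id if policy is not None else "baseline"
    usable: list[tuple[EventSeries, Posterior, frozenset, list[np.ndarray]]] = []
    skipped = []
    for ev in events:
        post = posteriors.get(ev.event_id)
        if post is None or not post.ok:
            logger.warning("event %s: no posterior; skipped", ev.event_id)
            skipped.append(ev.event_id)
            continue
        ban_set = (
            resolve_ban_set(policy, ev, strike_ledger)
            if policy is not None
            else frozenset()
        )
        pools = prepare_event(ev, ban_set)
        usable.append((ev, post, ban_set, pools))
    n_events = len(usable)
    per_event = np.zeros((n_runs, n_events))
    for r in range(n_runs):
        for i, (ev, post, ban_set, pools) in enumerate(usable):
            sim_rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(0, r, i))
            )
            lottery_rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(1, r, i))
            )
            params = post.sample_params(sim_rng)
            plan = compose_policy(policy, lottery_rng, ban_set=ban_set)
            traj = simulate_event(
                SimulationSpec(
                    event=ev,
                    params=params,
                    cap_multiplier=cap_multiplier,
                    rng_seed=sim_rng,
                    plan=plan,
                ),
                follower_pools=pools,
                plus_one=plus_one,
            )
            per_event[r, i] = traj.total
    return ScenarioResult(
        policy_id=policy_id,
        totals=per_event.sum(axis=1),
        per_event_totals=per_event,
        event_ids=[ev.event_id for ev, *_ in usable],
        rng_seed=seed,
        skipped=skipped,
    )


def percent_reduction(
    baseline: ScenarioResult, treated: ScenarioResult
) -> ReductionSummary:
    """Per-run reductions 1 - treated_i / median(baseline), summarized.

    Requires matching run counts and event sets.
    """
    if len(baseline.totals) != len(treated.totals):
        raise ValueError("scenarios have different run counts")
    if baseline.event_ids != treated.event_ids:
        raise ValueError("scenarios cover different event sets")
    base_median = float(np.median(baseline.totals))
    if base_median == 0:
        raise ValueError("baseline median is zero")
    reductions = 1.0 - treated.totals / base_median
    med, lo, hi = summarize_quantiles(reductions)
    return ReductionSummary(
        policy_id=treated.policy_id, median_reduction=med, ci89=(lo, hi)
    )


def report_table(
    baseline: ScenarioResult, treated: list[ScenarioResult]
) -> pd.DataFrame:
    """Summary table: median totals, 89% CIs and reductions per policy."""
    rows = []
    for res in [baseline] + list(treated):
        med, lo, hi = summarize_quantiles(res.totals)
        row = {
            "policy_id": res.policy_id,
            "median_total": med,
            "ci_lo": lo,
            "ci_hi": hi,
        }
        if res is not baseline:
            red = percent_reduction(baseline, res)
            row["median_reduction"] = red.median_reduction
            row["red_lo"], row["red_hi"] = red.ci89
        else:
            row["median_reduction"] = 0.0
            row["red_lo"] = row["red_hi"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def plot_scenarios(results: list[ScenarioResult], ax=None):
    """Minimal violin plot of run-total distributions per policy."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 * len(results) + 2, 4))
    ax.violinplot([r.totals for r in results], showmedians=True)
    ax.set_xticks(range(1, len(results) + 1))
    ax.set_xticklabels([r.policy_id for r in results], rotation=30, ha="right")
    ax.set_ylabel("total posts per run")
    return ax
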