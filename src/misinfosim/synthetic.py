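"""Synthetic corpora with the statistical structure the pipeline assumes.

The generator emulates the features of an election-misinformation corpus
that the pipeline relies on, without any external data: heavy-tailed
follower counts spanning roughly 0 to 1e8 (a discretized log-normal with a
point mass of near-zero-follower accounts), verified flags concentrated on
high-follower accounts, repeat-offender accounts recurring across
incidents, per-bin poster pools whose composition shifts over an event's
lifetime (large accounts over-represented early), and engagement
trajectories simulated forward from the engagement model itself. Incidents
place one or two such events between quiescent stretches of low-level
background chatter (below the segmentation boundary threshold) so the
segmentation rules are exercised end to end.

Every generated corpus ships with a ground-truth ledger (true parameters,
planted event locations, totals, expected strike times derivable from the
corpus) sufficient to verify every downstream stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import AccountRecord, AccountRegistry, Bin, EventSeries, IncidentSeries
from .model import EXP_CAP, ModelParams, draw_posts, log_sum_followers


@dataclass
class SynthSpec:
    """Knobs of the synthetic corpus generator (defaults = study conditions).

    Follower counts: with probability ``zero_inflation`` a small Poisson(2)
    count, otherwise round(LogNormal(follower_mu_log, follower_sigma_log)),
    clipped at ``max_followers``. The default log-normal (median ~200,
    sigma 2.5 on the log scale) gives a 1e5-account registry a maximum
    follower count above 1e6 with high probability, spanning the eight
    orders of magnitude seen on real platforms.
    """

    n_incidents: int = 20
    events_per_incident: tuple[float, ...] = (0.8, 0.2)  # P(1 event), P(2), ...
    n_accounts: int = 4000
    accounts_per_incident: int = 400
    repeat_offender_fraction: float = 0.05
    verified_fraction: float = 0.02
    follower_mu_log: float = 5.3
    follower_sigma_log: float = 2.5
    zero_inflation: float = 0.2
    max_followers: int = 100_000_000
    alpha_range: tuple[float, float] = (-2.5, -1.5)
    beta_range: tuple[float, float] = (0.2, 0.32)
    delta_range: tuple[float, float] = (0.5, 0.85)
    lam_range: tuple[float, float] = (0.03, 0.10)
    phi_range: tuple[float, float] = (1.5, 3.0)
    T_bins: int = 48
    seed_size_range: tuple[int, int] = (10, 30)
    background_rel: float = 0.02  # chatter rate as fraction of planted peak
    gap_bins: int = 18
    per_bin_ceiling: int = 5000
    early_bias: float = 0.5  # exponent tilting early bins to big accounts
    ensure_viral: bool = True  # redraw events until they qualify as viral
    max_event_attempts: int = 30
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("repeat_offender_fraction", "verified_fraction",
                     "zero_inflation", "background_rel"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.events_per_incident) - 1.0) > 1e-9:
            raise ValueError("events_per_incident must sum to 1")
        if not (0 <= self.delta_range[0] <= self.delta_range[1] <= 1):
            raise ValueError("delta_range outside [0, 1]")
        if self.lam_range[0] < 0 or self.phi_range[0] <= 0:
            raise ValueError("parameter ranges outside supports")
        if self.T_bins < 12:
            raise ValueError("T_bins must be >= 12 (one hour)")


def gen_accounts(
    spec: SynthSpec, rng: np.random.Generator
) -> tuple[AccountRegistry, frozenset]:
    """Generate the account registry; returns (registry, repeat-offender ids).

    Verified flags are assigned preferentially to high-follower accounts
    (sampling without replacement with probability proportional to
    log10(F + 10)).
    """
    n = spec.n_accounts
    is_small = rng.random(n) < spec.zero_inflation
    followers = np.where(
        is_small,
        rng.poisson(2.0, size=n),
        np.round(
            rng.lognormal(spec.follower_mu_log, spec.follower_sigma_log, size=n)
        ),
    ).astype(np.int64)
    followers = np.minimum(followers, spec.max_followers)
    n_verified = int(round(spec.verified_fraction * n))
    verified = np.zeros(n, dtype=bool)
    if n_verified:
        w = np.log10(followers + 10.0)
        verified[
            rng.choice(n, size=n_verified, replace=False, p=w / w.sum())
        ] = True
    n_offenders = int(round(spec.repeat_offender_fraction * n))
    offenders = frozenset(
        f"a{j:06d}" for j in rng.choice(n, size=n_offenders, replace=False)
    ) if n_offenders else frozenset()
    registry = AccountRegistry()
    for j in range(n):
        registry.add(
            AccountRecord(
                account_id=f"a{j:06d}",
                followers=int(followers[j]),
                verified=bool(verified[j]),
            )
        )
    return registry, offenders


def _sample_posters(
    aids: np.ndarray,
    followers: np.ndarray,
    k: int,
    t: int,
    T: int,
    early_bias: float,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Draw k posters; early bins tilt toward high-follower accounts."""
    if k == 0 or len(aids) == 0:
        return []
    tilt = early_bias * max(0.0, 1.0 - (t - 1) / (0.25 * T + 1))
    w = (followers + 1.0) ** tilt
    p = w / w.sum()
    idx = rng.choice(len(aids), size=k, replace=True, p=p)
    return [(str(aids[i]), int(followers[i])) for i in idx]


def gen_event(
    params: ModelParams,
    pool: tuple[np.ndarray, np.ndarray],
    T_bins: int,
    seed_size: int,
    rng: np.random.Generator,
    spec: SynthSpec | None = None,
    event_id: str = "synthetic/e1",
    incident_id: str = "synthetic",
) -> tuple[EventSeries, dict]:
    """Simulate one event forward from the generative model.

    ``pool`` is (account_ids, follower_counts) for the incident. Every post
    is attributed to a sampled account; an absolute per-bin ceiling guards
    against runaway and is recorded in the returned provenance dict.
    """
    spec = spec or SynthSpec()
    aids, followers = pool
    ceiling = spec.per_bin_ceiling
    bins: list[Bin] = []
    posters = _sample_posters(
        aids, followers, seed_size, 1, T_bins, spec.early_bias, rng
    )
    bins.append(Bin(index=1, n_posts=len(posters), posters=posters))
    x_prev = log_sum_followers([f for _a, f in posters])
    v = x_prev
    ceiling_hit = 0
    for t in range(2, T_bins + 1):
        eta = min(params.alpha + params.beta * v, EXP_CAP)
        y_t = draw_posts(max(math.exp(eta), 1e-300), params.phi, rng)
        if y_t > ceiling:
            y_t = ceiling
            ceiling_hit += 1
        posters = _sample_posters(
            aids, followers, y_t, t, T_bins, spec.early_bias, rng
        )
        bins.append(Bin(index=t, n_posts=len(posters), posters=posters))
        x_t = log_sum_followers([f for _a, f in posters])
        v = v * params.delta * math.exp(-params.lam * t) + x_prev
        x_prev = x_t
    event = EventSeries(
        event_id=event_id, incident_id=incident_id, bins=bins
    )
    provenance = {
        "ceiling": ceiling,
        "ceiling_hit_bins": ceiling_hit,
        "seed_size": seed_size,
        **{k: getattr(params, k) for k in ("alpha", "beta", "delta", "lam", "phi")},
    }
    return event, provenance


def viral_span(counts, frac: float = 0.05) -> int:
    """Length of the would-be segmented span around the largest peak.

    Counts the bins between (and including) the first bins on either side
    of the peak that fall below ``frac`` of the peak height — the span the
    boundary rule would cut for this burst in isolation.
    """
    counts = np.asarray(counts, dtype=float)
    p = int(np.argmax(counts))
    thresh = frac * counts[p]
    left = 0
    for j in range(p - 1, -1, -1):
        if counts[j] < thresh:
            left = j
            break
    right = len(counts) - 1
    for j in range(p + 1, len(counts)):
        if counts[j] < thresh:
            right = j
            break
    return right - left + 1


def _draw_params(spec: SynthSpec, rng: np.random.Generator) -> ModelParams:
    return ModelParams(
        alpha=rng.uniform(*spec.alpha_range),
        beta=rng.uniform(*spec.beta_range),
        delta=rng.uniform(*spec.delta_range),
        lam=rng.uniform(*spec.lam_range),
        phi=rng.uniform(*spec.phi_range),
    )


def gen_corpus(
    spec: SynthSpec, rng: np.random.Generator | int | None = None
) -> tuple[list[IncidentSeries], AccountRegistry, frozenset, pd.DataFrame]:
    """Assemble a full synthetic corpus with a ground-truth ledger.

    Returns (incidents, registry, repeat_offender_ids, truth). Each incident
    holds one or more planted events separated by quiescent gaps of
    low-level background chatter (rate ``background_rel`` of the planted
    peak, kept below the segmentation boundary threshold by default).
    Incidents start a day apart so strike times are orderable. ``truth``
    has one row per planted event: location, true parameters and totals.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(spec.rng_seed if rng is None else rng)
    registry, offenders = gen_accounts(spec, rng)
    all_aids = np.array(sorted(registry.accounts.keys()))
    offender_mask = np.isin(all_aids, sorted(offenders))
    regular = all_aids[~offender_mask]
    rng.shuffle(regular)
    offender_arr = all_aids[offender_mask]
    followers_of = {a: registry[a].followers for a in all_aids}

    incidents: list[IncidentSeries] = []
    truth_rows = []
    t0 = 1_600_000_000.0
    n_regular = len(regular)
    per_inc = min(spec.accounts_per_incident, max(1, n_regular // max(spec.n_incidents, 1)))
    for k in range(spec.n_incidents):
        iid = f"inc{k:03d}"
        start_time = t0 + k * 86_400.0
        lo = (k * per_inc) % max(n_regular, 1)
        own = regular[lo : lo + per_inc]
        if spec.repeat_offender_fraction > 0 and len(offender_arr):
            take = offender_arr[rng.random(len(offender_arr)) < 0.8]
            pool_aids = np.concatenate([own, take])
        else:
            pool_aids = own
        pool = (
            pool_aids,
            np.array([followers_of[a] for a in pool_aids], dtype=np.int64),
        )
        n_events = 1 + int(
            rng.choice(len(spec.events_per_incident), p=spec.events_per_incident)
        )
        bins: list[Bin] = []
        cursor = 0
        planted = []
        for e in range(n_events):
            gap = spec.gap_bins + int(rng.integers(0, 7))
            attempts = spec.max_event_attempts if spec.ensure_viral else 1
            for _attempt in range(attempts):
                params = _draw_params(spec, rng)
                seed_size = int(rng.integers(*spec.seed_size_range))
                event, prov = gen_event(
                    params,
                    pool,
                    spec.T_bins,
                    seed_size,
                    rng,
                    spec=spec,
                    event_id=f"{iid}/planted{e + 1}",
                    incident_id=iid,
                )
                qualified = viral_span(event.counts) >= 12
                if qualified or not spec.ensure_viral:
                    break
            peak = max(b.n_posts for b in event.bins)
            bg_rate = spec.background_rel * peak
            for _ in range(gap):
                cursor += 1
                y_bg = int(rng.poisson(bg_rate))
                y_bg = min(y_bg, max(int(0.04 * peak), 0))
                posters = _sample_posters(
                    pool[0], pool[1], y_bg, 1, spec.T_bins, 0.0, rng
                )
                bins.append(Bin(index=cursor, n_posts=y_bg, posters=posters))
            start_bin = cursor + 1
            peak_offset = int(np.argmax([b.n_posts for b in event.bins]))
            for b in event.bins:
                cursor += 1
                bins.append(Bin(index=cursor, n_posts=b.n_posts, posters=b.posters))
            planted.append(
                {
                    "incident_id": iid,
                    "event_index": e + 1,
                    "start_bin": start_bin,
                    "end_bin": cursor,
                    "peak_bin": start_bin + peak_offset,
                    "peak_volume": peak,
                    "total_posts": sum(b.n_posts for b in event.bins),
                    "seed_size": seed_size,
                    **{
                        name: getattr(params, name)
                        for name in ("alpha", "beta", "delta", "lam", "phi")
                    },
                    "ceiling_hit_bins": prov["ceiling_hit_bins"],
                    "seg_qualified": qualified,
                }
            )
        # trailing quiescence
        for _ in range(spec.gap_bins):
            cursor += 1
            bins.append(Bin(index=cursor, n_posts=0, posters=[]))
        incidents.append(
            IncidentSeries(incident_id=iid, start_time=start_time, bins=bins)
        )
        truth_rows.extend(planted)
    truth = pd.DataFrame(truth_rows)
    # registry memberships reflect actual posting
    for inc in incidents:
        for b in inc.bins:
            for aid, f in b.posters or []:
                registry.record_post(aid, f, inc.incident_id)
    return incidents, registry, offenders, truth


def gen_postevent_pairs(
    beta: float,
    sigma: float,
    n: int,
    rng: np.random.Generator,
    x_mu_log: float = 7.0,
    x_sigma_log: float = 1.5,
) -> pd.DataFrame:
    """Synthetic (event, post-event) engagement pairs from the regression.

    x ~ LogNormal(x_mu_log, x_sigma_log); y ~ LogNormal(beta ln x, sigma).
    """
    x = rng.lognormal(x_mu_log, x_sigma_log, size=n)
    y = np.exp(beta * np.log(x) + sigma * rng.standard_normal(n))
    return pd.DataFrame(
        {
            "incident_id": [f"inc{i:03d}" for i in range(n)],
            "event_engagement": x,
            "post_event_engagement": y,
        }
    )
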