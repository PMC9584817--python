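"""Data model and I/O for incident/event time series and account registries.

An *incident* is a distinct misleading story with a full collection-window
time series of post counts in five-minute bins; an *event* is a contiguous
viral episode segmented out of an incident. Each bin optionally carries the
multiset of posting accounts with their follower counts at post time, which
downstream stages use as empirical exposure pools.

Follower counts are stored per (account, bin) so follower growth over an
event is representable; the registry keeps the most recent value. Timestamps
are UTC epoch seconds. Bins are half-open, left-closed, with 1-based indices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

#: Default bin width in seconds (five minutes).
BIN_WIDTH = 300.0


class CorpusError(ValueError):
    """Schema or invariant violation in corpus data, with file/line context."""


@dataclass
class AccountRecord:
    """A platform account: opaque id, follower count (out-degree), flags."""

    account_id: str
    followers: int
    verified: bool = False
    banned: bool = False

    def __post_init__(self) -> None:
        if self.followers < 0:
            raise CorpusError(
                f"account {self.account_id!r}: negative follower count "
                f"{self.followers}"
            )


class AccountRegistry:
    """Accounts keyed by id, plus which incidents each account posted in."""

    def __init__(self) -> None:
        self.accounts: dict[str, AccountRecord] = {}
        self.memberships: dict[str, set[str]] = {}

    def add(self, record: AccountRecord) -> None:
        self.accounts[record.account_id] = record

    def record_post(self, account_id: str, followers: int, incident_id: str) -> None:
        """Register a post: update latest follower count and membership."""
        rec = self.accounts.get(account_id)
        if rec is None:
            self.accounts[account_id] = AccountRecord(account_id, followers)
        else:
            rec.followers = followers
        self.memberships.setdefault(account_id, set()).add(incident_id)

    def incidents_of(self, account_id: str) -> set[str]:
        return self.memberships.get(account_id, set())

    def __len__(self) -> int:
        return len(self.accounts)

    def __contains__(self, account_id: str) -> bool:
        return account_id in self.accounts

    def __getitem__(self, account_id: str) -> AccountRecord:
        return self.accounts[account_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AccountRegistry):
            return NotImplemented
        return self.accounts == other.accounts and self.memberships == other.memberships


@dataclass
class Bin:
    """One five-minute bin: 1-based index, post count y_t, poster multiset.

    ``posters`` is a list of ``(account_id, followers_at_post_time)`` pairs;
    ``None`` means poster detail is unavailable for this bin.
    """

    index: int
    n_posts: int
    posters: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise CorpusError(f"bin index must be >= 1, got {self.index}")
        if self.n_posts < 0:
            raise CorpusError(f"bin {self.index}: negative post count {self.n_posts}")
        if self.posters is not None:
            if len(self.posters) != self.n_posts:
                raise CorpusError(
                    f"bin {self.index}: n_posts={self.n_posts} but "
                    f"{len(self.posters)} poster records"
                )
            for aid, f in self.posters:
                if f < 0:
                    raise CorpusError(
                        f"bin {self.index}: account {aid!r} has negative "
                        f"follower count {f}"
                    )


def _check_contiguous(bins: list[Bin], label: str) -> None:
    for prev, cur in zip(bins, bins[1:]):
        if cur.index != prev.index + 1:
            raise CorpusError(
                f"{label}: bin indices not contiguous "
                f"({prev.index} followed by {cur.index})"
            )


@dataclass
class IncidentSeries:
    """A named incident's full binned time series over its collection window."""

    incident_id: str
    start_time: float
    bins: list[Bin]

    def __post_init__(self) -> None:
        if self.bins and self.bins[0].index != 1:
            raise CorpusError(
                f"incident {self.incident_id!r}: first bin index must be 1"
            )
        _check_contiguous(self.bins, f"incident {self.incident_id!r}")

    @property
    def counts(self) -> list[int]:
        return [b.n_posts for b in self.bins]


@dataclass
class EventSeries:
    """A contiguous viral episode cut from an incident, re-indexed to t = 1.

    ``start_bin``/``end_bin`` record where the event sat inside the parent
    incident (1-based, inclusive); ``start_time`` is the epoch time of the
    first event bin, used for strike/ban timing.
    """

    event_id: str
    incident_id: str
    bins: list[Bin]
    start_bin: int = 1
    end_bin: int = 0
    start_time: float = 0.0
    peak_volume: int = field(default=0)

    def __post_init__(self) -> None:
        if len(self.bins) < 12:
            raise CorpusError(
                f"event {self.event_id!r}: events must span >= 12 bins "
                f"(one hour), got {len(self.bins)}"
            )
        if self.bins[0].index != 1:
            raise CorpusError(f"event {self.event_id!r}: first bin must have t=1")
        _check_contiguous(self.bins, f"event {self.event_id!r}")
        if self.end_bin == 0:
            self.end_bin = self.start_bin + len(self.bins) - 1
        peak = max(b.n_posts for b in self.bins)
        if self.peak_volume == 0:
            self.peak_volume = peak
        elif self.peak_volume != peak:
            raise CorpusError(
                f"event {self.event_id!r}: peak_volume={self.peak_volume} "
                f"but max bin count is {peak}"
            )

    @property
    def counts(self) -> list[int]:
        return [b.n_posts for b in self.bins]

    @property
    def total_posts(self) -> int:
        return sum(b.n_posts for b in self.bins)


def bin_posts(
    posts: list[tuple[float, str, int]],
    start: float,
    width: float = BIN_WIDTH,
    end: float | None = None,
    incident_id: str = "incident",
) -> IncidentSeries:
    """Aggregate raw posts into a contiguous, half-open binned series.

    Parameters
    ----------
    posts
        ``(timestamp, account_id, followers)`` triples; order is irrelevant
        (sorted internally). Timestamps must be >= ``start``.
    start
        Window start (epoch seconds). Post with timestamp ``ts`` lands in the
        1-based bin ``floor((ts - start)/width) + 1``, i.e. bins are
        ``[start + (t-1)*width, start + t*width)``.
    width
        Bin width in seconds; default five minutes.
    end
        Window end; bins are materialized (empty ones included) up to the
        bin containing ``end`` (exclusive at an exact bin edge). Defaults to
        just past the latest post.
    """
    if width <= 0:
        raise CorpusError(f"bin width must be positive, got {width}")
    for ts, aid, f in posts:
        if ts < start:
            raise CorpusError(f"post at {ts} precedes window start {start}")
        if f < 0:
            raise CorpusError(f"account {aid!r}: negative follower count {f}")
    ordered = sorted(posts, key=lambda p: p[0])
    if end is None:
        end = (ordered[-1][0] + width) if ordered else start + width
    if end <= start:
        raise CorpusError("window end must be after start")
    n_bins = max(1, math.ceil((end - start) / width))
    posters: list[list[tuple[str, int]]] = [[] for _ in range(n_bins)]
    for ts, aid, f in ordered:
        t = int((ts - start) // width)
        if t >= n_bins:
            raise CorpusError(f"post at {ts} falls outside window end {end}")
        posters[t].append((aid, f))
    bins = [
        Bin(index=i + 1, n_posts=len(p), posters=p) for i, p in enumerate(posters)
    ]
    return IncidentSeries(incident_id=incident_id, start_time=start, bins=bins)


# ---------------------------------------------------------------------------
# Serialization
#
# Layout of a corpus directory:
#   accounts.csv           account_id,followers,verified,banned
#   incidents.csv          incident_id,start_time,n_bins
#   series/<iid>.csv       bin_index,timestamp,n_posts
#   posters/<iid>.jsonl    {"bin_index": t, "account_id": a, "followers": f}
# ---------------------------------------------------------------------------


def write_corpus(
    corpus: list[IncidentSeries],
    path: str | Path,
    registry: AccountRegistry | None = None,
    width: float = BIN_WIDTH,
) -> None:
    """Write a corpus directory with deterministic (sorted) ordering."""
    path = Path(path)
    (path / "series").mkdir(parents=True, exist_ok=True)
    (path / "posters").mkdir(parents=True, exist_ok=True)
    if registry is None:
        registry = build_registry(corpus)
    acc_rows = [
        {
            "account_id": r.account_id,
            "followers": r.followers,
            "verified": r.verified,
            "banned": r.banned,
        }
        for r in sorted(registry.accounts.values(), key=lambda r: r.account_id)
    ]
    pd.DataFrame(
        acc_rows, columns=["account_id", "followers", "verified", "banned"]
    ).to_csv(path / "accounts.csv", index=False)

    inc_rows = []
    for inc in sorted(corpus, key=lambda s: s.incident_id):
        inc_rows.append(
            {
                "incident_id": inc.incident_id,
                "start_time": inc.start_time,
                "n_bins": len(inc.bins),
            }
        )
        series = pd.DataFrame(
            {
                "bin_index": [b.index for b in inc.bins],
                "timestamp": [
                    inc.start_time + (b.index - 1) * width for b in inc.bins
                ],
                "n_posts": [b.n_posts for b in inc.bins],
            }
        )
        series.to_csv(path / "series" / f"{inc.incident_id}.csv", index=False)
        with open(path / "posters" / f"{inc.incident_id}.jsonl", "w") as fh:
            for b in inc.bins:
                for aid, f in b.posters or []:
                    fh.write(
                        json.dumps(
                            {
                                "bin_index": b.index,
                                "account_id": aid,
                                "followers": int(f),
                            }
                        )
                        + "\n"
                    )
    pd.DataFrame(inc_rows, columns=["incident_id", "start_time", "n_bins"]).to_csv(
        path / "incidents.csv", index=False
    )


def read_corpus(path: str | Path) -> tuple[list[IncidentSeries], AccountRegistry]:
    """Read a corpus directory written by :func:`write_corpus`.

    Returns the incidents (sorted by id) and the account registry with
    incident memberships rebuilt from the poster files. Schema violations
    raise :class:`CorpusError` with file context.
    """
    path = Path(path)
    registry = AccountRegistry()
    acc_file = path / "accounts.csv"
    if acc_file.exists():
        acc = pd.read_csv(acc_file, dtype={"account_id": str})
        for i, row in enumerate(acc.itertuples(index=False), start=2):
            try:
                registry.add(
                    AccountRecord(
                        account_id=str(row.account_id),
                        followers=int(row.followers),
                        verified=bool(row.verified),
                        banned=bool(row.banned),
                    )
                )
            except (CorpusError, ValueError) as exc:
                raise CorpusError(f"{acc_file}:{i}: {exc}") from exc

    incidents: list[IncidentSeries] = []
    inc_file = path / "incidents.csv"
    if not inc_file.exists():
        return incidents, registry
    inc_table = pd.read_csv(inc_file, dtype={"incident_id": str})
    for row in inc_table.itertuples(index=False):
        iid = str(row.incident_id)
        series_file = path / "series" / f"{iid}.csv"
        posters_file = path / "posters" / f"{iid}.jsonl"
        series = pd.read_csv(series_file)
        per_bin: dict[int, list[tuple[str, int]]] = {
            int(t): [] for t in series["bin_index"]
        }
        if posters_file.exists():
            with open(posters_file) as fh:
                for lineno, line in enumerate(fh, start=1):
                    try:
                        rec = json.loads(line)
                        t = int(rec["bin_index"])
                        per_bin[t].append(
                            (str(rec["account_id"]), int(rec["followers"]))
                        )
                    except (KeyError, ValueError, json.JSONDecodeError) as exc:
                        raise CorpusError(
                            f"{posters_file}:{lineno}: bad poster record: {exc}"
                        ) from exc
        bins = []
        for i, srow in enumerate(series.itertuples(index=False), start=2):
            t = int(srow.bin_index)
            try:
                bins.append(
                    Bin(index=t, n_posts=int(srow.n_posts), posters=per_bin[t])
                )
            except CorpusError as exc:
                raise CorpusError(f"{series_file}:{i}: {exc}") from exc
        try:
            inc = IncidentSeries(
                incident_id=iid, start_time=float(row.start_time), bins=bins
            )
        except CorpusError as exc:
            raise CorpusError(f"{series_file}: {exc}") from exc
        incidents.append(inc)
        for b in bins:
            for aid, f in b.posters or []:
                registry.record_post(aid, f, iid)
    # re-apply registry follower/flag values as authoritative
    if acc_file.exists():
        acc = pd.read_csv(acc_file, dtype={"account_id": str})
        for row in acc.itertuples(index=False):
            registry.add(
                AccountRecord(
                    account_id=str(row.account_id),
                    followers=int(row.followers),
                    verified=bool(row.verified),
                    banned=bool(row.banned),
                )
            )
    return incidents, registry


def build_registry(corpus: list[IncidentSeries]) -> AccountRegistry:
    """Derive a registry (latest follower values, memberships) from a corpus."""
    registry = AccountRegistry()
    for inc in corpus:
        for b in inc.bins:
            for aid, f in b.posters or []:
                registry.record_post(aid, f, inc.incident_id)
    return registry


def _safe_name(event_id: str) -> str:
    return event_id.replace("/", "__")


def write_events(events: list[EventSeries], path: str | Path) -> None:
    """Write segmented events: an index table plus per-event file pairs."""
    path = Path(path)
    (path / "series").mkdir(parents=True, exist_ok=True)
    (path / "posters").mkdir(parents=True, exist_ok=True)
    rows = []
    for ev in sorted(events, key=lambda e: e.event_id):
        rows.append(
            {
                "event_id": ev.event_id,
                "incident_id": ev.incident_id,
                "start_bin": ev.start_bin,
                "end_bin": ev.end_bin,
                "start_time": ev.start_time,
                "peak_volume": ev.peak_volume,
            }
        )
        name = _safe_name(ev.event_id)
        pd.DataFrame(
            {
                "bin_index": [b.index for b in ev.bins],
                "n_posts": [b.n_posts for b in ev.bins],
            }
        ).to_csv(path / "series" / f"{name}.csv", index=False)
        with open(path / "posters" / f"{name}.jsonl", "w") as fh:
            for b in ev.bins:
                for aid, f in b.posters or []:
                    fh.write(
                        json.dumps(
                            {
                                "bin_index": b.index,
                                "account_id": aid,
                                "followers": int(f),
                            }
                        )
                        + "\n"
                    )
    pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "incident_id",
            "start_bin",
            "end_bin",
            "start_time",
            "peak_volume",
        ],
    ).to_csv(path / "events.csv", index=False)


def read_events(path: str | Path) -> list[EventSeries]:
    """Read events written by :func:`write_events`."""
    path = Path(path)
    table = pd.read_csv(path / "events.csv", dtype={"event_id": str})
    events = []
    for row in table.itertuples(index=False):
        name = _safe_name(str(row.event_id))
        series = pd.read_csv(path / "series" / f"{name}.csv")
        per_bin: dict[int, list[tuple[str, int]]] = {
            int(t): [] for t in series["bin_index"]
        }
        posters_file = path / "posters" / f"{name}.jsonl"
        if posters_file.exists():
            with open(posters_file) as fh:
                for lineno, line in enumerate(fh, start=1):
                    try:
                        rec = json.loads(line)
                        per_bin[int(rec["bin_index"])].append(
                            (str(rec["account_id"]), int(rec["followers"]))
                        )
                    except (KeyError, ValueError, json.JSONDecodeError) as exc:
                        raise CorpusError(
                            f"{posters_file}:{lineno}: bad poster record: {exc}"
                        ) from exc
        bins = [
            Bin(
                index=int(srow.bin_index),
                n_posts=int(srow.n_posts),
                posters=per_bin[int(srow.bin_index)],
            )
            for srow in series.itertuples(index=False)
        ]
        events.append(
            EventSeries(
                event_id=str(row.event_id),
                incident_id=str(row.incident_id),
                bins=bins,
                start_bin=int(row.start_bin),
                end_bin=int(row.end_bin),
                start_time=float(row.start_time),
            )
        )
    return events


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_CONFIG_SECTIONS = {
    "segmentation": {
        "peak_rel_threshold": float,
        "boundary_rel_threshold": float,
        "min_bins": int,
        "boundary_anchor": str,
    },
    "mcmc": {
        "n_walkers": int,
        "n_steps": int,
        "n_burn": int,
        "n_chains": int,
        "thin": int,
    },
    "simulation": {
        "cap_multiplier": float,
        "cap_mode": str,
        "n_runs": int,
        "exposure_plus_one": str,
    },
    "policy": dict,  # validated by interventions.InterventionPolicy.from_dict
    "synth": dict,  # validated by synthetic.SynthSpec
}


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML config file against the documented schema.

    Top-level sections: ``segmentation``, ``mcmc``, ``simulation``,
    ``policy``, ``synth``. Unknown sections or keys raise
    :class:`CorpusError`; values are coerced to the schema type.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise CorpusError(f"{path}: config root must be a mapping")
    out: dict = {}
    for section, content in raw.items():
        if section not in _CONFIG_SECTIONS:
            raise CorpusError(f"{path}: unknown config section {section!r}")
        schema = _CONFIG_SECTIONS[section]
        if schema is dict:
            if not isinstance(content, dict):
                raise CorpusError(f"{path}: section {section!r} must be a mapping")
            out[section] = content
            continue
        out[section] = {}
        for key, value in (content or {}).items():
            if key not in schema:
                raise CorpusError(f"{path}: unknown key {section}.{key}")
            try:
                out[section][key] = schema[key](value)
            except (TypeError, ValueError) as exc:
                raise CorpusError(f"{path}: bad value for {section}.{key}") from exc
    return out
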