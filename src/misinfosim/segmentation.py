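"""Segmentation of viral events from incident time series.

Events are periods of rapid growth and decay bracketed by quiescence. The
rules: find the global maximum of the incident series; any bin reaching at
least 30% of that maximum qualifies as a peak (filters noise). Starting
with the largest peak, the event's boundaries are the nearest bins before
and after the peak where the count drops below 5% of the peak height; if no
such bin exists within the collection window the first (last) bin is used.
Peaks with no quiescent gap between them merge into one event. The process
repeats for remaining peaks not already absorbed. Events shorter than one
hour (12 five-minute bins) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import BIN_WIDTH, Bin, EventSeries, IncidentSeries


@dataclass
class SegmentationConfig:
    """Thresholds for event extraction.

    peak_rel_threshold
        A bin qualifies as an event peak if its count is at least this
        fraction of the incident's global maximum (default 0.30).
    boundary_rel_threshold
        Event boundaries are the nearest bins with counts below this
        fraction of the anchoring peak height (default 0.05).
    min_bins
        Minimum event duration in bins (default 12, i.e. one hour).
    boundary_anchor
        ``"peak"`` (default) anchors the 5% rule to the height of the peak
        being processed; ``"global"`` anchors it to the incident maximum.
    """

    peak_rel_threshold: float = 0.30
    boundary_rel_threshold: float = 0.05
    min_bins: int = 12
    boundary_anchor: str = "peak"

    def __post_init__(self) -> None:
        if not (0 < self.boundary_rel_threshold < self.peak_rel_threshold <= 1):
            raise ValueError(
                "need 0 < boundary_rel_threshold < peak_rel_threshold <= 1"
            )
        if self.min_bins < 1:
            raise ValueError("min_bins must be >= 1")
        if self.boundary_anchor not in ("peak", "global"):
            raise ValueError("boundary_anchor must be 'peak' or 'global'")


def find_global_peak(series: IncidentSeries) -> int | None:
    """Return the 1-based index of the largest bin, or None if all-zero.

    Ties are broken by the earliest bin.
    """
    if not series.bins:
        raise ValueError("empty series")
    counts = np.asarray(series.counts)
    if counts.max() == 0:
        return None
    return int(np.argmax(counts)) + 1


def segment_events(
    series: IncidentSeries,
    cfg: SegmentationConfig | None = None,
) -> list[EventSeries]:
    """Extract viral events from one incident series.

    Qualifying peaks are processed in descending height (ties: earliest
    first); each claims the contiguous span out to the first sub-threshold
    bin on either side (those boundary bins included). Bins already claimed
    are never re-used: a later peak inside a claimed span is absorbed, and
    a boundary scan stops at the edge of a claimed span.
    """
    cfg = cfg or SegmentationConfig()
    counts = np.asarray(series.counts, dtype=float)
    n = len(counts)
    if n == 0 or counts.max() == 0:
        return []
    global_max = counts.max()
    peak_floor = cfg.peak_rel_threshold * global_max
    order = sorted(
        (i for i in range(n) if counts[i] >= peak_floor),
        key=lambda i: (-counts[i], i),
    )
    taken = np.zeros(n, dtype=bool)
    spans: list[tuple[int, int, int]] = []  # (left, right, peak_idx) 0-based
    for p in order:
        if taken[p]:
            continue
        anchor = counts[p] if cfg.boundary_anchor == "peak" else global_max
        thresh = cfg.boundary_rel_threshold * anchor
        left = 0
        for j in range(p - 1, -1, -1):
            if taken[j]:
                left = j + 1
                break
            if counts[j] < thresh:
                left = j
                break
        right = n - 1
        for j in range(p + 1, n):
            if taken[j]:
                right = j - 1
                break
            if counts[j] < thresh:
                right = j
                break
        taken[left : right + 1] = True
        if right - left + 1 >= cfg.min_bins:
            spans.append((left, right, p))

    events = []
    for k, (left, right, _p) in enumerate(sorted(spans), start=1):
        bins = [
            Bin(index=i + 1, n_posts=b.n_posts, posters=b.posters)
            for i, b in enumerate(series.bins[left : right + 1])
        ]
        events.append(
            EventSeries(
                event_id=f"{series.incident_id}/e{k}",
                incident_id=series.incident_id,
                bins=bins,
                start_bin=left + 1,
                end_bin=right + 1,
                start_time=series.start_time + left * BIN_WIDTH,
            )
        )
    return events


def segment_corpus(
    corpus: list[IncidentSeries],
    cfg: SegmentationConfig | None = None,
) -> tuple[list[EventSeries], pd.DataFrame]:
    """Apply :func:`segment_events` to every incident.

    Returns all events plus a provenance table with columns
    ``event_id, incident_id, start_bin, end_bin, peak_volume`` preserving
    the incident linkage needed for strike counting.
    """
    events: list[EventSeries] = []
    rows = []
    for inc in corpus:
        for ev in segment_events(inc, cfg):
            events.append(ev)
            rows.append(
                {
                    "event_id": ev.event_id,
                    "incident_id": ev.incident_id,
                    "start_bin": ev.start_bin,
                    "end_bin": ev.end_bin,
                    "peak_volume": ev.peak_volume,
                }
            )
    table = pd.DataFrame(
        rows, columns=["event_id", "incident_id", "start_bin", "end_bin", "peak_volume"]
    )
    return events, table
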