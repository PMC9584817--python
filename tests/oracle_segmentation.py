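"""Brute-force reference segmenter, independent of the package internals.

Implements the event-extraction rules by exhaustive scanning over plain
Python lists and index sets, with none of the package's vectorization or
early-exit structure: every pass re-derives the set of unclaimed qualifying
peaks from scratch, picks the highest (earliest on ties), walks outward one
bin at a time to find the boundaries, and repeats until no peak remains.
Returns (start, end) spans, 1-based inclusive.
"""

from __future__ import annotations


def brute_force_segment(
    counts: list[int],
    peak_rel: float = 0.30,
    boundary_rel: float = 0.05,
    min_bins: int = 12,
    boundary_anchor: str = "peak",
) -> list[tuple[int, int]]:
    n = len(counts)
    if n == 0 or max(counts) == 0:
        return []
    global_max = max(counts)
    claimed: set[int] = set()
    spans: list[tuple[int, int]] = []
    while True:
        candidates = [
            i
            for i in range(n)
            if counts[i] >= peak_rel * global_max and i not in claimed
        ]
        if not candidates:
            break
        best = None
        for i in candidates:
            if best is None or counts[i] > counts[best]:
                best = i
        # earliest index wins ties: scan order already ascending, but make
        # the rule explicit
        for i in candidates:
            if counts[i] == counts[best] and i < best:
                best = i
        anchor = counts[best] if boundary_anchor == "peak" else global_max
        thresh = boundary_rel * anchor
        left = 0
        j = best - 1
        while j >= 0:
            if j in claimed:
                left = j + 1
                break
            if counts[j] < thresh:
                left = j
                break
            j -= 1
        right = n - 1
        j = best + 1
        while j < n:
            if j in claimed:
                right = j - 1
                break
            if counts[j] < thresh:
                right = j
                break
            j += 1
        for j in range(left, right + 1):
            claimed.add(j)
        if right - left + 1 >= min_bins:
            spans.append((left + 1, right + 1))
    return sorted(spans)


def random_series(rng, n):
    """Random incident-count series mixing noise, Gaussian bursts, sparse spikes."""
    import numpy as np

    kind = rng.integers(0, 3)
    if kind == 0:
        counts = rng.integers(0, 20, size=n)
    elif kind == 1:
        counts = np.zeros(n)
        for _ in range(rng.integers(1, 6)):
            c = rng.integers(0, n)
            h = int(rng.integers(5, 500))
            w = int(rng.integers(2, 40))
            counts += h * np.exp(-0.5 * ((np.arange(n) - c) / w) ** 2)
        counts = np.floor(counts + rng.poisson(1.0, size=n))
    else:
        counts = rng.poisson(2.0, size=n) * (rng.random(n) < 0.3)
    return counts.astype(int)
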