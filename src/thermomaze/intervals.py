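"""Closed-open time-interval arithmetic shared across the pipeline.

Intervals are ``(n, 2)`` float arrays of ``[start, end)`` rows in seconds.
All functions accept unsorted, possibly touching input and return sorted,
non-overlapping output.
"""

from __future__ import annotations

import numpy as np


def as_intervals(arr) -> np.ndarray:
    a = np.asarray(arr, dtype=float).reshape(-1, 2)
    if a.size and np.any(a[:, 1] < a[:, 0]):
        raise ValueError("interval end precedes start")
    return a


def merge(intervals) -> np.ndarray:
    """Union of intervals: sorted and with overlaps/touches coalesced."""
    a = as_intervals(intervals)
    if len(a) == 0:
        return a
    a = a[np.argsort(a[:, 0])]
    out = [a[0].copy()]
    for s, e in a[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.asarray(out)


def total_duration(intervals) -> float:
    a = merge(intervals)
    return float(np.sum(a[:, 1] - a[:, 0])) if len(a) else 0.0


def clip(intervals, lo: float, hi: float) -> np.ndarray:
    """Restrict intervals to [lo, hi), dropping what falls outside."""
    a = as_intervals(intervals)
    if len(a) == 0:
        return a
    s = np.maximum(a[:, 0], lo)
    e = np.minimum(a[:, 1], hi)
    keep = e > s
    return np.column_stack([s[keep], e[keep]])


def intersect(a, b) -> np.ndarray:
    """Pairwise intersection of two merged interval sets."""
    a, b = merge(a), merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if e > s:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=float).reshape(-1, 2)


def contains(intervals, times) -> np.ndarray:
    """Boolean mask: which of ``times`` fall inside the interval union."""
    a = merge(intervals)
    t = np.asarray(times, dtype=float)
    if len(a) == 0:
        return np.zeros(t.shape, dtype=bool)
    idx = np.searchsorted(a[:, 0], t, side="right") - 1
    ok = idx >= 0
    ok[ok] &= t[ok] < a[idx[ok], 1]
    return ok


def complement(intervals, lo: float, hi: float) -> np.ndarray:
    """Gaps of the interval union within [lo, hi)."""
    a = clip(merge(intervals), lo, hi)
    edges = np.concatenate([[lo], a.ravel(), [hi]])
    gaps = edges.reshape(-1, 2)
    keep = gaps[:, 1] > gaps[:, 0]
    return gaps[keep]


def sample_uniform(intervals, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` time points uniformly from the union of intervals."""
    a = merge(intervals)
    if len(a) == 0:
        raise ValueError("cannot sample from an empty interval set")
    lens = a[:, 1] - a[:, 0]
    which = rng.choice(len(a), size=n, p=lens / lens.sum())
    u = rng.uniform(size=n)
    return np.sort(a[which, 0] + u * lens[which])
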