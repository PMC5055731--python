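"""Half-open interval arithmetic on plain ``(start, end)`` tuples.

All coordinates are 0-based, half-open. Functions accept any iterable of
``(start, end)`` pairs and return sorted, merged, non-overlapping lists.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

Interval = tuple[int, int]


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping or adjacent intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Return ``a`` minus the union of ``b`` (both merged first)."""
    a_m = merge(a)
    b_m = merge(b)
    out: list[Interval] = []
    j = 0
    for s, e in a_m:
        cur = s
        while j < len(b_m) and b_m[j][1] <= cur:
            j += 1
        k = j
        while k < len(b_m) and b_m[k][0] < e:
            bs, be = b_m[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def complement(intervals: Iterable[Interval], length: int) -> list[Interval]:
    """Complement of the interval union within ``[0, length)``."""
    return subtract([(0, int(length))], intervals)


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def clip(intervals: Iterable[Interval], length: int) -> list[Interval]:
    """Clip intervals to ``[0, length)``, dropping empty leftovers."""
    out = []
    for s, e in intervals:
        s2, e2 = max(0, int(s)), min(int(length), int(e))
        if e2 > s2:
            out.append((s2, e2))
    return out


def points_in(intervals: Sequence[Interval], positions: np.ndarray) -> np.ndarray:
    """Boolean membership of each position in the merged interval union."""
    ivs = merge(intervals)
    pos = np.asarray(positions, dtype=np.int64)
    if not ivs:
        return np.zeros(pos.shape, dtype=bool)
    starts = np.array([s for s, _ in ivs], dtype=np.int64)
    ends = np.array([e for _, e in ivs], dtype=np.int64)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(pos.shape, dtype=bool)
    inside[ok] = pos[ok] < ends[idx[ok]]
    return inside


def count_points_per_interval(
    intervals: Sequence[Interval], positions: np.ndarray
) -> np.ndarray:
    """Number of positions falling inside each interval (intervals may overlap)."""
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    if len(intervals) == 0:
        return np.zeros(0, dtype=np.int64)
    starts = np.array([s for s, _ in intervals], dtype=np.int64)
    ends = np.array([e for _, e in intervals], dtype=np.int64)
    return np.searchsorted(pos, ends, side="left") - np.searchsorted(
        pos, starts, side="left"
    )
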