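"""Genomic interval arithmetic on 0-based half-open coordinates.

Interval sets are kept per chromosome as ``(n, 2)`` int64 arrays of
``[start, end)`` rows. After :func:`merge` a set is sorted and
non-overlapping, which every downstream routine assumes. A genome-wide
set is a ``dict`` mapping chromosome name to such an array.

These few operations — merge, union, subtract, overlap length, point
membership — are the substrate of PMD/PMI segmentation, so they are
implemented here directly (and cross-checked in the test suite against a
brute-force per-bp membership oracle) rather than routed through a
general-purpose interval library.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_array",
    "merge",
    "union",
    "subtract",
    "intersect",
    "total_bp",
    "overlap_bp",
    "jaccard",
    "points_in",
    "ranges_clear",
]


def as_array(intervals) -> np.ndarray:
    """Coerce an iterable of (start, end) pairs to an ``(n, 2)`` int64 array."""
    a = np.asarray(list(intervals) if not isinstance(intervals, np.ndarray) else intervals,
                   dtype=np.int64)
    if a.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    a = a.reshape(-1, 2)
    if np.any(a[:, 1] < a[:, 0]):
        raise ValueError("interval end precedes start")
    return a


def merge(a: np.ndarray, book_ended: bool = True) -> np.ndarray:
    """Sort and merge intervals; ``book_ended`` also fuses zero-gap neighbours."""
    a = as_array(a)
    if len(a) == 0:
        return a
    a = a[np.lexsort((a[:, 1], a[:, 0]))]
    starts, ends = a[:, 0], a[:, 1]
    # a new run begins where start exceeds the running max end so far
    run_end = np.maximum.accumulate(ends)
    if book_ended:
        breaks = starts[1:] > run_end[:-1]
    else:
        breaks = starts[1:] >= run_end[:-1]
    idx = np.concatenate(([0], np.flatnonzero(breaks) + 1))
    out_starts = starts[idx]
    out_ends = np.concatenate((run_end[idx[1:] - 1], [run_end[-1]]))
    return np.column_stack((out_starts, out_ends))


def union(*sets: np.ndarray) -> np.ndarray:
    parts = [as_array(s) for s in sets if len(as_array(s))]
    if not parts:
        return np.empty((0, 2), dtype=np.int64)
    return merge(np.concatenate(parts))


def intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two merged sets."""
    a, b = merge(a), merge(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append((lo, hi))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return as_array(out)


def subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Parts of ``a`` not covered by ``b`` (both merged first)."""
    a, b = merge(a), merge(b)
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    for s, e in a:
        cur = s
        # b intervals that can overlap [s, e)
        k0 = np.searchsorted(b[:, 1], s, side="right")
        for bs, be in b[k0:]:
            if bs >= e:
                break
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return as_array(out)


def total_bp(a: np.ndarray) -> int:
    a = merge(a)
    return int((a[:, 1] - a[:, 0]).sum()) if len(a) else 0


def overlap_bp(a: np.ndarray, b: np.ndarray) -> int:
    return total_bp(intersect(a, b))


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """bp-level Jaccard index; two empty sets score 1 by convention."""
    u = total_bp(union(a, b))
    if u == 0:
        return 1.0
    return overlap_bp(a, b) / u


def points_in(points: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Boolean mask: which 0-based positions fall inside the merged set ``a``."""
    points = np.asarray(points, dtype=np.int64)
    a = merge(a)
    if len(a) == 0:
        return np.zeros(points.shape, dtype=bool)
    idx = np.searchsorted(a[:, 0], points, side="right") - 1
    ok = idx >= 0
    ok[ok] &= points[ok] < a[idx[ok], 1]
    return ok


def ranges_clear(starts: np.ndarray, width: int, a: np.ndarray) -> np.ndarray:
    """Mask of query windows ``[s, s+width)`` that do NOT intersect merged set ``a``.

    Merged sets have strictly increasing starts and ends, so the number of
    overlapping intervals is a difference of two binary searches.
    """
    starts = np.asarray(starts, dtype=np.int64)
    a = merge(a)
    if len(a) == 0:
        return np.ones(starts.shape, dtype=bool)
    n_overlap = (np.searchsorted(a[:, 0], starts + width, side="left")
                 - np.searchsorted(a[:, 1], starts, side="right"))
    return n_overlap == 0


# ---------------------------------------------------------------------------
# genome-wide (per-chromosome dict) conveniences

def genome_merge(d: dict) -> dict:
    return {c: merge(v) for c, v in d.items()}


def genome_union(*ds: dict) -> dict:
    chroms = sorted({c for d in ds for c in d})
    return {c: union(*[d.get(c, np.empty((0, 2), np.int64)) for d in ds]) for c in chroms}


def genome_total_bp(d: dict) -> int:
    return sum(total_bp(v) for v in d.values())


def genome_overlap_bp(a: dict, b: dict) -> int:
    return sum(overlap_bp(a[c], b[c]) for c in set(a) & set(b))


def genome_jaccard(a: dict, b: dict) -> float:
    u = genome_total_bp(genome_union(a, b))
    if u == 0:
        return 1.0
    return genome_overlap_bp(a, b) / u
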