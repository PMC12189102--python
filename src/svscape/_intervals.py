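"""Low-level half-open interval arithmetic on numpy arrays.

All functions operate on per-chromosome ``(starts, ends)`` pairs of 0-based
half-open intervals.  Used by the overlap, annotation and repeat-content
modules; the merge/intersect semantics here define what "overlap" means
throughout the package (>= 1 shared bp; zero-length anchors overlap iff the
anchor point lies inside an interval).
"""

from __future__ import annotations

import numpy as np


def merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or bookended intervals; returns sorted disjoint set."""
    if len(starts) == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts, dtype=np.int64)[order]
    e = np.asarray(ends, dtype=np.int64)[order]
    out_s = [s[0]]
    out_e = [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            if e[i] > out_e[-1]:
                out_e[-1] = e[i]
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def overlap_mask(
    q_start: np.ndarray,
    q_end: np.ndarray,
    m_start: np.ndarray,
    m_end: np.ndarray,
) -> np.ndarray:
    """Boolean per query interval: >=1 bp overlap with the merged set (m sorted, disjoint).

    Zero-length queries (q_start == q_end) are treated as anchor points that
    overlap iff the point lies strictly inside an interval [s, e).
    """
    q_start = np.asarray(q_start, dtype=np.int64)
    q_end = np.asarray(q_end, dtype=np.int64)
    if len(m_start) == 0 or len(q_start) == 0:
        return np.zeros(len(q_start), dtype=bool)
    # index of first merged interval with end > q_start
    idx = np.searchsorted(m_end, q_start, side="right")
    ok = idx < len(m_start)
    res = np.zeros(len(q_start), dtype=bool)
    point = q_start == q_end
    span = ~point
    # span query overlaps iff m_start[idx] < q_end
    sel = ok & span
    res[sel] = m_start[idx[sel]] < q_end[sel]
    # anchor point overlaps iff m_start[idx] <= q_start (point inside [s,e))
    sel = ok & point
    res[sel] = m_start[idx[sel]] <= q_start[sel]
    return res


def covered_bases(
    q_start: np.ndarray,
    q_end: np.ndarray,
    m_start: np.ndarray,
    m_end: np.ndarray,
) -> np.ndarray:
    """Per query interval: number of its bases covered by the merged set."""
    q_start = np.asarray(q_start, dtype=np.int64)
    q_end = np.asarray(q_end, dtype=np.int64)
    n = len(q_start)
    if len(m_start) == 0 or n == 0:
        return np.zeros(n, dtype=np.int64)
    # cumulative covered length up to each merged interval start
    lengths = m_end - m_start
    cum = np.concatenate([[0], np.cumsum(lengths)])

    def cov_upto(pos: np.ndarray) -> np.ndarray:
        """Total merged bases in [0, pos)."""
        i = np.searchsorted(m_start, pos, side="right")  # intervals starting before pos
        full = cum[i]
        # subtract the part of interval i-1 beyond pos
        adj = np.where(i > 0, np.maximum(m_end[np.maximum(i - 1, 0)] - pos, 0), 0)
        return full - adj

    return cov_upto(q_end) - cov_upto(q_start)


def subtract(
    a_start: np.ndarray, a_end: np.ndarray, b_start: np.ndarray, b_end: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Set difference A \\ B on interval sets (each merged internally first)."""
    a_s, a_e = merge(a_start, a_end)
    b_s, b_e = merge(b_start, b_end)
    out_s, out_e = [], []
    j = 0
    for s, e in zip(a_s, a_e):
        cur = s
        while j < len(b_s) and b_e[j] <= cur:
            j += 1
        k = j
        while k < len(b_s) and b_s[k] < e:
            if b_s[k] > cur:
                out_s.append(cur)
                out_e.append(b_s[k])
            cur = max(cur, b_e[k])
            if cur >= e:
                break
            k += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def total_intersection(
    a_start: np.ndarray, a_end: np.ndarray, b_start: np.ndarray, b_end: np.ndarray
) -> int:
    """Total shared bp between two interval sets (each merged internally first)."""
    a_s, a_e = merge(a_start, a_end)
    b_s, b_e = merge(b_start, b_end)
    return int(covered_bases(a_s, a_e, b_s, b_e).sum())
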