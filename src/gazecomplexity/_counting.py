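"""Exact template-pair counting for sample entropy.

Sample entropy needs two counts over the same template index set: B, the
ordered pairs (i != j) of m-length templates within Chebyshev distance r,
and A, the same for (m + 1)-length templates.  The counts here are exactly
those of exhaustive O(N^2) enumeration, but are obtained sub-quadratically:
templates are swept in order of their first coordinate with a two-pointer
window of width 2r, and the remaining coordinates are held in a
sqrt-decomposition structure (buckets by second-coordinate rank, each bucket
kept sorted by third coordinate) supporting insert, delete and range count
in ~sqrt(N) time.  One sweep serves both counts, since the m- and
(m+1)-template pairs share the window on the leading coordinates.  Template
lengths above three (m > 2) fall back to a jitted brute-force double loop
with early abort.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _brute_force_ab(x, m, r, n_templates):  # pragma: no cover - jitted
    """(A, B) ordered-pair counts by exhaustive enumeration."""
    a = 0
    b = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            ok = True
            for k in range(m):
                d = x[i + k] - x[j + k]
                if d > r or d < -r:
                    ok = False
                    break
            if ok:
                b += 1
                d = x[i + m] - x[j + m]
                if -r <= d <= r:
                    a += 1
    return 2 * a, 2 * b


@njit(cache=False)
def _interval_count(arr, cnt, center, r):  # pragma: no cover - jitted
    """Half-open index range of sorted ``arr[:cnt]`` with |center - v| <= r.

    The match predicate is evaluated exactly as exhaustive counting does
    (rounded subtraction compared against r); binary-search positions are
    only a starting point and are corrected by walking, so boundary cases
    where ``center - r`` rounds differently from the pairwise difference
    still resolve exactly.  Valid because float subtraction is monotone in
    the subtrahend, making the matching set contiguous in sorted order.
    """
    # first matching index: start near center - r and walk to the boundary
    lo = np.searchsorted(arr[:cnt], center - r, side="left")
    while lo > 0 and -r <= center - arr[lo - 1] <= r:
        lo -= 1
    while lo < cnt and not (-r <= center - arr[lo] <= r):
        lo += 1
    if lo == cnt or not (-r <= center - arr[lo] <= r):
        return 0, 0  # nothing matches
    # one past the last matching index
    hi = np.searchsorted(arr[:cnt], center + r, side="right")
    if hi < lo:
        hi = lo
    while hi < cnt and -r <= center - arr[hi] <= r:
        hi += 1
    while hi > lo and not (-r <= center - arr[hi - 1] <= r):
        hi -= 1
    return lo, hi


@njit(cache=False)
def _sweep_ab(x0, y, z, yr, y_sorted, r, use_y, use_z):  # pragma: no cover - jitted
    """(A, B) unordered-pair counts in one sweep over the leading coordinate.

    A pair enters B when |dx0| <= r (and |dy| <= r when ``use_y``); it also
    enters A when additionally |dz| <= r (``use_z``).  ``yr`` holds each
    point's (distinct) rank by y value, ``y_sorted`` the sorted y values.
    Active points — those with x0 within r behind the sweep — live in rank
    buckets of ~sqrt(N), each kept sorted by z.  Every comparison uses the
    same rounded-subtraction predicate as exhaustive counting, so the
    result is bit-exact even when a pairwise difference equals r.
    """
    n = x0.shape[0]
    order = np.argsort(x0, kind="mergesort")
    bs = int(np.sqrt(n)) + 1
    nb = (n + bs - 1) // bs
    bucket_z = np.empty((nb, bs))
    bucket_yr = np.empty((nb, bs), np.int64)
    bucket_cnt = np.zeros(nb, np.int64)

    count_a = 0
    count_b = 0
    left = 0
    for idx in range(n):
        i = order[idx]
        xi = x0[i]
        # evict points out of the x0 window; same predicate as the match
        # test (the pair fails exactly when xi - x0j > r)
        while xi - x0[order[left]] > r:
            p = order[left]
            b = yr[p] // bs
            cnt = bucket_cnt[b]
            pos = 0
            while bucket_yr[b, pos] != yr[p]:
                pos += 1
            for q in range(pos, cnt - 1):
                bucket_z[b, q] = bucket_z[b, q + 1]
                bucket_yr[b, q] = bucket_yr[b, q + 1]
            bucket_cnt[b] = cnt - 1
            left += 1
        # exact y-rank interval of |yi - yj| <= r
        if use_y:
            lo, hi_open = _interval_count(y_sorted, n, y[i], r)
            hi = hi_open - 1
        else:
            lo = 0
            hi = n - 1
        if lo <= hi:
            b_lo = lo // bs
            b_hi = hi // bs
            for b in range(b_lo, b_hi + 1):
                cnt = bucket_cnt[b]
                if cnt == 0:
                    continue
                if b_lo < b < b_hi:
                    # bucket fully inside the y interval
                    count_b += cnt
                    if use_z:
                        z_lo, z_hi = _interval_count(bucket_z[b], cnt, z[i], r)
                        count_a += z_hi - z_lo
                else:
                    for q in range(cnt):
                        if lo <= bucket_yr[b, q] <= hi:
                            count_b += 1
                            if use_z and -r <= z[i] - bucket_z[b, q] <= r:
                                count_a += 1
        # insert the current point, keeping its bucket z-sorted
        b = yr[i] // bs
        cnt = bucket_cnt[b]
        pos = np.searchsorted(bucket_z[b, :cnt], z[i], side="right")
        for q in range(cnt, pos, -1):
            bucket_z[b, q] = bucket_z[b, q - 1]
            bucket_yr[b, q] = bucket_yr[b, q - 1]
        bucket_z[b, pos] = z[i]
        bucket_yr[b, pos] = yr[i]
        bucket_cnt[b] = cnt + 1
    if not use_z:
        count_a = -1  # caller computes A from the y-filtered count instead
    return count_a, count_b


def count_ab_pairs(x: np.ndarray, m: int, r: float, n_templates: int) -> tuple[int, int]:
    """Ordered-pair template match counts (A, B) of sample entropy.

    B counts pairs (i != j), i, j < ``n_templates``, of m-length templates
    within Chebyshev distance r; A counts the same pairs that still match
    when the templates are extended to length m + 1.
    """
    x = np.ascontiguousarray(x, dtype=float)
    if n_templates < 2:
        return 0, 0
    all_pairs = n_templates * (n_templates - 1)
    if np.ptp(x[: n_templates + m]) <= r:
        return all_pairs, all_pairs
    if m > 2:
        a, b = _brute_force_ab(x, m, float(r), n_templates)
        return int(a), int(b)
    y = np.ascontiguousarray(x[1 : n_templates + 1])
    if m == 2:
        z = np.ascontiguousarray(x[2 : n_templates + 2])
    else:
        z = np.zeros(n_templates)
    order = np.argsort(y, kind="mergesort")
    yr = np.empty(n_templates, dtype=np.int64)
    yr[order] = np.arange(n_templates)
    y_sorted = y[order]
    if m == 1:
        # B needs x0 only; A needs (x0, y).  One sweep, y-filtered count = A.
        a, b = _sweep_ab(
            x[:n_templates], y, z, yr, y_sorted, float(r), True, False
        )
        # that call returned (sentinel, y-filtered pairs) = (-1, A); redo B
        a = b
        _, b = _sweep_ab(
            x[:n_templates], y, z, yr, y_sorted, float(r), False, False
        )
        return 2 * int(a), 2 * int(b)
    a, b = _sweep_ab(x[:n_templates], y, z, yr, y_sorted, float(r), True, True)
    return 2 * int(a), 2 * int(b)


def count_template_pairs(x: np.ndarray, length: int, r: float, n_templates: int) -> int:
    """Ordered pairs (i != j) of length-``length`` templates within Chebyshev r.

    Single-length variant of :func:`count_ab_pairs` (the B count with
    m = ``length``), kept for direct use and cross-checking.
    """
    x = np.ascontiguousarray(x, dtype=float)
    if n_templates < 2:
        return 0
    if np.ptp(x[: n_templates + length - 1]) <= r:
        return n_templates * (n_templates - 1)
    if length > 3:
        a, b = _brute_force_ab(x, length - 1, float(r), n_templates)
        return int(a)
    if length == 1:
        srt = np.sort(x[:n_templates])
        hi = np.searchsorted(srt, srt + r, side="right")
        lo = np.searchsorted(srt, srt - r, side="left")
        return int(np.sum(hi - lo) - n_templates)
    y = np.ascontiguousarray(x[1 : n_templates + 1])
    if length == 3:
        z = np.ascontiguousarray(x[2 : n_templates + 2])
    else:
        z = np.zeros(n_templates)
    order = np.argsort(y, kind="mergesort")
    yr = np.empty(n_templates, dtype=np.int64)
    yr[order] = np.arange(n_templates)
    y_sorted = y[order]
    use_z = length == 3
    a, b = _sweep_ab(x[:n_templates], y, z, yr, y_sorted, float(r), True, use_z)
    return 2 * int(a) if use_z else 2 * int(b)
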