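"""Empirical mode decomposition by envelope-mean sifting.

A signal X(t) is decomposed into a small set of intrinsic mode functions
(IMFs) c_i(t) and a residue r_n(t) with X(t) = sum_i c_i(t) + r_n(t).  Each
IMF is obtained by sifting: repeatedly subtracting the mean of the upper and
lower cubic-spline envelopes through the local maxima and minima until the
candidate is locally symmetric.  Extraction stops when the residue is
monotone (too few extrema) or a configurable mode cap is reached; the
residue is defined as input minus the extracted modes, so reconstruction is
exact by construction.

Numerical choices: envelopes use cubic interpolation through extrema with
mirror extension of the signal at both ends to suppress end swings; sifting
stops on a Cauchy-type criterion (normalized squared change between
successive siftings below 0.2) with a hard cap of 100 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

DEFAULT_MAX_IMF = 6
CAUCHY_THRESHOLD = 0.2
MAX_SIFTINGS = 100


class MonotoneResidueError(ValueError):
    """The series has too few extrema to build envelopes (monotone residue)."""


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus residue for one channel."""

    source_channel: str
    imfs: list[np.ndarray]
    residue: np.ndarray

    @property
    def n(self) -> int:
        """Number of extracted IMFs."""
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Sum of IMFs and residue; equals the input exactly."""
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def find_extrema(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima.

    Detected by sign changes of the first difference after compressing
    equal-value runs, so a plateau extremum counts once at its midpoint.
    Endpoints are never extrema.
    """
    x = np.asarray(series, dtype=float)
    empty = np.array([], dtype=int)
    if x.size < 3:
        return empty, empty
    keep = np.concatenate(([True], np.diff(x) != 0))
    run_start = np.flatnonzero(keep)
    run_end = np.append(run_start[1:] - 1, x.size - 1)
    xc = x[run_start]
    if xc.size < 3:
        return empty, empty
    d = np.sign(np.diff(xc))
    interior = np.arange(1, xc.size - 1)
    is_max = (d[:-1] > 0) & (d[1:] < 0)
    is_min = (d[:-1] < 0) & (d[1:] > 0)
    max_runs = interior[is_max]
    min_runs = interior[is_min]
    maxima = (run_start[max_runs] + run_end[max_runs]) // 2
    minima = (run_start[min_runs] + run_end[min_runs]) // 2
    return maxima, minima


def zero_crossings(series: np.ndarray) -> int:
    """Count of sign changes, ignoring exact zeros."""
    x = np.asarray(series, dtype=float)
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def is_imf(series: np.ndarray, mean_tolerance: float = 0.1) -> bool:
    """Check the two defining IMF properties.

    Extrema and zero-crossing counts may differ by at most one, and the mean
    of the upper/lower envelopes must be small relative to the mode's
    amplitude (RMS of envelope mean below ``mean_tolerance`` times the RMS
    of the series).
    """
    x = np.asarray(series, dtype=float)
    maxima, minima = find_extrema(x)
    n_ext = maxima.size + minima.size
    if abs(n_ext - zero_crossings(x)) > 1:
        return False
    try:
        mean_env = _envelope_mean(x)
    except MonotoneResidueError:
        return False
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        return True
    return bool(np.sqrt(np.mean(mean_env**2)) <= mean_tolerance * rms)


def _envelope_mean(x: np.ndarray) -> np.ndarray:
    """Mean of the cubic upper and lower envelopes, with mirror extension."""
    n = x.size
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise MonotoneResidueError("fewer than two maxima or two minima")

    # mirror just enough signal at each end to supply boundary extrema
    all_ext = np.sort(np.concatenate([maxima, minima]))
    k_left = int(min(max(all_ext[1], 2), n - 1))
    k_right = int(min(max(n - 1 - all_ext[-2], 2), n - 1))
    x_ext = np.concatenate([x[k_left:0:-1], x, x[n - 2 : n - 2 - k_right : -1]])
    t_ext = np.arange(-k_left, n + k_right - 1)

    ext_max, ext_min = find_extrema(x_ext)
    t = np.arange(n)
    upper = _spline_through(t_ext, x_ext, ext_max, t)
    lower = _spline_through(t_ext, x_ext, ext_min, t)
    return (upper + lower) / 2.0


def _spline_through(
    t_ext: np.ndarray, x_ext: np.ndarray, knots: np.ndarray, t_eval: np.ndarray
) -> np.ndarray:
    """Cubic interpolation through the knot samples, clamped to the span ends."""
    kt = t_ext[knots]
    kv = x_ext[knots]
    # ensure the knots bracket the evaluation range
    if kt.size == 0 or kt[0] > t_eval[0]:
        kt = np.concatenate([[t_ext[0]], kt])
        kv = np.concatenate([[x_ext[0]], kv])
    if kt[-1] < t_eval[-1]:
        kt = np.concatenate([kt, [t_ext[-1]]])
        kv = np.concatenate([kv, [x_ext[-1]]])
    if kt.size < 2:
        raise MonotoneResidueError("not enough envelope knots")
    if kt.size < 4:
        # too few knots for a cubic: fall back to linear interpolation
        return np.interp(t_eval, kt, kv)
    return CubicSpline(kt, kv)(t_eval)


def sift(
    series: np.ndarray,
    cauchy_threshold: float = CAUCHY_THRESHOLD,
    max_siftings: int = MAX_SIFTINGS,
) -> np.ndarray:
    """Extract one candidate IMF from the series.

    Iteratively subtracts the envelope mean until the normalized squared
    difference between successive siftings falls below ``cauchy_threshold``
    and the extrema/zero-crossing counts differ by at most one (or the
    iteration cap is reached).  Raises :class:`MonotoneResidueError` when no
    envelopes can be built.
    """
    h = np.asarray(series, dtype=float).copy()
    for _ in range(max_siftings):
        mean_env = _envelope_mean(h)
        denom = float(np.sum(h**2))
        h_new = h - mean_env
        if denom == 0:
            return h_new
        sd = float(np.sum(mean_env**2)) / denom
        h = h_new
        maxima, minima = find_extrema(h)
        if maxima.size < 2 or minima.size < 2:
            break
        # accept once the change is small and the extrema/zero-crossing
        # counts agree to within one (the defining IMF property)
        if sd < cauchy_threshold and abs(
            maxima.size + minima.size - zero_crossings(h)
        ) <= 1:
            break
    return h


def decompose(
    series: np.ndarray,
    max_imf: int = DEFAULT_MAX_IMF,
    source_channel: str = "",
) -> IMFSet:
    """Full EMD of one series into at most ``max_imf`` IMFs plus residue.

    Stops early when the working residue becomes monotone or loses the
    extrema needed for envelope construction; a constant input yields zero
    IMFs and a residue equal to the input.  The residue is computed as
    input minus the sum of modes, so the reconstruction identity holds to
    machine precision.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("series too short to decompose (need >= 10 samples)")
    if max_imf < 1:
        raise ValueError("max_imf must be >= 1")
    imfs: list[np.ndarray] = []
    work = x.copy()
    while len(imfs) < max_imf:
        maxima, minima = find_extrema(work)
        if maxima.size < 2 or minima.size < 2:
            break
        try:
            imf = sift(work)
        except MonotoneResidueError:
            break
        if not np.any(imf):
            break
        imfs.append(imf)
        work = work - imf
    residue = x - np.sum(imfs, axis=0) if imfs else x.copy()
    return IMFSet(source_channel=source_channel, imfs=imfs, residue=residue)
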