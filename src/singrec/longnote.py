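"""Sustained-note ("long note") scoring from a frame-level pitch track.

Seven per-trial statistics summarise how steadily a singer holds a target
pitch: mean absolute deviation in cents (accuracy), pitch variance in Hz²,
a path-normalised DTW distance between the sung deviation contour and an
ideal flat contour, the mean autocorrelation of the track, a
Wald–Wolfowitz runs-test z statistic, and the count and timing of mean
changepoints (a late/early second changepoint can indicate an onset
"scoop").  Changepoints are found with a PELT mean-shift segmentation
under an MBIC-style penalty, mirroring the R ``changepoint::cpt.mean``
routine the measure set was defined around.

Measures are computed on the voiced frames of the track as given.  An
optional 5-frame running-median smoother (``smooth=True``) approximates a
pYIN-style smoothed track for callers holding raw frame estimates; it is
off by default so that the statistics retain their textbook sampling
behaviour on white-noise tracks (e.g. the runs test stays N(0,1) under an
i.i.d. null).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.signal import medfilt

from .core import PitchTrack, cents_deviation

__all__ = [
    "LongNoteMeasures",
    "long_note_measures",
    "average_over_trials",
    "dtw_distance",
    "runs_test_z",
    "pelt_mean_changepoints",
]


@dataclass(frozen=True)
class LongNoteMeasures:
    accuracy: float  # mean |deviation| from target, cents
    var: float  # variance of voiced f0, Hz^2
    dtw_distance: float  # path-normalised DTW vs flat contour, cents
    autocorrelation_mean: float  # mean sample ACF over lags 1..L//2
    run_test: float  # Wald-Wolfowitz z about the median; NaN if degenerate
    no_cpts: float  # number of mean changepoints
    beginning_of_second_cpt: float  # seconds; NaN when fewer than 2 changepoints


def _dtw_kernel(x, y):
    n, m = len(x), len(y)
    D = np.full((n + 1, m + 1), np.inf)
    L = np.zeros((n + 1, m + 1), dtype=np.int64)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        xi = x[i - 1]
        for j in range(1, m + 1):
            c = abs(xi - y[j - 1])
            d_diag = D[i - 1, j - 1]
            d_up = D[i - 1, j]
            d_left = D[i, j - 1]
            # lowest accumulated cost wins; ties go to the diagonal
            if d_diag <= d_up and d_diag <= d_left:
                D[i, j] = d_diag + c
                L[i, j] = L[i - 1, j - 1] + 1
            elif d_up <= d_left:
                D[i, j] = d_up + c
                L[i, j] = L[i - 1, j] + 1
            else:
                D[i, j] = d_left + c
                L[i, j] = L[i, j - 1] + 1
    return D[n, m] / L[n, m]


try:  # optional jit: identical semantics, much faster on long tracks
    from numba import njit

    _dtw_kernel = njit(cache=False)(_dtw_kernel)
except ImportError:  # pragma: no cover
    pass


def dtw_distance(x, y) -> float:
    """Dynamic-time-warping distance with |a-b| local cost, per path step.

    The accumulated cost of the optimal monotone alignment is divided by
    the length of the warping path, removing the trivial dependence on
    series length.
    """
    x = np.ascontiguousarray(x, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("dtw_distance needs non-empty series")
    return float(_dtw_kernel(x, y))


def runs_test_z(values) -> float:
    """Wald–Wolfowitz runs-test z statistic for randomness about the median.

    Values equal to the median are dropped.  Returns NaN (degenerate) when
    either sign class is empty, e.g. for a constant series.
    """
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    signs = np.sign(v - med)
    signs = signs[signs != 0]
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    if n1 == 0 or n2 == 0:
        return float("nan")
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
    if var <= 0:
        return float("nan")
    return (runs - mu) / math.sqrt(var)


def _mad_sigma2(y: np.ndarray) -> float:
    """Robust noise-variance estimate from first differences."""
    d = np.diff(y)
    if len(d) == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    sigma = mad / 0.6744897501960817 / math.sqrt(2.0)
    return float(sigma * sigma)


def pelt_mean_changepoints(y, penalty: float | None = None) -> list[int]:
    """PELT segmentation for shifts in mean; returns new-segment start indices.

    The segment cost is the residual sum of squares about the segment mean
    scaled by a robust (difference-based MAD) noise-variance estimate; the
    default penalty is MBIC-style, 3·log(n) per changepoint.  A constant
    (zero-noise-estimate) series falls back to an exact zero-variance rule.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        return []
    sigma2 = _mad_sigma2(y)
    if sigma2 <= 0:
        # noiseless piecewise-constant series: boundaries are exact level shifts
        return [int(i) for i in np.flatnonzero(np.diff(y) != 0) + 1]
    if penalty is None:
        penalty = 3.0 * math.log(n)
    cs = np.concatenate([[0.0], np.cumsum(y)])
    ss = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_cost(a: int, b: int) -> float:  # [a, b)
        s = cs[b] - cs[a]
        return (ss[b] - ss[a] - s * s / (b - a)) / sigma2

    F = np.empty(n + 1)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    candidates = [0]
    for t in range(1, n + 1):
        best, best_s = math.inf, 0
        for s in candidates:
            val = F[s] + seg_cost(s, t) + penalty
            if val < best:
                best, best_s = val, s
        F[t] = best
        prev[t] = best_s
        candidates = [s for s in candidates if F[s] + seg_cost(s, t) <= F[t]]
        candidates.append(t)

    cpts = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            cpts.append(s)
        t = s
    return sorted(cpts)


def _smooth_median5(y: np.ndarray) -> np.ndarray:
    if len(y) < 5:
        return y.copy()
    return medfilt(y, kernel_size=5)


def long_note_measures(
    track: PitchTrack,
    target_midi: int,
    smooth: bool = False,
    min_voiced: int = 10,
    cpt_penalty: float | None = None,
) -> LongNoteMeasures:
    """All seven long-note statistics for one sustained-note trial.

    ``smooth`` applies a 5-frame running median to the voiced f0 values
    first (pYIN-style smoothing for raw tracks).  Fields that are undefined
    for a given track (runs test on a constant series, second-changepoint
    time with fewer than two changepoints) come back as NaN rather than
    failing the whole call.
    """
    times, f0 = track.voiced()
    if len(f0) < min_voiced:
        raise ValueError(
            f"long-note measures need at least {min_voiced} voiced frames, got {len(f0)}"
        )
    if smooth:
        f0 = _smooth_median5(f0)
    cents = cents_deviation(f0, target_midi)

    accuracy = float(np.mean(np.abs(cents)))
    var = float(np.var(f0))
    dtw = dtw_distance(cents, np.zeros_like(cents))

    L = len(f0)
    centred = f0 - f0.mean()
    denom = float(centred @ centred)
    if denom == 0:
        ac_mean = float("nan")
    else:
        lags = range(1, L // 2 + 1)
        ac = [float(centred[:-k] @ centred[k:]) / denom for k in lags]
        ac_mean = float(np.mean(ac)) if ac else float("nan")

    z = runs_test_z(f0)
    cpts = pelt_mean_changepoints(f0, penalty=cpt_penalty)
    second = float(times[cpts[1]]) if len(cpts) >= 2 else float("nan")

    return LongNoteMeasures(
        accuracy=accuracy,
        var=var,
        dtw_distance=dtw,
        autocorrelation_mean=ac_mean,
        run_test=z,
        no_cpts=float(len(cpts)),
        beginning_of_second_cpt=second,
    )


def average_over_trials(per_trial: list[LongNoteMeasures]) -> LongNoteMeasures:
    """Field-wise mean across trials, ignoring NaN fields per measure."""
    if not per_trial:
        raise ValueError("average_over_trials needs at least one trial")
    vals = {}
    for f in fields(LongNoteMeasures):
        col = np.array([getattr(m, f.name) for m in per_trial], dtype=float)
        col = col[~np.isnan(col)]
        vals[f.name] = float(np.mean(col)) if len(col) else float("nan")
    return LongNoteMeasures(**vals)
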