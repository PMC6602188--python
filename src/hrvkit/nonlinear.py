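"""Nonlinear HRV metrics: Poincaré SD1/SD2, sample entropy, DFA.

Poincaré SD1/SD2 are the dispersions of the lag-1 return map along its
minor and major axes; SD1 equals RMSSD/√2 exactly. Sample entropy is −ln(A/B) where B and A count m- and
(m+1)-length template matches within a Chebyshev tolerance r (0.2 × SD
by default, templates drawn from the first N−m points, self-matches
excluded). Detrended fluctuation analysis integrates the mean-centered
series, removes a linear fit in non-overlapping boxes, and regresses
log fluctuation on log box size; the short-range exponent α1 uses box
sizes 4–13 beats and the long-range exponent α2 uses 14 and above.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .config import DEFAULT_CONFIG
from .preprocess import CleanRRSeries

logger = logging.getLogger(__name__)

__all__ = [
    "NonlinearMetrics",
    "poincare_sd",
    "sample_entropy",
    "dfa",
    "dfa_fluctuations",
    "nonlinear_metrics",
]


@dataclass(frozen=True)
class NonlinearMetrics:
    sd1: float  # ms
    sd2: float  # ms
    sampen: Optional[float]
    dfa_alpha: Optional[float]
    dfa_alpha1: Optional[float]
    dfa_alpha2: Optional[float]


def _intervals(series) -> np.ndarray:
    if isinstance(series, CleanRRSeries):
        return series.intervals
    return np.asarray(series, dtype=float)


def poincare_sd(series) -> Tuple[float, float]:
    """SD1 and SD2 of the lag-1 Poincaré scatter.

    SD1 is the uncentered RMS of the minor-axis coordinate
    (RR_{i+1} − RR_i)/√2, which makes SD1 = RMSSD/√2 an exact identity;
    SD2 is the sample SD (n−1) of the major-axis coordinate about its
    mean.
    """
    x = _intervals(series)
    if x.size < 3:
        raise ValueError("need at least 3 intervals")
    diff = (x[1:] - x[:-1]) / math.sqrt(2.0)
    summ = (x[1:] + x[:-1]) / math.sqrt(2.0)
    sd1 = math.sqrt(float(np.mean(diff**2)))
    return sd1, float(summ.std(ddof=1))


def sample_entropy(
    series,
    m: int = DEFAULT_CONFIG.sampen_m,
    r_fraction: float = DEFAULT_CONFIG.sampen_r_fraction,
) -> Optional[float]:
    """Sample entropy with template length ``m`` and tolerance
    ``r_fraction`` × SD of the series.

    Returns None (undefined) for a constant series or when no template
    matches exist at either length.
    """
    x = _intervals(series)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"need more than m+1 = {m + 1} intervals")
    if r_fraction <= 0:
        raise ValueError("r_fraction must be positive")
    sd = x.std(ddof=1)
    if sd == 0:
        logger.info("sample entropy undefined: zero-variance series")
        return None
    r = r_fraction * sd
    # Chebyshev template matching, vectorized over template pairs.
    # Both B (length m) and A (length m+1) draw templates from the first
    # n - m points so the counts are comparable.
    n_tpl = n - m
    within = np.abs(x[:, None] - x[None, :]) <= r  # pointwise closeness
    match_m = np.ones((n_tpl, n_tpl), dtype=bool)
    for k in range(m):
        match_m &= within[k : k + n_tpl, k : k + n_tpl]
    match_m1 = match_m & within[m : m + n_tpl, m : m + n_tpl]
    np.fill_diagonal(match_m, False)
    np.fill_diagonal(match_m1, False)
    B = int(match_m.sum())
    A = int(match_m1.sum())
    if A == 0 or B == 0:
        logger.warning("sample entropy undefined: no template matches (A=%d B=%d)", A, B)
        return None
    return float(-math.log(A / B))


def _box_sizes(box_min: int, box_max: int, n_points: int = 30) -> np.ndarray:
    grid = np.unique(
        np.round(np.logspace(math.log10(box_min), math.log10(box_max), n_points))
    ).astype(int)
    return grid[(grid >= box_min) & (grid <= box_max)]


def dfa_fluctuations(
    series, box_min: int = DEFAULT_CONFIG.dfa_box_min,
    box_max: int = DEFAULT_CONFIG.dfa_box_max,
) -> Tuple[np.ndarray, np.ndarray]:
    """Fluctuation function F(n) over a log-spaced integer box grid.

    The series is mean-centered and integrated; within each
    non-overlapping box of n beats a first-order polynomial trend is
    removed; F(n) is the RMS residual over all covered points.
    """
    x = _intervals(series)
    N = x.size
    box_max = min(box_max, N // 4)
    if box_max < box_min:
        raise ValueError(f"series of {N} beats too short for boxes >= {box_min}")
    y = np.cumsum(x - x.mean())
    sizes = _box_sizes(box_min, box_max)
    fluct = np.empty(sizes.size)
    for j, n in enumerate(sizes):
        n_boxes = N // n
        seg = y[: n_boxes * n].reshape(n_boxes, n)
        t = np.arange(n)
        # per-box linear detrend via least squares
        tm = t - t.mean()
        denom = (tm**2).sum()
        slope = seg @ tm / denom
        inter = seg.mean(axis=1)
        resid = seg - (inter[:, None] + slope[:, None] * tm[None, :])
        fluct[j] = math.sqrt(float((resid**2).mean()))
    return sizes, fluct


def _log_slope(sizes: np.ndarray, fluct: np.ndarray) -> Optional[float]:
    ok = fluct > 0
    if ok.sum() < 3:
        return None
    return float(np.polyfit(np.log(sizes[ok]), np.log(fluct[ok]), 1)[0])


def dfa(
    series,
    breakpoint: int = DEFAULT_CONFIG.dfa_breakpoint,
    box_min: int = DEFAULT_CONFIG.dfa_box_min,
    box_max: int = DEFAULT_CONFIG.dfa_box_max,
) -> Tuple[Optional[float], Optional[float], Optional[float]]:
    """Scaling exponents (α, α1, α2) from log F(n) vs log n.

    α1 regresses over box sizes in [box_min, breakpoint], α2 over
    (breakpoint, box_max], α over the full grid. An exponent whose
    segment holds fewer than 3 box sizes is None.
    """
    sizes, fluct = dfa_fluctuations(series, box_min, box_max)
    short = sizes <= breakpoint
    alpha = _log_slope(sizes, fluct)
    alpha1 = _log_slope(sizes[short], fluct[short])
    alpha2 = _log_slope(sizes[~short], fluct[~short])
    return alpha, alpha1, alpha2


def nonlinear_metrics(series, config=DEFAULT_CONFIG) -> NonlinearMetrics:
    """Full nonlinear metric set on a corrected RR series."""
    sd1, sd2 = poincare_sd(series)
    sampen = sample_entropy(series, config.sampen_m, config.sampen_r_fraction)
    try:
        a, a1, a2 = dfa(series, config.dfa_breakpoint, config.dfa_box_min, config.dfa_box_max)
    except ValueError:
        a = a1 = a2 = None
    return NonlinearMetrics(
        sd1=sd1, sd2=sd2, sampen=sampen, dfa_alpha=a, dfa_alpha1=a1, dfa_alpha2=a2
    )
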