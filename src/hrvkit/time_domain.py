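"""Time-domain HRV metrics.

Mean IBI, heart rate, SDNN, RMSSD, and the geometric histogram measures
TI and TINN. Heart rate is the mean of instantaneous per-beat rates
(60000/RR_i), not the reciprocal of the mean interval — the two differ
by Jensen's inequality and per-subject study values are only consistent
with the per-beat convention. Standard deviations use the n−1
denominator throughout the package.
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

__all__ = ["TimeDomainMetrics", "time_metrics", "triangular_histogram"]


@dataclass(frozen=True)
class TimeDomainMetrics:
    mean_ibi: float  # ms
    mean_hr: float  # bpm, mean of per-beat instantaneous rates
    sdnn: float  # ms
    rmssd: float  # ms
    ti: Optional[float]  # triangular index, dimensionless
    tinn: Optional[float]  # ms


def _intervals(series) -> np.ndarray:
    if isinstance(series, CleanRRSeries):
        return series.intervals
    return np.asarray(series, dtype=float)


def triangular_histogram(
    series, bin_width: float = DEFAULT_CONFIG.histogram_bin_width_ms
) -> Tuple[float, float]:
    """Triangular index and TINN of the RR histogram.

    The histogram uses bins of ``bin_width`` ms aligned to multiples of
    the bin width (the conventional 1/128 s grid by default). TI is the
    total beat count divided by the modal bin count. TINN is the base
    width M − N of the best least-squares triangular fit to the
    histogram whose apex is fixed at the modal bin; N and M are searched
    over bin edges on either side of the mode.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = _intervals(series)
    lo = math.floor(x.min() / bin_width)
    hi = math.floor(x.max() / bin_width) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    counts, _ = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    peak = int(np.argmax(counts))
    ti = x.size / counts[peak]
    if np.count_nonzero(counts) == 1:
        logger.info("degenerate RR histogram: all beats in one bin")
        return float(ti), float(bin_width)

    apex_t, apex_h = centers[peak], counts[peak]

    def sse(n_left: float, m_right: float) -> float:
        tri = np.zeros_like(centers, dtype=float)
        up = (centers >= n_left) & (centers <= apex_t)
        if apex_t > n_left:
            tri[up] = apex_h * (centers[up] - n_left) / (apex_t - n_left)
        down = (centers > apex_t) & (centers <= m_right)
        if m_right > apex_t:
            tri[down] = apex_h * (m_right - centers[down]) / (m_right - apex_t)
        tri[centers == apex_t] = apex_h
        return float(np.sum((counts - tri) ** 2))

    left_candidates = edges[edges <= centers[peak]]
    right_candidates = edges[edges >= centers[peak]]
    best = None
    for nl in left_candidates:
        for mr in right_candidates:
            err = sse(nl, mr)
            if best is None or err < best[0]:
                best = (err, nl, mr)
    _, n_left, m_right = best
    return float(ti), float(m_right - n_left)


def time_metrics(series) -> TimeDomainMetrics:
    """Compute the time-domain metric set from a corrected RR series."""
    x = _intervals(series)
    if x.size < 2:
        raise ValueError("need at least 2 intervals")
    mean_ibi = float(x.mean())
    mean_hr = float(np.mean(60000.0 / x))
    sdnn = float(x.std(ddof=1))
    rmssd = float(np.sqrt(np.mean(np.diff(x) ** 2)))
    if x.size >= 20:
        ti, tinn = triangular_histogram(x)
    else:
        logger.info("series too short for stable TI/TINN (n=%d)", x.size)
        ti, tinn = None, None
    return TimeDomainMetrics(
        mean_ibi=mean_ibi, mean_hr=mean_hr, sdnn=sdnn, rmssd=rmssd, ti=ti, tinn=tinn
    )
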