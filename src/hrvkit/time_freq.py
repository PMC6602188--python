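"""Time-frequency HRV: windowed Burg spectrogram and rLF/HF.

The tachogram is broken into 30 s windows overlapping by 15 s; each
window is mean-removed and given its own order-16 Burg spectrum. The
summary statistic rLF/HF — the ratio of LF to HF ratios — is the
arithmetic mean over windows of the per-window LF/HF ratio (switchable
to the median). Unlike the whole-segment LF/HF it tracks shifts of
sympathovagal balance over time: values above 1 are read as sympathetic
dominance, below 1 as parasympathetic preeminence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .freq_domain import BandPowers, SpectrumEstimate, SpectrumError, band_powers, burg_psd
from .preprocess import UniformTachogram

logger = logging.getLogger(__name__)

__all__ = [
    "TFSpectrogram",
    "TFSummary",
    "windowed_burg",
    "tf_summary",
    "sympathovagal_class",
    "expected_window_count",
]


@dataclass(frozen=True)
class TFSpectrogram:
    window_starts_s: np.ndarray
    spectra: List[Optional[SpectrumEstimate]]  # None marks an unstable window
    window_length_s: float
    overlap_s: float

    @property
    def n_windows(self) -> int:
        return len(self.spectra)

    @property
    def n_valid(self) -> int:
        return sum(s is not None for s in self.spectra)


@dataclass(frozen=True)
class TFSummary:
    lf_abs: float  # ms^2, mean over windows
    hf_abs: float  # ms^2, mean over windows
    nlf: float
    nhf: float
    rlfhf: float


def expected_window_count(duration_s: float, window_s: float, overlap_s: float) -> int:
    """Number of fully contained windows on a hop grid."""
    if duration_s < window_s:
        return 0
    hop = window_s - overlap_s
    return int(math.floor((duration_s - window_s) / hop + 1e-9)) + 1


def windowed_burg(
    tach: UniformTachogram,
    window_s: float = DEFAULT_CONFIG.tf_window_s,
    overlap_s: float = DEFAULT_CONFIG.tf_overlap_s,
    order: int = DEFAULT_CONFIG.spectrum_order,
    n_freq: int = DEFAULT_CONFIG.spectrum_n_freq,
) -> TFSpectrogram:
    """Per-window Burg spectra on an overlapping window grid.

    Windows that do not fit entirely inside the signal are discarded
    (no padding). A window whose AR fit is unstable is kept as ``None``
    and excluded from summaries.
    """
    if not window_s > overlap_s >= 0:
        raise ValueError("need window_s > overlap_s >= 0")
    fs = tach.sample_rate
    n_win = int(round(window_s * fs))
    hop = int(round((window_s - overlap_s) * fs))
    x = np.asarray(tach.samples, float)
    if x.size < n_win:
        raise ValueError(
            f"tachogram spans {x.size / fs:.1f} s, shorter than one {window_s} s window"
        )
    starts, spectra = [], []
    for s0 in range(0, x.size - n_win + 1, hop):
        seg = x[s0 : s0 + n_win]
        seg = seg - seg.mean()
        try:
            spec = burg_psd(seg, sample_rate=fs, order=order, n_freq=n_freq)
        except SpectrumError:
            logger.warning("unstable AR fit in window at %.1f s; excluded", s0 / fs)
            spec = None
        starts.append(tach.start_time_s + s0 / fs)
        spectra.append(spec)
    return TFSpectrogram(
        window_starts_s=np.array(starts),
        spectra=spectra,
        window_length_s=window_s,
        overlap_s=overlap_s,
    )


def tf_summary(
    spectro: TFSpectrogram, config: AnalysisConfig = DEFAULT_CONFIG
) -> TFSummary:
    """Across-window band-power summary and the rLF/HF ratio of ratios.

    Absolute LF/HF are means of per-window band powers; normalized
    powers derive from those means. Windows with zero HF power are
    excluded from rLF/HF with a warning.
    """
    per_window: List[BandPowers] = [
        band_powers(s, config) for s in spectro.spectra if s is not None
    ]
    if not per_window:
        raise ValueError("no valid windows")
    lf_abs = float(np.mean([b.lf for b in per_window]))
    hf_abs = float(np.mean([b.hf for b in per_window]))
    total = lf_abs + hf_abs
    nlf = lf_abs / total if total > 0 else math.nan
    nhf = hf_abs / total if total > 0 else math.nan
    ratios = []
    for i, b in enumerate(per_window):
        if b.hf > 0:
            ratios.append(b.lf / b.hf)
        else:
            logger.warning("window %d has zero HF power; excluded from rLF/HF", i)
    if not ratios:
        rlfhf = math.nan
    elif config.tf_rlfhf_aggregation == "median":
        rlfhf = float(np.median(ratios))
    elif config.tf_rlfhf_aggregation == "mean":
        rlfhf = float(np.mean(ratios))
    else:
        raise ValueError(f"unknown rLF/HF aggregation {config.tf_rlfhf_aggregation!r}")
    return TFSummary(lf_abs=lf_abs, hf_abs=hf_abs, nlf=nlf, nhf=nhf, rlfhf=rlfhf)


def sympathovagal_class(rlfhf: float) -> str:
    """Classify autonomic balance from rLF/HF.

    Above 1 → ``"sympathetic_dominant"``, below 1 →
    ``"parasympathetic_dominant"``, exactly 1 → ``"balanced"``.
    """
    if math.isnan(rlfhf):
        raise ValueError("rLF/HF is undefined")
    if rlfhf > 1:
        return "sympathetic_dominant"
    if rlfhf < 1:
        return "parasympathetic_dominant"
    return "balanced"
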