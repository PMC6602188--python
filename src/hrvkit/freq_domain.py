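"""Frequency-domain HRV: Burg autoregressive spectra and band powers.

The power spectral density of the detrended, uniformly resampled
tachogram is estimated from an autoregressive model fitted with Burg's
reflection-coefficient recursion (order 16 by default). The one-sided
density is evaluated from the AR transfer function,

    S(f) = 2 σ² / fs / |1 − Σ_k a_k e^{−i 2π f k / fs}|²,

so that its integral over [0, Nyquist] approximates the signal
variance (Parseval scaling). Band powers are trapezoidal integrals over
the standard HRV bands — ULF [0, 0.0033), VLF [0.0033, 0.04),
LF [0.04, 0.15), HF [0.15, 0.4] Hz — with normalized powers defined
against LF + HF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.regression.linear_model import burg as _burg_fit

from .config import AnalysisConfig, DEFAULT_CONFIG
from .preprocess import UniformTachogram

__all__ = ["SpectrumEstimate", "BandPowers", "burg_psd", "band_powers", "spectral_profile"]


class SpectrumError(RuntimeError):
    """AR spectral estimation failed (unstable model)."""


@dataclass(frozen=True)
class SpectrumEstimate:
    frequencies: np.ndarray  # Hz, uniform grid on [0, fs/2]
    density: np.ndarray  # ms^2/Hz, one-sided
    ar_order: int
    method: str = "burg"

    @property
    def resolution(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass(frozen=True)
class BandPowers:
    """Band powers in ms² plus normalized quantities.

    ``nlf``/``nhf`` are LF and HF normalized to LF + HF; they are NaN
    (undefined) when LF + HF is zero, as is ``lf_hf`` when HF is zero.
    """

    ulf: float
    vlf: float
    lf: float
    hf: float
    nlf: float
    nhf: float
    lf_hf: float


def burg_psd(
    signal,
    sample_rate: float = DEFAULT_CONFIG.resample_rate_hz,
    order: int = DEFAULT_CONFIG.spectrum_order,
    n_freq: int = DEFAULT_CONFIG.spectrum_n_freq,
) -> SpectrumEstimate:
    """Order-``order`` Burg AR spectrum on a uniform frequency grid.

    Accepts a :class:`UniformTachogram` or a plain array (with
    ``sample_rate``). A zero-variance signal yields an all-zero density.
    """
    if isinstance(signal, UniformTachogram):
        x = np.asarray(signal.samples, float)
        sample_rate = signal.sample_rate
    else:
        x = np.asarray(signal, float)
    if order < 1:
        raise ValueError("order must be >= 1")
    if n_freq < 256:
        raise ValueError("n_freq must be >= 256")
    if x.size <= 2 * order:
        raise ValueError(f"signal length {x.size} must exceed 2 x order ({2 * order})")
    freqs = np.linspace(0.0, sample_rate / 2.0, n_freq)
    if x.var() < 1e-24:
        return SpectrumEstimate(freqs, np.zeros(n_freq), order)
    rho, sigma2 = _burg_fit(x, order=order, demean=True)
    poles = np.roots(np.concatenate([[1.0], -rho]))
    if np.any(np.abs(poles) >= 1.0):
        raise SpectrumError(
            "Burg recursion produced a marginally unstable AR model "
            f"(max pole magnitude {np.abs(poles).max():.6f})"
        )
    k = np.arange(1, order + 1)
    transfer = 1.0 - np.exp(-2j * np.pi * np.outer(freqs / sample_rate, k)) @ rho
    density = 2.0 * sigma2 / sample_rate / np.abs(transfer) ** 2
    return SpectrumEstimate(freqs, density, order)


def _band_integral(spec: SpectrumEstimate, lo: float, hi: float, closed_hi: bool) -> float:
    f, S = spec.frequencies, spec.density
    if closed_hi:
        mask = (f >= lo) & (f <= hi)
    else:
        mask = (f >= lo) & (f < hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(S[mask], f[mask]))


def band_powers(
    spec: SpectrumEstimate, config: AnalysisConfig = DEFAULT_CONFIG
) -> BandPowers:
    """Integrate the spectrum over the four HRV bands.

    Bands are half-open [lo, hi) except HF, closed at its upper edge, so
    no grid point is counted twice.
    """
    if spec.resolution > 0.002:
        raise ValueError(
            f"grid resolution {spec.resolution:.4f} Hz too coarse (need <= 0.002)"
        )
    ulf = _band_integral(spec, *config.bands_ulf, closed_hi=False)
    vlf = _band_integral(spec, *config.bands_vlf, closed_hi=False)
    lf = _band_integral(spec, *config.bands_lf, closed_hi=False)
    hf = _band_integral(spec, *config.bands_hf, closed_hi=True)
    total = lf + hf
    if total > 0:
        nlf, nhf = lf / total, hf / total
    else:
        nlf = nhf = math.nan
    lf_hf = lf / hf if hf > 0 else math.nan
    return BandPowers(ulf=ulf, vlf=vlf, lf=lf, hf=hf, nlf=nlf, nhf=nhf, lf_hf=lf_hf)


def spectral_profile(
    tach: UniformTachogram, config: AnalysisConfig = DEFAULT_CONFIG
) -> BandPowers:
    """Whole-segment frequency-domain profile of a detrended tachogram."""
    spec = burg_psd(tach, order=config.spectrum_order, n_freq=config.spectrum_n_freq)
    return band_powers(spec, config)
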