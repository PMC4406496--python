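"""Linear EEG measures: Welch PSD, band powers, mF, SEF, std, autocorrelation.

The PSD is the Welch average of Hamming-tapered one-second modified
periodograms at 25% overlap (density scaling, taper power corrected), so the
integrated density matches the window variance up to discretization.  Band
powers are trapezoidal areas over the band normalized by the total area over
the analyzed stream's support (0–64 Hz on the 128 Hz stream, 0–150 Hz on the
300 Hz stream); mF is the spectral centroid within the band and SEFxx the
frequency below which xx% of the in-band area lies (linearly interpolated on
the cumulative area to remove the 1 Hz staircase bias).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_io import BandDefinition
from .preprocessing import AnalysisWindow

__all__ = [
    "PSDEstimate",
    "welch_psd",
    "band_power",
    "weighted_mean_frequency",
    "spectral_edge",
    "autocorrelation",
]


@dataclass
class PSDEstimate:
    """Welch power spectral density on a uniform frequency grid (μV²/Hz)."""

    freqs: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < -1e-12):
            raise ValueError("PSD density must be nonnegative")

    @property
    def total_area(self) -> float:
        return float(np.trapezoid(self.density, self.freqs))


def welch_psd(window: AnalysisWindow | np.ndarray, fs: float | None = None
              ) -> PSDEstimate:
    """Welch PSD with 1 s Hamming segments and 25% overlap."""
    if isinstance(window, AnalysisWindow):
        x, fs = window.samples, window.fs
    else:
        x = np.asarray(window, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    nperseg = int(round(fs))
    if len(x) < 2 * nperseg:
        raise ValueError(f"window of {len(x) / fs:.2f} s too short for Welch "
                         "PSD (need >= 2 s)")
    freqs, density = sps.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                               noverlap=nperseg // 4, detrend="constant",
                               scaling="density")
    return PSDEstimate(freqs, density)


def _band_slice(psd: PSDEstimate, f_lo: float, f_hi: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """Frequency/density arrays restricted to [f_lo, f_hi], with interpolated
    edge points so trapezoidal areas are exact at non-grid band edges."""
    f, s = psd.freqs, psd.density
    if f_lo < f[0] or f_hi > f[-1]:
        raise ValueError(f"band [{f_lo}, {f_hi}] outside PSD support "
                         f"[{f[0]}, {f[-1]}]")
    inside = (f > f_lo) & (f < f_hi)
    fb = np.concatenate(([f_lo], f[inside], [f_hi]))
    sb = np.concatenate(([np.interp(f_lo, f, s)], s[inside],
                         [np.interp(f_hi, f, s)]))
    return fb, sb


def band_power(psd: PSDEstimate, band: BandDefinition) -> float:
    """Fraction of total PSD area inside the band (P_band)."""
    total = psd.total_area
    if total <= 0:
        warnings.warn("zero total power; band power undefined", RuntimeWarning)
        return float("nan")
    fb, sb = _band_slice(psd, band.f_lo, band.f_hi)
    return float(np.trapezoid(sb, fb) / total)


def weighted_mean_frequency(psd: PSDEstimate, band: BandDefinition) -> float:
    """Centroid frequency of the PSD within the band (mF, Hz)."""
    fb, sb = _band_slice(psd, band.f_lo, band.f_hi)
    area = np.trapezoid(sb, fb)
    if area <= 0:
        warnings.warn(f"zero in-band power in {band.name}; mF undefined",
                      RuntimeWarning)
        return float("nan")
    return float(np.trapezoid(fb * sb, fb) / area)


def spectral_edge(psd: PSDEstimate, band: BandDefinition,
                  fraction: float) -> float:
    """Smallest frequency with cumulative in-band area >= fraction of total.

    ``fraction`` is typically 0.50, 0.75 or 0.90 (SEF50/75/90).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    fb, sb = _band_slice(psd, band.f_lo, band.f_hi)
    seg = 0.5 * (sb[1:] + sb[:-1]) * np.diff(fb)
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    if cum[-1] <= 0:
        warnings.warn(f"zero in-band power in {band.name}; SEF undefined",
                      RuntimeWarning)
        return float("nan")
    target = fraction * cum[-1]
    k = int(np.searchsorted(cum, target))
    if k == 0:
        return float(fb[0])
    # linear interpolation in cumulative area between grid points
    frac_seg = (target - cum[k - 1]) / (cum[k] - cum[k - 1])
    return float(fb[k - 1] + frac_seg * (fb[k] - fb[k - 1]))


def autocorrelation(window: AnalysisWindow | np.ndarray,
                    max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation over lags 0..max_lag, Ac(0) = 1."""
    x = window.samples if isinstance(window, AnalysisWindow) else np.asarray(
        window, dtype=float)
    n = len(x)
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the window length")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("constant signal: autocorrelation undefined")
    # FFT-based biased autocovariance
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(spec * np.conj(spec))[: max_lag + 1]
    return acov / denom
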