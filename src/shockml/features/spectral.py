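"""Spectral and time-frequency VF-detection features."""

from __future__ import annotations

import numpy as np

from ..records import FS
from . import constants as C
from .wavelet import dwt_band_energies


def amplitude_spectrum(x: np.ndarray, fs: float = FS) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of the Hamming-windowed segment."""
    w = np.hamming(x.size)
    a = np.abs(np.fft.rfft(x * w))
    f = np.fft.rfftfreq(x.size, 1.0 / fs)
    return f, a


def vfleak(x: np.ndarray) -> float:
    """VF-filter leakage: residual of a comb null at the estimated half mean
    period.  N = round(pi * sum|x| / sum|dx|) samples; leakage =
    sum|x_i + x_{i-N}| / sum(|x_i| + |x_{i-N}|).  Near zero for a pure
    oscillation at the mean frequency, larger for organized rhythms."""
    ax = np.abs(x)
    dn = np.abs(np.diff(x)).sum()
    if dn == 0:
        return 1.0
    half_period = int(np.pi * ax.sum() / dn + 0.5)
    half_period = min(max(half_period, 1), x.size - 1)
    num = np.abs(x[half_period:] + x[:-half_period]).sum()
    den = (ax[half_period:] + ax[:-half_period]).sum()
    return float(num / den) if den > 0 else 1.0


def _dominant_peak(f: np.ndarray, a: np.ndarray) -> float:
    lo, hi = C.PEAK_SEARCH_HZ
    band = (f >= lo) & (f <= hi)
    return float(f[band][np.argmax(a[band])])


def barro(x: np.ndarray, fs: float = FS) -> tuple[float, float, float, float]:
    """Normalized first spectral moment M and the band amplitude ratios
    A1-A3 around the dominant peak F (searched in 0.5-9 Hz):

    * analysis band: 0 < f <= min(20 F, 30 Hz)
    * M  = sum(a f) / (F sum a) over the analysis band
    * A1 = amplitude share below F/2
    * A2 = amplitude share in 0.7 F - 1.4 F
    * A3 = amplitude share in the harmonic bands k F +/- 0.3 F, k = 2..8
    """
    f, a = amplitude_spectrum(x, fs)
    F = _dominant_peak(f, a)
    cap = min(C.SPECTRUM_CAP_FACTOR * F, C.SPECTRUM_CAP_HZ)
    band = (f > 0) & (f <= cap)
    fa, aa = f[band], a[band]
    total = aa.sum()
    if total == 0:
        return 0.0, 0.0, 0.0, 0.0
    m = float((aa * fa).sum() / (F * total))
    a1 = float(aa[fa <= F / 2].sum() / total)
    lo, hi = C.A2_BAND_FACTORS
    a2 = float(aa[(fa >= lo * F) & (fa <= hi * F)].sum() / total)
    harm = np.zeros(fa.size, dtype=bool)
    for k in C.A3_HARMONICS:
        harm |= (fa >= (k - C.A3_HALF_WIDTH) * F) & (fa <= (k + C.A3_HALF_WIDTH) * F)
    a3 = float(aa[harm].sum() / total)
    return m, a1, a2, a3


def band_power_ratios(x: np.ndarray, fs: float = FS) -> tuple[float, float, float]:
    """Relative power (squared amplitude) in three bands over 0.5-30 Hz:
    x3 in the 13-16.5 Hz narrow band, x4 in 6.5-13 Hz, x5 in 16.5-30 Hz."""
    f, a = amplitude_spectrum(x, fs)
    p = a**2

    def rel(lo: float, hi: float) -> float:
        return float(p[(f >= lo) & (f <= hi)].sum())

    total = rel(*C.POWER_TOTAL_BAND)
    if total == 0:
        return 0.0, 0.0, 0.0
    x3 = rel(C.BP_LOW_HZ, C.BP_HIGH_HZ) / total
    x4 = rel(*C.X4_BAND) / total
    x5 = rel(*C.X5_BAND) / total
    return x3, x4, x5


def wavelet_bands(x: np.ndarray) -> tuple[float, float, float]:
    """Wavelet band-energy features from the 6-level db4 decomposition:

    * Li  — energy share of the ~2-7.8 Hz detail bands (VF band)
    * bWT — energy share of the final approximation (baseline, < ~2 Hz)
    * bW  — energy share of the > ~15.6 Hz detail bands
    """
    d, a = dwt_band_energies(x, C.DWT_LEVELS)
    total = d.sum() + a
    if total == 0:
        return 0.0, 0.0, 0.0
    li = float(sum(d[lev - 1] for lev in C.LI_DETAIL_LEVELS) / total)
    bwt = float(a / total)
    bw = float(sum(d[lev - 1] for lev in C.BW_DETAIL_LEVELS) / total)
    return li, bwt, bw
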