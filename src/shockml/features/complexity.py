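"""Complexity and nonlinear-dynamics VF-detection features."""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

from ..records import FS
from . import constants as C


def lz_complexity(b: np.ndarray) -> int:
    """Lempel-Ziv (1976) production complexity of a binary sequence, by the
    Kaspar-Schuster scanning algorithm: number of phrases in the exhaustive
    parsing where each new phrase is the shortest prefix-extension not yet
    seen in the history."""
    s = b.astype(np.int8).tolist()  # plain list: scalar indexing dominates
    n = len(s)
    c, l, i, k, kmax = 1, 1, 0, 1, 1
    while l + k <= n:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
        else:
            kmax = max(k, kmax)
            i += 1
            if i == l:
                c += 1
                l += kmax
                i, k, kmax = 0, 1, 1
            else:
                k = 1
    if k > 1:
        c += 1
    return c


def cm(x: np.ndarray) -> float:
    """Normalized Lempel-Ziv complexity of the mean-binarized segment:
    CM = c(n) * log2(n) / n."""
    b = (x >= x.mean()).astype(np.int8)
    n = b.size
    return lz_complexity(b) * np.log2(n) / n


def binary_features(x: np.ndarray, fs: float = FS) -> tuple[float, float, float]:
    """Statistics of the binary signal b = (|x| >= 0.2 max|x|):

    * abin   — area, the fraction of above-threshold samples
    * Frqbin — rising edges per second
    * CVbin  — coefficient of variation of per-1-s sub-window areas
    """
    ax = np.abs(x)
    mx = ax.max()
    b = (ax >= C.BIN_THRESHOLD * mx).astype(float) if mx > 0 else np.zeros_like(ax)
    abin = float(b.mean())
    rising = int(np.sum((b[1:] == 1) & (b[:-1] == 0)))
    frqbin = rising / (x.size / fs)
    n_win = int(round(C.CVBIN_WIN_S * fs))
    areas = [b[s : s + n_win].mean() for s in range(0, b.size - n_win + 1, n_win)]
    areas = np.asarray(areas)
    cvbin = float(areas.std() / areas.mean()) if areas.mean() > 0 else 0.0
    return cvbin, abin, frqbin


def kurt(x: np.ndarray) -> float:
    """Sample kurtosis m4/m2^2 of the segment amplitudes (Pearson, not
    excess); spiky QRS rhythms are heavy-tailed, VF close to sinusoidal."""
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 == 0:
        return 0.0
    return float(np.mean(d**4) / m2**2)


def _grid_occupancy(u: np.ndarray, v: np.ndarray) -> float:
    """Fraction of visited cells when (u, v) in [0,1]^2 are binned on the
    40x40 grid."""
    bins = C.GRID_BINS
    iu = np.minimum((u * bins).astype(int), bins - 1)
    iv = np.minimum((v * bins).astype(int), bins - 1)
    visited = np.zeros((bins, bins), dtype=bool)
    visited[iu, iv] = True
    return float(visited.sum()) / (bins * bins)


def psr(x: np.ndarray, fs: float = FS) -> float:
    """Phase-space reconstruction occupancy: delay-embed the min-max
    normalized signal with a 0.5-s delay and report the fraction of visited
    cells in a 40x40 grid."""
    tau = int(round(C.PSR_DELAY_S * fs))
    rng = np.ptp(x)
    if rng == 0:
        return 0.0
    u = (x - x.min()) / rng
    return _grid_occupancy(u[:-tau], u[tau:])


def hilb(x: np.ndarray) -> float:
    """Analytic-signal phase-plane occupancy: x(t) against its Hilbert
    transform, each axis normalized by its maximum magnitude, binned on the
    40x40 grid."""
    y = np.imag(hilbert(x))
    mx, my = np.abs(x).max(), np.abs(y).max()
    if mx == 0 or my == 0:
        return 0.0
    u = (x / mx + 1.0) / 2.0
    v = (y / my + 1.0) / 2.0
    return _grid_occupancy(np.clip(u, 0, 1), np.clip(v, 0, 1))


def sampen(x: np.ndarray) -> float:
    """Sample entropy with m = 2 and tolerance r = 0.2 * SD, Chebyshev
    distance, self-matches excluded.  If no template pairs match at either
    length the theoretical cap ln(P) with P the number of template pairs is
    returned."""
    m = C.SAMPEN_M
    r = C.SAMPEN_R * x.std()
    n = x.size
    # Chebyshev template distances built incrementally from the sample
    # distance matrix: D_k[i, j] = max(|x[i+t] - x[j+t]|, t = 0..k-1)
    d1 = np.abs(x[:, None] - x[None, :])
    dm = d1
    for t in range(1, m):
        dm = np.maximum(dm[:-1, :-1], d1[t:, t:])
    # dm[i, j] is now the Chebyshev distance of length-m templates at i, j;
    # both match counts use the first n-m templates so A and B average over
    # the same i range (Richman & Moorman convention)
    nb = n - m
    b = int(np.sum(np.triu(dm[:nb, :nb] <= r, k=1)))
    dm1 = np.maximum(dm[:-1, :-1], d1[m:, m:])
    a = int(np.sum(np.triu(dm1 <= r, k=1)))
    pairs = nb * (nb - 1) / 2
    if a == 0 or b == 0:
        return float(np.log(pairs)) if pairs > 0 else 0.0
    return float(-np.log(a / b))
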