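"""Compact periodized Daubechies-4 filter bank for the wavelet band features.

The transform is the textbook circular-convolution DWT with the orthonormal
8-tap Daubechies scaling filter; the input is zero-padded to the next power of
two so every level halves exactly.  Orthonormality makes the level energies an
exact partition of the padded signal's energy, which is what the band-ratio
features (Li, bWT, bW) consume.
"""

from __future__ import annotations

import numpy as np

# orthonormal Daubechies-4 (8-tap) scaling coefficients, sum = sqrt(2)
DB4_LO = np.array(
    [
        0.23037781330885523,
        0.7148465705525415,
        0.6308807679295904,
        -0.02798376941698385,
        -0.18703481171888114,
        0.030841381835986965,
        0.032883011666982945,
        -0.010597401784997278,
    ]
)
# quadrature mirror: hi[n] = (-1)^n * lo[L-1-n]
DB4_HI = np.array(
    [(-1.0) ** n * DB4_LO[DB4_LO.size - 1 - n] for n in range(DB4_LO.size)]
)


def _analysis_step(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One periodized analysis step: a[k] = sum_n lo[n] x[(2k+n) mod N]."""
    n = a.size
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(DB4_LO.size)[None, :]) % n
    window = a[idx]
    return window @ DB4_LO, window @ DB4_HI


def dwt_band_energies(x: np.ndarray, levels: int) -> tuple[np.ndarray, float]:
    """Detail energies per level (fine to coarse) and the final approximation
    energy, after zero-padding to the next power of two."""
    n = 1 << int(np.ceil(np.log2(x.size)))
    a = np.zeros(n)
    a[: x.size] = x
    d_energies = np.empty(levels)
    for lev in range(levels):
        a, d = _analysis_step(a)
        d_energies[lev] = float(np.sum(d**2))
    return d_energies, float(np.sum(a**2))
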