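"""Independent brute-force oracles for every feature and key procedures.

Each oracle is a straight-line transcription of the published definition,
written with explicit loops and elementary constructs; it deliberately shares
no code path with the package implementation (library primitives like FFT,
Butterworth design and the analytic signal are shared infrastructure, not the
logic under test).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal as sps
from scipy.spatial.distance import cdist

FS = 250


# ---------------------------------------------------------------- temporal


def oracle_tci(x, fs=FS):
    n_stage = int(round(1.0 * fs))
    n_stages = len(x) // n_stage
    ax = [abs(v) for v in x]
    b = [False] * len(x)
    for j in range(n_stages):
        mx = max(ax[j * n_stage : (j + 1) * n_stage])
        if mx > 0:
            for i in range(j * n_stage, (j + 1) * n_stage):
                b[i] = ax[i] >= 0.2 * mx
    pulses = []
    i = 0
    while i < len(b):
        if b[i]:
            j = i
            while j < len(b) and b[j]:
                j += 1
            pulses.append((i, j))
            i = j
        else:
            i += 1
    vals = []
    stages = range(1, n_stages - 1) if n_stages > 2 else range(n_stages)
    for j in stages:
        s0, s1 = j * n_stage, (j + 1) * n_stage
        inside = [p for p in pulses if s0 <= p[0] < s1]
        if not inside:
            vals.append(1000.0)
            continue
        before = [p[1] for p in pulses if p[1] <= s0]
        t1 = (s0 - before[-1]) / fs if before else 1.0
        t2 = (inside[0][0] - s0) / fs
        after = [p[0] for p in pulses if p[0] >= s1]
        t4 = (after[0] - s1) / fs if after else 1.0
        t3 = max((s1 - inside[-1][1]) / fs, 0.0)
        fa = t1 / (t1 + t2) if (t1 + t2) > 0 else 0.5
        fb = t3 / (t3 + t4) if (t3 + t4) > 0 else 0.5
        den = len(inside) - 1 + fa + fb
        vals.append(min(1000.0 / den, 1000.0) if den > 0 else 1000.0)
    return sum(vals) / len(vals)


def oracle_tcsc(x, fs=FS):
    n_win, hop, n_ramp = 3 * fs, fs, fs // 4
    vals = []
    for s in range(0, len(x) - n_win + 1, hop):
        y = []
        for i in range(n_win):
            t = i / fs
            if i < n_ramp:
                w = 0.5 * (1 - math.cos(4 * math.pi * t))
            elif i >= n_win - n_ramp:
                w = 0.5 * (1 - math.cos(4 * math.pi * (n_win - i - 1) / fs))
            else:
                w = 1.0
            y.append(x[s + i] * w)
        mx = max(abs(v) for v in y)
        vals.append(
            sum(1 for v in y if abs(v) / mx > 0.2) / n_win if mx > 0 else 0.0
        )
    return sum(vals) / len(vals)


def oracle_exp(x, fs=FS):
    ax = [abs(v) for v in x]
    im = ax.index(max(ax))
    c = 0
    prev_neg = None
    for i in range(len(x)):
        env = ax[im] * math.exp(-abs(i - im) / (3.0 * fs))
        neg = (ax[i] - env) < 0
        if prev_neg is not None and neg != prev_neg:
            c += 1
        prev_neg = neg
    return c / (len(x) / fs)


def oracle_expmod(x, fs=FS):
    ax = [abs(v) for v in x]
    decay = math.exp(-1.0 / (0.2 * fs))
    env = ax[0]
    count = 0
    lifting = False
    for i in range(1, len(x)):
        env *= decay
        if ax[i] >= env:
            env = ax[i]
            if not lifting:
                count += 1
            lifting = True
        else:
            lifting = False
    return count / (len(x) / fs)


def oracle_mav(x, fs=FS):
    n_win = 2 * fs
    vals = []
    for s in range(0, len(x) - n_win + 1, n_win):
        y = [abs(v) for v in x[s : s + n_win]]
        mx = max(y)
        vals.append(sum(v / mx for v in y) / n_win if mx > 0 else 0.0)
    return sum(vals) / len(vals)


def oracle_counts(x, fs=FS):
    n_ma = int(round(0.04 * fs))
    ax = np.abs(np.asarray(x, float))
    aux = np.convolve(ax, np.ones(n_ma) / n_ma, mode="same").tolist()
    mx = max(aux)
    mean = sum(aux) / len(aux)
    c1 = sum(1 for v in aux if v >= 0.5 * mx)
    c2 = sum(1 for v in aux if v >= mean)
    c3 = sum(1 for v in aux if v <= 0.2 * mx)
    return c1, c2, c3


def oracle_x1_x2(x, fs=FS):
    b, a = sps.butter(2, [13.0, 16.5], btype="bandpass", fs=fs)
    y = [abs(v) for v in sps.filtfilt(b, a, np.asarray(x, float))]
    mx = max(y)
    if mx == 0:
        return 0.0, 0.0
    mean = sum(y) / len(y)
    var = sum((v - mean) ** 2 for v in y) / len(y)
    return mean / mx, math.sqrt(var) / mx


def oracle_bcp(x):
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    mx = max(abs(v) for v in d)
    if mx == 0:
        return 0.0
    return sum(1 for v in d if abs(v) >= 0.5 * mx) / len(d)


# ---------------------------------------------------------------- spectral


def oracle_vfleak(x):
    ax = [abs(v) for v in x]
    num = math.pi * sum(ax)
    den = sum(abs(x[i] - x[i - 1]) for i in range(1, len(x)))
    if den == 0:
        return 1.0
    N = int(num / den + 0.5)
    N = min(max(N, 1), len(x) - 1)
    top = sum(abs(x[i] + x[i - N]) for i in range(N, len(x)))
    bot = sum(ax[i] + ax[i - N] for i in range(N, len(x)))
    return top / bot if bot > 0 else 1.0


def _spectrum(x, fs):
    n = len(x)
    w = [0.54 - 0.46 * math.cos(2 * math.pi * i / (n - 1)) for i in range(n)]
    a = np.abs(np.fft.rfft(np.asarray(x, float) * np.asarray(w)))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    return f.tolist(), a.tolist()


def oracle_barro(x, fs=FS):
    f, a = _spectrum(x, fs)
    best = None
    for fi, ai in zip(f, a):
        if 0.5 <= fi <= 9.0 and (best is None or ai > best[1]):
            best = (fi, ai)
    F = best[0]
    cap = min(20 * F, 30.0)
    fa = [(fi, ai) for fi, ai in zip(f, a) if 0 < fi <= cap]
    total = sum(ai for _, ai in fa)
    if total == 0:
        return 0.0, 0.0, 0.0, 0.0
    m = sum(ai * fi for fi, ai in fa) / (F * total)
    a1 = sum(ai for fi, ai in fa if fi <= F / 2) / total
    a2 = sum(ai for fi, ai in fa if 0.7 * F <= fi <= 1.4 * F) / total
    a3 = (
        sum(
            ai
            for fi, ai in fa
            if any(abs(fi - k * F) <= 0.3 * F for k in range(2, 9))
        )
        / total
    )
    return m, a1, a2, a3


def oracle_band_powers(x, fs=FS):
    f, a = _spectrum(x, fs)
    p = [(fi, ai * ai) for fi, ai in zip(f, a)]
    total = sum(pi for fi, pi in p if 0.5 <= fi <= 30.0)
    if total == 0:
        return 0.0, 0.0, 0.0
    x3 = sum(pi for fi, pi in p if 13.0 <= fi <= 16.5) / total
    x4 = sum(pi for fi, pi in p if 6.5 <= fi <= 13.0) / total
    x5 = sum(pi for fi, pi in p if 16.5 <= fi <= 30.0) / total
    return x3, x4, x5


# orthonormal Daubechies-4 analysis filters (standard published decimals)
_LO = [
    0.23037781330885523, 0.7148465705525415, 0.6308807679295904,
    -0.02798376941698385, -0.18703481171888114, 0.030841381835986965,
    0.032883011666982945, -0.010597401784997278,
]
_HI = [((-1) ** n) * _LO[len(_LO) - 1 - n] for n in range(len(_LO))]


def oracle_wavelet_bands(x):
    n = 1
    while n < len(x):
        n *= 2
    a = [0.0] * n
    for i, v in enumerate(x):
        a[i] = float(v)
    d_energies = []
    for _ in range(6):
        m = len(a)
        approx, detail = [], []
        for k in range(m // 2):
            sa = sd = 0.0
            for t in range(len(_LO)):
                v = a[(2 * k + t) % m]
                sa += _LO[t] * v
                sd += _HI[t] * v
            approx.append(sa)
            detail.append(sd)
        d_energies.append(sum(v * v for v in detail))
        a = approx
    ea = sum(v * v for v in a)
    total = sum(d_energies) + ea
    if total == 0:
        return 0.0, 0.0, 0.0
    li = (d_energies[4] + d_energies[5]) / total
    bwt = ea / total
    bw = (d_energies[0] + d_energies[1] + d_energies[2]) / total
    return li, bwt, bw


# -------------------------------------------------------------- complexity


def oracle_lz(bits) -> int:
    """Exhaustive-history LZ76 parsing via substring membership."""
    s = "".join("1" if v else "0" for v in bits)
    c, i, n = 0, 0, len(s)
    while i < n:
        k = 1
        while i + k <= n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        c += 1
        i += k
    return c


def oracle_cm(x):
    mean = sum(x) / len(x)
    bits = [v >= mean for v in x]
    return oracle_lz(bits) * math.log2(len(x)) / len(x)


def oracle_binary(x, fs=FS):
    ax = [abs(v) for v in x]
    mx = max(ax)
    b = [1.0 if (mx > 0 and v >= 0.2 * mx) else 0.0 for v in ax]
    abin = sum(b) / len(b)
    rising = sum(1 for i in range(1, len(b)) if b[i] == 1 and b[i - 1] == 0)
    frqbin = rising / (len(x) / fs)
    n_win = fs
    areas = [
        sum(b[s : s + n_win]) / n_win for s in range(0, len(b) - n_win + 1, n_win)
    ]
    am = sum(areas) / len(areas)
    if am == 0:
        cv = 0.0
    else:
        var = sum((v - am) ** 2 for v in areas) / len(areas)
        cv = math.sqrt(var) / am
    return cv, abin, frqbin


def oracle_kurt(x):
    mean = sum(x) / len(x)
    m2 = sum((v - mean) ** 2 for v in x) / len(x)
    m4 = sum((v - mean) ** 4 for v in x) / len(x)
    return m4 / m2**2 if m2 > 0 else 0.0


def oracle_psr(x, fs=FS):
    tau = fs // 2
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0.0
    grid = set()
    for i in range(len(x) - tau):
        u = (x[i] - lo) / (hi - lo)
        v = (x[i + tau] - lo) / (hi - lo)
        grid.add((min(int(u * 40), 39), min(int(v * 40), 39)))
    return len(grid) / 1600.0


def oracle_hilb(x):
    y = np.imag(sps.hilbert(np.asarray(x, float))).tolist()
    mx = max(abs(v) for v in x)
    my = max(abs(v) for v in y)
    if mx == 0 or my == 0:
        return 0.0
    grid = set()
    for xi, yi in zip(x, y):
        u = min(max((xi / mx + 1) / 2, 0.0), 1.0)
        v = min(max((yi / my + 1) / 2, 0.0), 1.0)
        grid.add((min(int(u * 40), 39), min(int(v * 40), 39)))
    return len(grid) / 1600.0


def oracle_sampen(x, m=2, r_frac=0.2):
    xa = np.asarray(x, float)
    r = r_frac * xa.std()
    n = xa.size
    tm = np.array([xa[i : i + m] for i in range(n - m)])
    tm1 = np.array([xa[i : i + m + 1] for i in range(n - m)])
    dm = cdist(tm, tm, metric="chebyshev")
    dm1 = cdist(tm1, tm1, metric="chebyshev")
    b = a = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if dm[i, j] <= r:
                b += 1
            if dm1[i, j] <= r:
                a += 1
    pairs = (n - m) * (n - m - 1) / 2
    if a == 0 or b == 0:
        return math.log(pairs) if pairs > 0 else 0.0
    return -math.log(a / b)


# ------------------------------------------------------- composite oracle


def oracle_features(x, fs=FS) -> dict:
    """All 30 raw features from the oracles above, keyed canonically."""
    out = {}
    out["TCI"] = oracle_tci(list(x), fs)
    out["TCSC"] = oracle_tcsc(list(x), fs)
    out["Exp"] = oracle_exp(list(x), fs)
    out["Expmod"] = oracle_expmod(list(x), fs)
    out["MAV"] = oracle_mav(list(x), fs)
    out["Count1"], out["Count2"], out["Count3"] = oracle_counts(list(x), fs)
    out["x1"], out["x2"] = oracle_x1_x2(list(x), fs)
    out["bCP"] = oracle_bcp(list(x))
    out["vFleak"] = oracle_vfleak(list(x))
    out["M"], out["A1"], out["A2"], out["A3"] = oracle_barro(list(x), fs)
    out["x3"], out["x4"], out["x5"] = oracle_band_powers(list(x), fs)
    out["Li"], out["bWT"], out["bW"] = oracle_wavelet_bands(list(x))
    out["CM"] = oracle_cm(list(x))
    out["CVbin"], out["abin"], out["Frqbin"] = oracle_binary(list(x), fs)
    out["Kurt"] = oracle_kurt(list(x))
    out["PSR"] = oracle_psr(list(x), fs)
    out["HILB"] = oracle_hilb(list(x))
    out["SamEn"] = oracle_sampen(list(x))
    return out


# ------------------------------------------------ other procedure oracles


def oracle_filter_gain(freq_hz, fs=FS):
    """Composite magnitude response of the conditioning chain at one
    frequency, from the designed filters (filtfilt stages squared)."""
    w = 2 * math.pi * freq_hz / fs
    ma = abs(sum(math.e ** (-1j * w * k) for k in range(5)) / 5)
    b_hp, a_hp = sps.butter(2, 1.0, btype="highpass", fs=fs)
    b_lp, a_lp = sps.butter(4, 30.0, btype="lowpass", fs=fs)
    _, h_hp = sps.freqz(b_hp, a_hp, worN=[w])
    _, h_lp = sps.freqz(b_lp, a_lp, worN=[w])
    return ma * abs(h_hp[0]) ** 2 * abs(h_lp[0]) ** 2


def oracle_ml_threshold(sh, nsh, grid_points=2000):
    """Dense-grid scan for the density crossing between the class means."""
    from scipy.stats import gaussian_kde

    ksh = gaussian_kde(np.asarray(sh, float), bw_method="silverman")
    kns = gaussian_kde(np.asarray(nsh, float), bw_method="silverman")
    mu_a, mu_b = float(np.mean(sh)), float(np.mean(nsh))
    lo, hi = min(mu_a, mu_b), max(mu_a, mu_b)
    best_t, best_d = None, None
    for g in range(grid_points):
        t = lo + (hi - lo) * g / (grid_points - 1)
        d = abs(float(ksh(t)[0]) - float(kns(t)[0]))
        if best_d is None or d < best_d:
            best_t, best_d = t, d
    return best_t
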