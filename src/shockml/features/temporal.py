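"""Temporal VF-detection features: amplitude, slope and rate descriptors."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from ..records import FS
from . import constants as C


def _runs_of_ones(b: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of ones as half-open (start, end) index pairs."""
    d = np.diff(np.concatenate(([0], b.astype(int), [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def tci(x: np.ndarray, fs: float = FS) -> float:
    """Threshold crossing interval, ms.

    The segment is split into 1-s stages; within each stage the signal is
    binarized at 20% of the stage maximum of |x| and the pulses (runs above
    threshold) are interval-averaged with fractional corrections at the stage
    boundaries: TCI = 1000 / (N - 1 + t1/(t1+t2) + t3/(t3+t4)), with N the
    pulse count in the stage, t1/t2 the times from the last pre-stage pulse to
    the stage start and from the stage start to the first in-stage pulse, and
    t3/t4 their mirror images at the stage end.  A stage without pulses
    contributes the 1000 ms cap.  The feature is the mean over interior
    stages.
    """
    n_stage = int(round(C.TCI_STAGE_S * fs))
    n_stages = x.size // n_stage
    # per-stage binarization, then global pulse list
    b = np.zeros(x.size, dtype=bool)
    ax = np.abs(x)
    for j in range(n_stages):
        sl = slice(j * n_stage, (j + 1) * n_stage)
        mx = ax[sl].max()
        if mx > 0:
            b[sl] = ax[sl] >= C.TCI_THRESHOLD * mx
    pulses = _runs_of_ones(b)
    starts = np.array([p[0] for p in pulses], dtype=float)
    ends = np.array([p[1] for p in pulses], dtype=float)

    def _stage_tci(j: int) -> float:
        s0, s1 = j * n_stage, (j + 1) * n_stage
        inside = (starts >= s0) & (starts < s1)
        N = int(inside.sum())
        if N == 0:
            return C.TCI_CAP_MS
        before = ends[ends <= s0]
        t1 = (s0 - before[-1]) / fs if before.size else C.TCI_STAGE_S
        t2 = (starts[inside][0] - s0) / fs
        after = starts[starts >= s1]
        t4 = (after[0] - s1) / fs if after.size else C.TCI_STAGE_S
        t3 = (s1 - ends[inside][-1]) / fs
        if t3 < 0:  # pulse runs through the stage end
            t3 = 0.0
        frac_a = t1 / (t1 + t2) if (t1 + t2) > 0 else 0.5
        frac_b = t3 / (t3 + t4) if (t3 + t4) > 0 else 0.5
        denom = (N - 1) + frac_a + frac_b
        if denom <= 0:
            return C.TCI_CAP_MS
        return min(1000.0 / denom, C.TCI_CAP_MS)

    interior = range(1, n_stages - 1) if n_stages > 2 else range(n_stages)
    vals = [_stage_tci(j) for j in interior]
    return float(np.mean(vals))


def tcsc(x: np.ndarray, fs: float = FS) -> float:
    """Threshold crossing sample count: mean fraction of samples above a 0.2
    relative threshold in cosine-tapered 3-s sub-windows (1-s hop)."""
    n_win = int(round(C.TCSC_WIN_S * fs))
    hop = int(round(C.TCSC_HOP_S * fs))
    n_ramp = int(round(C.TCSC_TAPER_S * fs))
    t = np.arange(n_win) / fs
    w = np.ones(n_win)
    ramp = 0.5 * (1 - np.cos(4 * np.pi * t[:n_ramp]))
    w[:n_ramp] = ramp
    w[-n_ramp:] = ramp[::-1]
    vals = []
    for s in range(0, x.size - n_win + 1, hop):
        y = x[s : s + n_win] * w
        mx = np.abs(y).max()
        if mx == 0:
            vals.append(0.0)
            continue
        vals.append(float(np.mean(np.abs(y) / mx > C.TCSC_THRESHOLD)))
    return float(np.mean(vals))


def exp_standard(x: np.ndarray, fs: float = FS) -> float:
    """Crossings per second between |x| and a fixed exponential envelope
    decaying (both directions) from the global maximum with a 3-s constant."""
    ax = np.abs(x)
    im = int(np.argmax(ax))
    env = ax[im] * np.exp(-np.abs(np.arange(x.size) - im) / (C.EXP_TAU_S * fs))
    d = ax - env
    neg = d < 0
    crossings = int(np.sum(neg[1:] != neg[:-1]))
    return crossings / (x.size / fs)


def exp_modified(x: np.ndarray, fs: float = FS) -> float:
    """Lifts per second of a resetting exponential envelope: the envelope
    decays with a 0.2-s constant and jumps to |x| whenever |x| reaches it;
    each maximal run of lifting samples counts once."""
    ax = np.abs(x)
    decay = np.exp(-1.0 / (C.EXPMOD_TAU_S * fs))
    env = ax[0]
    lifting = False
    count = 0
    for i in range(1, x.size):
        env *= decay
        if ax[i] >= env:
            env = ax[i]
            if not lifting:
                count += 1
            lifting = True
        else:
            lifting = False
    return count / (x.size / fs)


def mav(x: np.ndarray, fs: float = FS) -> float:
    """Mean absolute value of the max-normalized signal over non-overlapping
    2-s sub-windows, averaged."""
    n_win = int(round(C.MAV_WIN_S * fs))
    vals = []
    for s in range(0, x.size - n_win + 1, n_win):
        y = np.abs(x[s : s + n_win])
        mx = y.max()
        vals.append(float(np.mean(y / mx)) if mx > 0 else 0.0)
    return float(np.mean(vals))


def counts(x: np.ndarray, fs: float = FS) -> tuple[int, int, int]:
    """Raw amplitude-bin counts on the 40-ms moving-averaged |x|:
    count1 = samples >= 0.5*max, count2 = samples >= mean,
    count3 = samples <= 0.2*max.  Normalization to the window size happens in
    the feature transform stage."""
    n_ma = max(1, int(round(C.COUNT_MA_S * fs)))
    aux = np.convolve(np.abs(x), np.ones(n_ma) / n_ma, mode="same")
    mx = aux.max()
    c1 = int(np.sum(aux >= C.COUNT1_LO * mx))
    c2 = int(np.sum(aux >= aux.mean()))
    c3 = int(np.sum(aux <= C.COUNT3_HI * mx))
    return c1, c2, c3


def narrowband(x: np.ndarray, fs: float = FS) -> np.ndarray:
    """Zero-phase 13-16.5 Hz Butterworth band-pass used by x1/x2."""
    b, a = sps.butter(
        C.BP_ORDER, [C.BP_LOW_HZ, C.BP_HIGH_HZ], btype="bandpass", fs=fs
    )
    return sps.filtfilt(b, a, x)


def x1_x2(x: np.ndarray, fs: float = FS) -> tuple[float, float]:
    """Amplitude-distribution statistics of the narrow band-passed signal:
    mean and SD of |y| relative to its maximum."""
    y = np.abs(narrowband(x, fs))
    mx = y.max()
    if mx == 0:
        return 0.0, 0.0
    return float(y.mean() / mx), float(y.std() / mx)


def bcp(x: np.ndarray) -> float:
    """Slope-peak fraction: share of first-difference samples whose magnitude
    reaches half the maximum slope.  High for oscillatory VF, low for rhythms
    whose slope is concentrated in sparse QRS complexes."""
    d = np.diff(x)
    mx = np.abs(d).max()
    if mx == 0:
        return 0.0
    return float(np.mean(np.abs(d) >= C.BCP_THRESHOLD * mx))
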