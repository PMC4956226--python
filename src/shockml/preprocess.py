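"""ECG conditioning, segmentation and shock/no-shock labelling.

The conditioning chain reproduces the monitor bandwidth used by defibrillation
analysis algorithms (≈1–30 Hz): mean subtraction, a 5-tap moving average, a
1 Hz Butterworth high-pass for baseline-drift suppression and a 30 Hz 4th-order
Butterworth low-pass.  The IIR stages run forward-backward so that segment
morphology is not phase-skewed.  Input at 500 Hz is first decimated to the
250 Hz working rate behind an anti-alias filter.

Labelling follows standard rhythm-annotation practice for automated external
defibrillator testing: analysis windows must contain a single rhythm; noise,
asystole-level activity (peak-to-peak < 100 µV or rate < 12 bpm), fine VF
(peak-to-peak < 200 µV) and slow VT (< 150 bpm) are excluded as intermediate
or non-analyzable rhythms before the shockable / non-shockable decision.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import (
    FS,
    NSH,
    SH,
    NONSHOCKABLE_RHYTHMS,
    EcgRecord,
    EcgSegment,
    InvalidInputError,
)

# exclusion thresholds (µV, bpm); amplitude rules are applied to the
# preprocessed signal by default (configurable at the call site)
FINE_VF_UV = 200.0
ASYSTOLE_UV = 100.0
ASYSTOLE_BPM = 12.0
SLOW_VT_BPM = 150.0

_MA_TAPS = 5  # moving-average length, samples
_HP_ORDER, _HP_FC = 2, 1.0  # high-pass: order, cutoff Hz
_LP_ORDER, _LP_FC = 4, 30.0  # low-pass: order, cutoff Hz


def _design_filters(fs: float):
    b_hp, a_hp = sps.butter(_HP_ORDER, _HP_FC, btype="highpass", fs=fs)
    b_lp, a_lp = sps.butter(_LP_ORDER, _LP_FC, btype="lowpass", fs=fs)
    return (b_hp, a_hp), (b_lp, a_lp)


def preprocess(signal: np.ndarray, fs: float) -> np.ndarray:
    """Condition a raw ECG to the 250 Hz, ≈1–30 Hz analysis band.

    Parameters
    ----------
    signal : array of µV samples.
    fs : input sampling rate, 250 or 500 Hz.

    Returns
    -------
    Filtered signal at 250 Hz, same duration as the input (within resampling
    tolerance).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InvalidInputError("signal must be a non-empty 1-D array")
    if fs <= 0:
        raise InvalidInputError("sampling rate must be positive")
    if fs not in (250, 500):
        raise InvalidInputError("supported input rates are 250 and 500 Hz")
    if fs == 500:
        x = sps.decimate(x, 2, zero_phase=True)

    x = x - x.mean()
    # centred 5-tap moving average (zero phase for a symmetric FIR)
    x = np.convolve(x, np.ones(_MA_TAPS) / _MA_TAPS, mode="same")
    (b_hp, a_hp), (b_lp, a_lp) = _design_filters(FS)
    x = sps.filtfilt(b_hp, a_hp, x)
    x = sps.filtfilt(b_lp, a_lp, x)
    return x


def preprocess_record(record: EcgRecord) -> EcgRecord:
    """Return a copy of ``record`` with conditioned samples at 250 Hz."""
    return EcgRecord(
        patient_id=record.patient_id,
        fs=FS,
        samples=preprocess(record.samples, record.fs),
        annotations=list(record.annotations),
    )


def segment_record(record: EcgRecord, duration: int) -> list[EcgSegment]:
    """Cut a (preprocessed) record into non-overlapping single-rhythm windows.

    Windows are left-aligned within each annotation interval; a trailing
    remainder shorter than ``duration`` is dropped, and no window ever spans
    two annotations.
    """
    if duration not in (4, 8):
        raise InvalidInputError("duration must be 4 or 8 s")
    if record.fs != FS:
        raise InvalidInputError("record must be preprocessed to 250 Hz first")
    n_win = duration * FS
    out: list[EcgSegment] = []
    for ann in record.annotations:
        i0 = int(np.ceil(ann.start * FS - 1e-9))
        i1 = int(np.floor(ann.end * FS + 1e-9))
        for s in range(i0, i1 - n_win + 1, n_win):
            out.append(
                EcgSegment(
                    patient_id=record.patient_id,
                    samples=record.samples[s : s + n_win],
                    duration=duration,
                    source_rhythm=ann.rhythm,
                    vt_rate=ann.vt_rate,
                    start=s / FS,
                )
            )
    return out


def segmentation_audit(record: EcgRecord, duration: int) -> dict:
    """Account for every window of the global tiling of ``record``.

    Tiles the record from t=0 in steps of ``duration`` and classifies each
    window: ``single_rhythm`` (lies inside one annotation), ``transition``
    (intersects more than one annotation or unannotated signal).  Windows
    dropped as sub-duration remainders of annotation intervals are counted
    separately.  This is the audit-trail companion of :func:`segment_record`
    (which aligns windows per annotation, so transition windows are excluded
    by construction).
    """
    if duration not in (4, 8):
        raise InvalidInputError("duration must be 4 or 8 s")
    n = int(record.duration // duration)
    single = transition = 0
    for w in range(n):
        t0, t1 = w * duration, (w + 1) * duration
        inside = any(
            ann.start <= t0 + 1e-9 and t1 <= ann.end + 1e-9
            for ann in record.annotations
        )
        if inside:
            single += 1
        else:
            transition += 1
    remainders = sum(
        1 for ann in record.annotations if (ann.end - ann.start) % duration > 1e-9
    )
    return {
        "windows": n,
        "single_rhythm": single,
        "transition": transition,
        "remainder_intervals": remainders,
    }


def estimate_rate_bpm(samples: np.ndarray, fs: float = FS) -> float:
    """Crude rate estimate: peaks of |x| above 40% of the window maximum with a
    200 ms refractory period, scaled to beats per minute.

    Used only for the asystole / slow-VT exclusion logic; annotated VT rates
    take precedence when present.
    """
    x = np.abs(np.asarray(samples, dtype=float))
    if x.size == 0:
        raise InvalidInputError("empty signal")
    mx = x.max()
    if mx <= 0:
        return 0.0
    distance = max(1, int(round(0.2 * fs)))
    peaks, _ = sps.find_peaks(x, height=0.4 * mx, distance=distance)
    return len(peaks) / (x.size / fs) * 60.0


@dataclass
class LabelAudit:
    """Per-reason accounting of what the exclusion rules did."""

    retained: int = 0
    excluded: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {"retained": self.retained, "excluded": dict(self.excluded)}


def label_and_filter(
    segments: list[EcgSegment],
    *,
    amplitude_on_raw: bool = False,
    raw_windows: list[np.ndarray] | None = None,
) -> tuple[list[EcgSegment], LabelAudit]:
    """Apply the exclusion rules and attach shock/no-shock labels.

    Exclusions, in order of precedence: annotated noise; asystole-level
    windows (peak-to-peak < 100 µV or estimated rate < 12 bpm); fine VF
    (peak-to-peak < 200 µV); slow VT (rate < 150 bpm).  Retained segments are
    labelled +1 for VF/VT and -1 for organized non-shockable rhythms.  An
    annotation label outside the known set raises; nothing is dropped
    silently — every exclusion is tallied in the returned audit.

    ``amplitude_on_raw`` switches the peak-to-peak thresholds to caller-
    provided raw windows instead of the filtered samples.
    """
    if amplitude_on_raw and (
        raw_windows is None or len(raw_windows) != len(segments)
    ):
        raise InvalidInputError("raw_windows must parallel segments")
    retained: list[EcgSegment] = []
    audit = LabelAudit()
    for i, seg in enumerate(segments):
        rhythm = seg.source_rhythm
        amp_src = raw_windows[i] if amplitude_on_raw else seg.samples
        p2p = float(np.ptp(amp_src))
        if rhythm == "NOISE":
            audit.excluded["noise"] += 1
            continue
        if rhythm == "AS":
            audit.excluded["AS"] += 1
            continue
        if rhythm not in NONSHOCKABLE_RHYTHMS and rhythm not in ("VF", "VT"):
            raise InvalidInputError(f"unknown rhythm label {rhythm!r}")
        if p2p < ASYSTOLE_UV or estimate_rate_bpm(seg.samples) < ASYSTOLE_BPM:
            audit.excluded["AS"] += 1
            continue
        if rhythm == "VF":
            if p2p < FINE_VF_UV:
                audit.excluded["fine VF"] += 1
                continue
            seg.label = SH
        elif rhythm == "VT":
            rate = seg.vt_rate if seg.vt_rate is not None else estimate_rate_bpm(
                seg.samples
            )
            if rate < SLOW_VT_BPM:
                audit.excluded["slow VT"] += 1
                continue
            seg.label = SH
        else:
            seg.label = NSH
        retained.append(seg)
        audit.retained += 1
    return retained, audit
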