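"""Core ECG containers: annotated records and fixed-duration labelled segments.

Amplitudes are microvolts throughout; the working sampling rate is 250 Hz.
Rhythm labels follow cardiac-arrest annotation practice: shockable rhythms are
ventricular fibrillation (VF) and rapid ventricular tachycardia (VT at or above
150 bpm, including flutter); non-shockable rhythms are sinus rhythm (NSR),
supraventricular tachycardia (SVT), pulseless electrical activity (PEA), other
pulse-generating rhythms (PR) and miscellaneous organized rhythms (OTHER_NSH);
asystole (AS) and noise are excluded before the shock/no-shock decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FS = 250  # working sampling rate, Hz

RHYTHM_LABELS = frozenset(
    {"VF", "VT", "NSR", "SVT", "PEA", "PR", "AS", "NOISE", "OTHER_NSH"}
)
#: rhythms that map to the shockable class (+1); VT only when rate >= 150 bpm
SHOCKABLE_RHYTHMS = frozenset({"VF", "VT"})
NONSHOCKABLE_RHYTHMS = frozenset({"NSR", "SVT", "PEA", "PR", "OTHER_NSH"})

SH = 1
NSH = -1


class InvalidInputError(ValueError):
    """Raised for empty signals, non-positive sampling rates and similar misuse."""


class DegenerateSegmentError(ValueError):
    """Raised when a feature is requested on a zero-variance segment."""


@dataclass(frozen=True)
class RhythmInterval:
    """Single-rhythm annotation interval, half-open [start, end) in seconds."""

    start: float
    end: float
    rhythm: str
    #: annotated ventricular rate in bpm; only meaningful for VT intervals
    vt_rate: float | None = None

    def __post_init__(self) -> None:
        if self.rhythm not in RHYTHM_LABELS:
            raise InvalidInputError(f"unknown rhythm label {self.rhythm!r}")
        if not self.end > self.start:
            raise InvalidInputError("annotation interval must have positive length")


@dataclass
class EcgRecord:
    """A patient's continuous annotated ECG.

    Invariants checked on construction: positive sampling rate, non-empty
    signal, ordered non-overlapping annotations lying within the record extent.
    """

    patient_id: str
    fs: float
    samples: np.ndarray
    annotations: list[RhythmInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise InvalidInputError("samples must be a non-empty 1-D array")
        if self.fs <= 0:
            raise InvalidInputError("sampling rate must be positive")
        dur = self.duration
        prev_end = 0.0
        for ann in self.annotations:
            if ann.start < prev_end - 1e-9:
                raise InvalidInputError("annotations overlap or are unordered")
            if ann.end > dur + 1e-9:
                raise InvalidInputError("annotation extends beyond record")
            prev_end = ann.end

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs


@dataclass
class EcgSegment:
    """Fixed-duration single-rhythm analysis window at 250 Hz.

    ``label`` is +1 (shockable) or -1 (non-shockable); ``duration`` is 4 or
    8 s and the sample count is exactly ``duration * 250``.
    """

    patient_id: str
    samples: np.ndarray
    duration: int
    source_rhythm: str
    label: int | None = None
    #: annotated rate for VT segments, bpm
    vt_rate: float | None = None
    #: start time of the window within its source record, seconds
    start: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.duration not in (4, 8):
            raise InvalidInputError("segment duration must be 4 or 8 s")
        if self.samples.size != self.duration * FS:
            raise InvalidInputError(
                f"segment must hold exactly {self.duration * FS} samples"
            )

    @property
    def fs(self) -> int:
        return FS
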