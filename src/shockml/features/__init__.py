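"""The 30-feature ECG parametrization for shockable-rhythm detection.

`compute_features` evaluates the raw features on one preprocessed segment;
`transform_features` applies the count normalization and the fixed monotone
log transforms used to de-skew feature histograms; `build_dataset` turns a
list of labelled segments into a `FeatureDataset`; `standardize` learns
zero-mean/unit-variance statistics on the training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..records import FS, DegenerateSegmentError, EcgSegment
from . import complexity, spectral, temporal

#: canonical feature order and spelling (matches the standard reporting order)
FEATURE_NAMES = (
    # temporal
    "TCI", "TCSC", "Exp", "Expmod", "MAV", "Count1", "Count2", "Count3",
    "x1", "x2", "bCP",
    # spectral
    "vFleak", "M", "A1", "A2", "A3", "x3", "x4", "x5", "bWT", "bW",
    # time-frequency
    "Li",
    # complexity
    "CM", "CVbin", "abin", "Frqbin", "Kurt", "PSR", "HILB", "SamEn",
)

#: features divided by the window sample count (raw integer counts)
COUNT_FEATURES = ("Count1", "Count2", "Count3")
#: right-skewed features passed through log1p after count normalization
LOG_TRANSFORMED = ("Kurt", "M", "A1", "x1", "x3", "x5", "Count3")


def compute_features(segment: EcgSegment | np.ndarray, fs: float = FS) -> dict:
    """Raw (untransformed) 30-feature vector for one segment.

    Raises ``DegenerateSegmentError`` on zero-variance input, which upstream
    exclusion rules should already have removed.
    """
    x = segment.samples if isinstance(segment, EcgSegment) else np.asarray(segment, float)
    if x.std() == 0:
        raise DegenerateSegmentError("zero-variance segment")
    out: dict[str, float] = {}
    out["TCI"] = temporal.tci(x, fs)
    out["TCSC"] = temporal.tcsc(x, fs)
    out["Exp"] = temporal.exp_standard(x, fs)
    out["Expmod"] = temporal.exp_modified(x, fs)
    out["MAV"] = temporal.mav(x, fs)
    out["Count1"], out["Count2"], out["Count3"] = temporal.counts(x, fs)
    out["x1"], out["x2"] = temporal.x1_x2(x, fs)
    out["bCP"] = temporal.bcp(x)
    out["vFleak"] = spectral.vfleak(x)
    out["M"], out["A1"], out["A2"], out["A3"] = spectral.barro(x, fs)
    out["x3"], out["x4"], out["x5"] = spectral.band_power_ratios(x, fs)
    out["Li"], out["bWT"], out["bW"] = spectral.wavelet_bands(x)
    out["CM"] = complexity.cm(x)
    out["CVbin"], out["abin"], out["Frqbin"] = complexity.binary_features(x, fs)
    out["Kurt"] = complexity.kurt(x)
    out["PSR"] = complexity.psr(x, fs)
    out["HILB"] = complexity.hilb(x)
    out["SamEn"] = complexity.sampen(x)
    return out


def transform_features(raw: dict, duration: int) -> dict:
    """Count normalization then the fixed strictly monotone de-skew maps.

    Counts are divided by the window sample count (duration x 250); the seven
    right-skewed nonnegative features get log(1 + v).  Everything else passes
    through bit-identically.
    """
    n = duration * FS
    out = dict(raw)
    for name in COUNT_FEATURES:
        out[name] = out[name] / n
    for name in LOG_TRANSFORMED:
        out[name] = float(np.log1p(out[name]))
    return out


@dataclass
class FeatureDataset:
    """N x 30 feature matrix with per-row patient ids and +/-1 labels."""

    X: pd.DataFrame
    y: np.ndarray
    patients: np.ndarray
    duration: int

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.patients = np.asarray(self.patients)
        assert len(self.X) == self.y.size == self.patients.size

    def __len__(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset_patients(self, patient_ids) -> "FeatureDataset":
        mask = np.isin(self.patients, list(patient_ids))
        return replace(
            self,
            X=self.X.loc[mask].reset_index(drop=True),
            y=self.y[mask],
            patients=self.patients[mask],
        )

    def subset_features(self, names) -> "FeatureDataset":
        return replace(self, X=self.X.loc[:, list(names)].copy())


def build_dataset(segments: list[EcgSegment], duration: int) -> FeatureDataset:
    """Compute, transform and assemble features for labelled segments."""
    rows, ys, pids = [], [], []
    for seg in segments:
        if seg.duration != duration:
            continue
        rows.append(transform_features(compute_features(seg), duration))
        ys.append(seg.label)
        pids.append(seg.patient_id)
    X = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    return FeatureDataset(X, np.asarray(ys), np.asarray(pids), duration)


def standardize(
    train: FeatureDataset, *others: FeatureDataset
) -> tuple[FeatureDataset, ...]:
    """Zero-mean/unit-variance columns using training-set statistics only.

    Population SD convention.  A constant training column carries no
    information: it is mapped to zero everywhere and a warning is emitted.
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    mean = train.X.mean(axis=0)
    sd = train.X.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"constant training columns mapped to 0: {list(sd.index[zero])}",
            stacklevel=2,
        )
        sd = sd.mask(zero, 1.0)
    out = []
    for ds in (train, *others):
        Z = (ds.X - mean) / sd
        Z.loc[:, zero[zero].index] = 0.0
        out.append(replace(ds, X=Z))
    return tuple(out)
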