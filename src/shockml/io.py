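"""Readers and writers for records, segment datasets and feature tables.

The repo's plain-text dialects: a record CSV has columns ``time_s,uv`` plus a
sidecar annotation CSV ``start_s,end_s,rhythm,vt_rate``; feature tables are
CSV with the 30 canonical feature columns plus ``patient_id``, ``duration``
and ``label``.  PhysioNet WFDB reading (for reproduction runs on the public
arrhythmia databases) is available when the optional ``wfdb`` package is
installed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureDataset
from .records import EcgRecord, RhythmInterval


def write_record_csv(record: EcgRecord, path: str | Path) -> None:
    path = Path(path)
    t = np.arange(record.samples.size) / record.fs
    pd.DataFrame({"time_s": t, "uv": record.samples}).to_csv(path, index=False)
    ann = pd.DataFrame(
        [
            {"start_s": a.start, "end_s": a.end, "rhythm": a.rhythm, "vt_rate": a.vt_rate}
            for a in record.annotations
        ]
    )
    ann.to_csv(path.with_suffix(".ann.csv"), index=False)


def read_record_csv(path: str | Path, patient_id: str | None = None) -> EcgRecord:
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[0] < 2:
        raise ValueError("record CSV needs at least two samples")
    fs = 1.0 / float(np.median(np.diff(df["time_s"].to_numpy())))
    ann_path = path.with_suffix(".ann.csv")
    annotations = []
    if ann_path.exists():
        for _, row in pd.read_csv(ann_path).iterrows():
            vt = row.get("vt_rate")
            annotations.append(
                RhythmInterval(
                    start=float(row["start_s"]),
                    end=float(row["end_s"]),
                    rhythm=str(row["rhythm"]),
                    vt_rate=None if pd.isna(vt) else float(vt),
                )
            )
    return EcgRecord(
        patient_id=patient_id or path.stem,
        fs=round(fs),
        samples=df["uv"].to_numpy(dtype=float),
        annotations=annotations,
    )


def read_wfdb_record(record_path: str, rhythm_map: dict | None = None) -> EcgRecord:
    """Read a WFDB record and its rhythm annotations (first channel only).

    Requires the optional ``wfdb`` dependency; rhythm aux labels are mapped
    through ``rhythm_map`` (e.g. ``{"(VF": "VF", "(N": "NSR"}``) and unmapped
    stretches are labelled OTHER_NSH.
    """
    try:
        import wfdb
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError(
            "WFDB reading needs the optional 'wfdb' package (pip install wfdb)"
        ) from err
    rec = wfdb.rdrecord(record_path, channels=[0])
    ann = wfdb.rdann(record_path, "atr")
    fs = float(rec.fs)
    samples = rec.p_signal[:, 0] * 1000.0  # mV -> µV
    rhythm_map = rhythm_map or {}
    intervals: list[RhythmInterval] = []
    bounds = [
        (s / fs, (rhythm_map.get(a.rstrip("\x00"), "OTHER_NSH") if a else None))
        for s, a in zip(ann.sample, ann.aux_note)
        if a
    ]
    for i, (t0, rhythm) in enumerate(bounds):
        t1 = bounds[i + 1][0] if i + 1 < len(bounds) else samples.size / fs
        if t1 > t0 and rhythm:
            intervals.append(RhythmInterval(start=t0, end=t1, rhythm=rhythm))
    return EcgRecord(
        patient_id=Path(record_path).stem, fs=fs, samples=samples, annotations=intervals
    )


def write_segment_table(segments, audit, path: str | Path) -> None:
    """One row per candidate segment: id, duration, label or exclusion."""
    rows = [
        {
            "patient_id": s.patient_id,
            "start_s": s.start,
            "duration": s.duration,
            "rhythm": s.source_rhythm,
            "label": s.label,
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    pd.Series(audit.as_dict()).to_json(Path(path).with_suffix(".audit.json"))


def write_feature_table(ds: FeatureDataset, path: str | Path) -> None:
    df = ds.X.copy()
    df.insert(0, "patient_id", ds.patients)
    df.insert(1, "duration", ds.duration)
    df.insert(2, "label", ds.y)
    df.to_csv(path, index=False)


def write_bootstrap_result(result, path: str | Path) -> None:
    """Per-resample metric table (CSV) plus a summary JSON sidecar.

    The CSV holds one row per defined resample (Se, Sp, BER and the drawn
    patient list), so percentile intervals are reproducible from the file.
    """
    import json

    path = Path(path)
    rows = [
        {
            "resample": i,
            "Se": result.se[i],
            "Sp": result.sp[i],
            "BER": result.ber[i],
            "patients": ";".join(map(str, result.resample_patients[i])),
        }
        for i in range(result.se.size)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    summary = dict(result.summary(), n_undefined=result.n_undefined, **result.meta)
    with open(path.with_suffix(".summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)


def read_feature_table(path: str | Path) -> FeatureDataset:
    df = pd.read_csv(path)
    feature_cols = [c for c in df.columns if c in FEATURE_NAMES] or [
        c for c in df.columns if c not in ("patient_id", "duration", "label")
    ]
    return FeatureDataset(
        X=df[feature_cols].copy(),
        y=df["label"].to_numpy(dtype=int),
        patients=df["patient_id"].to_numpy(dtype=str),
        duration=int(df["duration"].iloc[0]),
    )
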