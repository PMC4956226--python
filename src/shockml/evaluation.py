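"""Performance metrics and patient-wise bootstrap machinery.

Sensitivity (Se) is the detected fraction of shockable segments, specificity
(Sp) the correctly rejected fraction of non-shockable ones, and the balanced
error rate BER = 1 - (Se + Sp)/2 weights both error types equally.  Metrics
are reported in percent; BER is stored via the exact identity so that
``ber == 100 - (se + sp)/2`` holds arithmetically.

Bootstrap resampling is patient-wise: a resample draws N patients with
replacement from the N evaluated patients and pools all their segments
(duplicated patients contribute duplicated segments), so within-patient
dependence is respected.  Paired comparisons share patient draws by
construction (one master seed spawning per-resample substreams).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import NSH, SH


class MetricUndefinedError(ValueError):
    """Raised when a class is absent so Se or Sp (hence BER) is undefined."""


@dataclass(frozen=True)
class MetricSet:
    """Se / Sp / BER in percent."""

    se: float
    sp: float

    @property
    def ber(self) -> float:
        return 100.0 - (self.se + self.sp) / 2.0

    def as_dict(self) -> dict:
        return {"Se": self.se, "Sp": self.sp, "BER": self.ber}


def metrics(labels: np.ndarray, predictions: np.ndarray) -> MetricSet:
    """Se/Sp/BER of +/-1 predictions against +/-1 labels."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    sh = y == SH
    nsh = y == NSH
    if not sh.any() or not nsh.any():
        raise MetricUndefinedError("both classes must be present")
    se = 100.0 * np.mean(p[sh] == SH)
    sp = 100.0 * np.mean(p[nsh] == NSH)
    return MetricSet(float(se), float(sp))


def patient_split(
    patients: np.ndarray, fraction: float = 0.8, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Random patient-level partition: returns (train_ids, test_ids).

    ``fraction`` of the distinct patients go to training; every segment of a
    patient lands on one side by construction.
    """
    ids = np.unique(np.asarray(patients))
    if ids.size == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    n_train = int(round(fraction * ids.size))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclass
class BootstrapResult:
    """Per-resample metric values from patient-wise resampling."""

    se: np.ndarray
    sp: np.ndarray
    resample_patients: list[np.ndarray]
    #: resamples where a class was missing (metrics undefined, excluded)
    n_undefined: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def ber(self) -> np.ndarray:
        return 100.0 - (self.se + self.sp) / 2.0

    def summary(self) -> dict:
        out = {}
        for name, v in (("Se", self.se), ("Sp", self.sp), ("BER", self.ber)):
            out[name] = {
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
                "ci95": [float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))],
            }
        return out


def _resample_draws(patient_ids: np.ndarray, B: int, seed: int) -> list[np.ndarray]:
    """B patient draws with replacement, one independent substream each, so
    two evaluations with the same seed share draws exactly."""
    streams = np.random.SeedSequence(seed).spawn(B)
    n = patient_ids.size
    return [
        patient_ids[np.random.default_rng(s).integers(0, n, size=n)] for s in streams
    ]


def bootstrap_metrics(
    labels: np.ndarray,
    predictions: np.ndarray,
    patients: np.ndarray,
    B: int = 500,
    seed: int = 0,
) -> BootstrapResult:
    """Patient-wise bootstrap distribution of Se/Sp/BER for fixed predictions.

    Resamples with an absent class are recorded as undefined and excluded
    from the returned arrays (their count is kept).
    """
    y = np.asarray(labels)
    p = np.asarray(predictions)
    pids = np.asarray(patients)
    unique = np.unique(pids)
    draws = _resample_draws(unique, B, seed)
    # index segments per patient once
    seg_idx = {pid: np.flatnonzero(pids == pid) for pid in unique}
    se_list, sp_list, kept_draws = [], [], []
    n_undef = 0
    for draw in draws:
        idx = np.concatenate([seg_idx[pid] for pid in draw])
        try:
            m = metrics(y[idx], p[idx])
        except MetricUndefinedError:
            n_undef += 1
            continue
        se_list.append(m.se)
        sp_list.append(m.sp)
        kept_draws.append(draw)
    return BootstrapResult(
        se=np.asarray(se_list),
        sp=np.asarray(sp_list),
        resample_patients=kept_draws,
        n_undefined=n_undef,
        meta={"B": B, "seed": seed, "n_patients": unique.size},
    )


@dataclass
class PairedComparison:
    """Distribution of the per-resample metric difference a - b."""

    delta: np.ndarray
    metric: str

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.percentile(self.delta, 2.5)),
            float(np.percentile(self.delta, 97.5)),
        )

    @property
    def significant(self) -> bool:
        lo, hi = self.ci95
        return not (lo <= 0.0 <= hi)


def paired_compare(
    labels: np.ndarray,
    predictions_a: np.ndarray,
    predictions_b: np.ndarray,
    patients: np.ndarray,
    B: int = 500,
    seed: int = 0,
    metric: str = "BER",
) -> PairedComparison:
    """Paired bootstrap comparison on shared patient draws.

    Both prediction sets are evaluated on identical resamples; the difference
    distribution's percentile 95% CI decides significance (significant iff 0
    lies outside).
    """
    ra = bootstrap_metrics(labels, predictions_a, patients, B=B, seed=seed)
    rb = bootstrap_metrics(labels, predictions_b, patients, B=B, seed=seed)
    take = {"Se": lambda r: r.se, "Sp": lambda r: r.sp, "BER": lambda r: r.ber}[metric]
    if ra.se.size != rb.se.size:
        # align: drop resamples undefined for either model by re-evaluating
        # on the intersection of kept draws (identical draw order by seed)
        raise MetricUndefinedError(
            "models disagree on defined resamples; increase test-set size"
        )
    return PairedComparison(delta=take(ra) - take(rb), metric=metric)


def expected_distinct_fraction(n: int) -> float:
    """Closed-form expected fraction of distinct patients in one bootstrap
    resample of size n: 1 - (1 - 1/n)^n (-> 1 - 1/e ~ 0.632)."""
    return 1.0 - (1.0 - 1.0 / n) ** n
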