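"""Synthetic patient-structured ECG corpora.

The generators are phenomenological, not electrophysiological: they produce
signals with the amplitude, spectral and morphological structure the analysis
pipeline cares about, under two population profiles.  ``public_like`` mimics
Holter-database arrhythmia recordings (coarse high-frequency VF, narrow-QRS
organized rhythms at normal rates); ``ohca_like`` mimics ECG seen minutes
into out-of-hospital cardiac arrest (lower VF amplitude and dominant
frequency, bradycardic wide-QRS PEA, more asystole and noise, and a smaller
class-separability margin).  Every generator is bit-reproducible from its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import FS, EcgRecord, InvalidInputError, RhythmInterval


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_vf(duration: float, amplitude: float, f0: float, seed) -> np.ndarray:
    """Ventricular-fibrillation-like oscillation.

    A sum of four sinusoids clustered around a slowly drifting instantaneous
    frequency near ``f0`` (drift bounded to +/-0.2 Hz), with random phase
    offsets, mild second-harmonic content and slow amplitude modulation; no
    isoelectric baseline.  The realized peak-to-peak amplitude is
    ``amplitude`` microvolts up to ~+/-20% seed jitter, and the spectral peak
    stays within +/-0.3 Hz of ``f0``.
    """
    if not 1.5 <= f0 <= 7.0:
        raise InvalidInputError("VF dominant frequency must lie in [1.5, 7] Hz")
    rng = _rng(seed)
    n = int(round(duration * FS))
    t = np.arange(n) / FS
    # bounded random-walk frequency drift, low-pass smoothed
    steps = rng.normal(0, 0.02, size=n)
    drift = np.clip(np.cumsum(steps) / np.sqrt(np.arange(1, n + 1)), -0.2, 0.2)
    drift = np.convolve(drift, np.ones(FS) / FS, mode="same")
    phase = 2 * np.pi * np.cumsum(f0 + drift) / FS
    offsets = rng.uniform(-0.25, 0.25, size=3)
    amps = np.array([1.0, 0.55, 0.35])
    y = np.zeros(n)
    for a, df in zip(amps, np.concatenate(([0.0], offsets[:2]))):
        y += a * np.sin(phase + 2 * np.pi * df * t + rng.uniform(0, 2 * np.pi))
    # mild sharpening harmonic
    y += 0.2 * np.sin(2 * phase + rng.uniform(0, 2 * np.pi))
    am = 1.0 + 0.25 * np.sin(2 * np.pi * rng.uniform(0.3, 1.0) * t + rng.uniform(0, 2 * np.pi))
    y *= am
    jitter = 1.0 + float(np.clip(rng.normal(0, 0.08), -0.2, 0.2))
    return y / np.ptp(y) * amplitude * jitter


def _qrs_kernel(width_ms: float, aberrant: bool, rng: np.random.Generator) -> np.ndarray:
    """Biphasic Gaussian-derivative QRS wavelet; aberrant morphology adds a
    delayed opposite-polarity lobe (wide, notched complex)."""
    sigma = width_ms / 1000.0 / 5.0
    half = int(round(3 * sigma * FS)) + 1
    tt = np.arange(-half, half + 1) / FS
    k = -tt / sigma * np.exp(-(tt**2) / (2 * sigma**2))
    if aberrant:
        shift = int(round(1.5 * sigma * FS))
        k2 = np.roll(k, shift) * -0.6
        k = k + k2
    return k / np.abs(k).max()


def gen_organized(
    duration: float,
    rate_bpm: float,
    qrs_width_ms: float = 90.0,
    aberrant: bool = False,
    seed=None,
    amplitude: float = 1000.0,
    rr_jitter: float = 0.03,
) -> np.ndarray:
    """Organized (QRS-train) rhythm.

    Beats are biphasic Gaussian-derivative wavelets at the requested rate
    with relative RR jitter; narrow-QRS rhythms below 150 bpm also carry
    low-amplitude P/T-like bumps.  The first beat sits at a quarter RR
    interval so the beat count over the window equals rate * duration / 60
    deterministically (e.g. 2 beats in 8 s at 15 bpm).
    """
    if not 10.0 <= rate_bpm <= 250.0:
        raise InvalidInputError("rate must lie in [10, 250] bpm")
    rng = _rng(seed)
    n = int(round(duration * FS))
    rr = 60.0 / rate_bpm
    y = np.zeros(n)
    kernel = _qrs_kernel(qrs_width_ms, aberrant, rng)
    half = kernel.size // 2
    t_beat = 0.25 * rr
    beats = []
    while t_beat < duration:
        beats.append(t_beat)
        t_beat += rr * (1.0 + rr_jitter * float(np.clip(rng.normal(), -2, 2)))
    for tb in beats:
        i = int(round(tb * FS))
        lo, hi = i - half, i + half + 1
        klo, khi = max(0, -lo), kernel.size - max(0, hi - n)
        y[max(0, lo) : min(n, hi)] += kernel[klo:khi]
    if not aberrant and rate_bpm < 150:
        t = np.arange(n) / FS
        for tb in beats:
            tc = tb + 0.35 * rr
            y += 0.22 * np.exp(-((t - tc) ** 2) / (2 * 0.05**2))
    return y / max(np.ptp(y), 1e-12) * amplitude


def gen_noise(duration: float, sd: float, seed) -> np.ndarray:
    """Artifact epoch: band-limited Gaussian noise plus baseline wander."""
    rng = _rng(seed)
    n = int(round(duration * FS))
    b, a = sps.butter(2, [1.0, 30.0], btype="bandpass", fs=FS)
    w = sps.filtfilt(b, a, rng.normal(0, 1, size=n))
    w = w / max(w.std(), 1e-12) * sd
    t = np.arange(n) / FS
    wander = 2.0 * sd * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    return w + wander


@dataclass(frozen=True)
class PopulationProfile:
    """Rhythm prevalences and morphology ranges for one study population."""

    name: str
    prevalence: dict
    vf_amp_uv: tuple[float, float]
    vf_f0_hz: tuple[float, float]
    nsh_rate_bpm: tuple[float, float]
    qrs_width_ms: tuple[float, float]
    aberrant_prob: float
    organized_amp_uv: tuple[float, float]
    noise_sd_uv: float
    noise_epoch_prob: float
    transition_prob: float
    #: 0 < separability <= 1; smaller adds measurement noise (sd/separability)
    separability: float

    def __post_init__(self) -> None:
        total = sum(self.prevalence.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidInputError("prevalences must sum to 1")
        if not 0 < self.separability <= 1:
            raise InvalidInputError("separability must lie in (0, 1]")


PUBLIC_LIKE = PopulationProfile(
    name="public_like",
    prevalence={
        "VF": 0.30, "VT": 0.08, "NSR": 0.34, "SVT": 0.10,
        "PEA": 0.08, "AS": 0.05, "NOISE": 0.05,
    },
    vf_amp_uv=(400.0, 1500.0),
    vf_f0_hz=(3.5, 6.5),
    nsh_rate_bpm=(50.0, 160.0),
    qrs_width_ms=(70.0, 110.0),
    aberrant_prob=0.10,
    organized_amp_uv=(800.0, 2000.0),
    noise_sd_uv=15.0,
    noise_epoch_prob=0.06,
    transition_prob=0.10,
    separability=1.0,
)

OHCA_LIKE = PopulationProfile(
    name="ohca_like",
    prevalence={
        "VF": 0.28, "VT": 0.05, "NSR": 0.02, "SVT": 0.07,
        "PEA": 0.33, "PR": 0.10, "AS": 0.10, "NOISE": 0.05,
    },
    vf_amp_uv=(150.0, 600.0),
    vf_f0_hz=(2.0, 4.5),
    nsh_rate_bpm=(10.0, 120.0),
    qrs_width_ms=(80.0, 160.0),
    aberrant_prob=0.40,
    organized_amp_uv=(300.0, 1000.0),
    noise_sd_uv=40.0,
    noise_epoch_prob=0.08,
    transition_prob=0.12,
    separability=0.5,
)

PROFILES = {p.name: p for p in (PUBLIC_LIKE, OHCA_LIKE)}


@dataclass
class SyntheticCorpus:
    """Generated records plus the config needed to regenerate them."""

    records: list[EcgRecord]
    profile: PopulationProfile
    n_patients: int
    records_per_patient: int
    seed: int
    record_duration_s: float
    meta: dict = field(default_factory=dict)


def _patient_params(profile: PopulationProfile, rng: np.random.Generator) -> dict:
    """Persistent per-patient morphology.

    Each patient carries a "hardness" h in [0, 1-separability] that places
    them toward the class-boundary region: VF drifts slow and low-amplitude
    (but clear of the fine-VF exclusion floor) and acquires isolated
    QRS-like complexes, organized rhythm drifts fast, wide and rides a
    fibrillatory baseline — the borderline VF-PEA continuum seen minutes
    into untreated arrest.  With separability 1 every patient is clean; the
    same knob scales the measurement noise, so shrinking it degrades the
    corpus monotonically on both axes.
    """
    # every patient in a degraded population is affected (recordings start
    # minutes after arrest onset), with per-patient severity spread
    h = (1.0 - profile.separability) * float(rng.uniform(0.7, 1.0))
    f0_lo, f0_hi = profile.vf_f0_hz
    rate_lo, rate_hi = profile.nsh_rate_bpm
    amp_lo, amp_hi = profile.vf_amp_uv
    span = amp_hi - amp_lo
    f0_draw = float(rng.uniform(f0_lo, f0_hi))
    rate_draw = float(rng.uniform(rate_lo, rate_hi))
    amp_draw = float(rng.uniform(amp_lo + 0.15 * span, amp_hi))
    return {
        "amp_scale": float(np.exp(rng.normal(0, 0.2))),
        # hardness pulls VF toward the slow end and organized rhythm toward
        # the fast end of their ranges
        "f0": f0_lo + (f0_draw - f0_lo) * (1.0 - h),
        "rate": rate_hi - (rate_hi - rate_draw) * (1.0 - h),
        "qrs_width": float(rng.uniform(*profile.qrs_width_ms)),
        "aberrant": bool(rng.random() < profile.aberrant_prob + h * (1 - profile.aberrant_prob)),
        "vf_amp": amp_draw - (amp_draw - (amp_lo + 0.2 * span)) * 0.7 * h,
        "org_amp": float(rng.uniform(*profile.organized_amp_uv)),
        "hardness": h,
    }


def _gen_rhythm(
    rhythm: str,
    duration: float,
    profile: PopulationProfile,
    pp: dict,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float | None]:
    """Samples plus the annotated VT rate (None for other rhythms)."""
    amp = pp["amp_scale"]
    if rhythm == "VF":
        x = gen_vf(duration, pp["vf_amp"] * amp, pp["f0"], rng)
        h = pp.get("hardness", 0.0)
        if h > 0.05:
            # prolonged untreated VF often shows isolated QRS-like
            # complexes, a classic source of missed shock advisories
            n_qrs = max(1, int(round(duration / 3)))
            kernel = _qrs_kernel(110.0, True, rng) * 2.8 * h * np.ptp(x) / 2
            half = kernel.size // 2
            for _ in range(n_qrs):
                c = int(rng.uniform(half, x.size - half - 1))
                x[c - half : c + half + 1] += kernel
        return x, None
    if rhythm == "VT":
        rate = float(rng.uniform(120.0, 220.0))
        x = gen_organized(
            duration, rate, pp["qrs_width"], aberrant=True, seed=rng,
            amplitude=pp["org_amp"] * amp, rr_jitter=0.02,
        )
        return x, rate
    if rhythm == "SVT":
        rate = float(rng.uniform(150.0, 200.0))
        x = gen_organized(
            duration, rate, 70.0, aberrant=False, seed=rng,
            amplitude=pp["org_amp"] * amp,
        )
        return x, None
    if rhythm in ("NSR", "PEA", "PR"):
        rate = pp["rate"] if rhythm != "NSR" else float(rng.uniform(55.0, 100.0))
        rate = float(np.clip(rate, 10.0, 250.0))
        aberrant = pp["aberrant"] if rhythm == "PEA" else False
        x = gen_organized(
            duration, rate, pp["qrs_width"], aberrant=aberrant, seed=rng,
            amplitude=pp["org_amp"] * amp,
        )
        h = pp.get("hardness", 0.0)
        if rhythm == "PEA" and h > 0.05:
            # borderline VF-PEA: organized complexes riding a fibrillatory
            # low-amplitude oscillation instead of an isoelectric baseline
            fib = gen_vf(duration, 0.9 * h * np.ptp(x), max(pp["f0"], 2.0), rng)
            x = x + fib[: x.size]
        return x, None
    if rhythm == "AS":
        return gen_noise(duration, 12.0, rng), None
    if rhythm == "NOISE":
        return gen_noise(duration, 4.0 * profile.noise_sd_uv + 60.0, rng), None
    raise InvalidInputError(f"unknown rhythm {rhythm!r}")


def gen_corpus(
    profile: PopulationProfile | str,
    n_patients: int,
    records_per_patient: int = 1,
    seed: int = 0,
    record_duration_s: float = 60.0,
) -> SyntheticCorpus:
    """Generate a patient-structured annotated corpus.

    Each patient draws persistent morphology parameters once (amplitude
    scale, VF dominant frequency, preferred rate, QRS shape); each record
    then draws a rhythm from the profile prevalences, with configurable
    chances of a mid-record rhythm transition or an inserted noise epoch.
    Measurement noise with SD ``noise_sd / separability`` is added
    throughout, so lowering the separability knob monotonically blurs the
    classes.
    """
    if isinstance(profile, str):
        profile = PROFILES[profile]
    if n_patients < 2:
        raise InvalidInputError("need at least 2 patients")
    master = np.random.SeedSequence(seed)
    records: list[EcgRecord] = []
    rhythms = sorted(profile.prevalence)
    probs = np.array([profile.prevalence[r] for r in rhythms])
    for p, pseq in enumerate(master.spawn(n_patients)):
        prng = np.random.default_rng(pseq)
        pp = _patient_params(profile, prng)
        pid = f"{profile.name[:3]}{p:03d}"
        for r in range(records_per_patient):
            segments: list[tuple[str, float, float | None]] = []
            rhythm = str(prng.choice(rhythms, p=probs))
            if prng.random() < profile.transition_prob:
                split = float(prng.uniform(0.3, 0.7)) * record_duration_s
                other = str(prng.choice(rhythms, p=probs))
                segments = [(rhythm, split, None), (other, record_duration_s - split, None)]
            elif prng.random() < profile.noise_epoch_prob:
                third = record_duration_s / 3.0
                segments = [(rhythm, third, None), ("NOISE", third, None), (rhythm, third, None)]
            else:
                segments = [(rhythm, record_duration_s, None)]
            samples = []
            annotations = []
            t0 = 0.0
            for rh, dur, _ in segments:
                x, vt_rate = _gen_rhythm(rh, dur, profile, pp, prng)
                samples.append(x)
                # annotation end derived from realized sample count so the
                # intervals tile the record exactly despite rounding
                t1 = t0 + x.size / FS
                annotations.append(
                    RhythmInterval(start=t0, end=t1, rhythm=rh, vt_rate=vt_rate)
                )
                t0 = t1
            x = np.concatenate(samples)
            x = x + prng.normal(
                0, profile.noise_sd_uv / profile.separability, size=x.size
            )
            records.append(
                EcgRecord(patient_id=pid, fs=FS, samples=x, annotations=annotations)
            )
    return SyntheticCorpus(
        records=records,
        profile=profile,
        n_patients=n_patients,
        records_per_patient=records_per_patient,
        seed=seed,
        record_duration_s=record_duration_s,
    )


def make_planted_features(
    n_informative: int = 2,
    n_noise: int = 28,
    patients_per_class: int = 30,
    segments_per_patient: int = 4,
    effect: float = 3.0,
    patient_sd: float = 0.5,
    seed: int = 0,
):
    """Feature-level fixture with patient structure and planted signal.

    Informative columns separate the classes by ``effect`` (in units of the
    within-patient SD); noise columns are pure noise.  Every column carries a
    patient random intercept so intra-patient rows are more alike than
    inter-patient rows, which is what makes patient-wise resampling matter.
    Feature names are ``inf1..`` / ``noise1..``; patients are single-class.
    """
    import pandas as pd

    from .features import FeatureDataset
    from .records import NSH, SH

    rng = np.random.default_rng(seed)
    rows, ys, pids = [], [], []
    K = n_informative + n_noise
    names = [f"inf{j + 1}" for j in range(n_informative)] + [
        f"noise{j + 1}" for j in range(n_noise)
    ]
    for cls, label in (("S", SH), ("N", NSH)):
        for p in range(patients_per_class):
            intercepts = rng.normal(0, patient_sd, size=K)
            for _ in range(segments_per_patient):
                x = intercepts + rng.normal(0, 1, size=K)
                x[:n_informative] += label * effect / 2.0
                rows.append(x)
                ys.append(label)
                pids.append(f"{cls}{p:03d}")
    X = pd.DataFrame(np.asarray(rows), columns=names)
    return FeatureDataset(X, np.asarray(ys), np.asarray(pids), duration=4)
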