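"""Shared fixtures: deterministic preprocessed segments of every rhythm
flavour the feature oracles and property tests exercise."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from shockml.preprocess import preprocess

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from shockml.records import FS
from shockml.synthetic import gen_noise, gen_organized, gen_vf


def _sine(duration, freq, amp=500.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _square(duration, freq, amp=500.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sign(np.sin(2 * np.pi * freq * t))


def _pulse_train(duration, rate_hz, width_s=0.06, amp=800.0, fs=FS):
    """Unipolar pulse train (crude QRS caricature for rate features)."""
    n = int(duration * fs)
    x = np.zeros(n)
    period = int(round(fs / rate_hz))
    half = int(width_s * fs / 2)
    for c in range(period // 2, n, period):
        lo, hi = max(0, c - half), min(n, c + half)
        x[lo:hi] = amp
    return x


@pytest.fixture(scope="session")
def oracle_fixtures():
    """20 deterministic 4-s preprocessed segments spanning VF-like,
    organized, noisy and synthetic waveforms."""
    raw = [
        ("vf_2p5", gen_vf(4, 300, 2.5, seed=11)),
        ("vf_3p5", gen_vf(4, 450, 3.5, seed=12)),
        ("vf_4p5", gen_vf(4, 800, 4.5, seed=13)),
        ("vf_5p5", gen_vf(4, 1200, 5.5, seed=14)),
        ("vf_6p5", gen_vf(4, 600, 6.5, seed=15)),
        ("nsr_60", gen_organized(4, 60, 90, seed=21)),
        ("nsr_90", gen_organized(4, 90, 80, seed=22)),
        ("svt_170", gen_organized(4, 170, 70, seed=23)),
        ("pea_40_wide", gen_organized(4, 40, 150, aberrant=True, seed=24)),
        ("pea_15_wide", gen_organized(4, 15, 160, aberrant=True, seed=25)),
        ("vt_180", gen_organized(4, 180, 130, aberrant=True, seed=26)),
        ("noise_a", gen_noise(4, 120, seed=31)),
        ("noise_b", gen_noise(4, 300, seed=32)),
        ("sine_5hz", _sine(4, 5.0)),
        ("sine_1hz", _sine(4, 1.0)),
        ("sine_3hz_noisy", _sine(4, 3.0) + gen_noise(4, 60, seed=33)),
        ("square_5hz", _square(4, 5.0)),
        ("pulse_2hz", _pulse_train(4, 2.0)),
        ("vf_plus_qrs", gen_vf(4, 500, 4.0, seed=16) + gen_organized(4, 30, 100, seed=27) * 0.5),
        ("mixed_noise_sine", 0.6 * _sine(4, 6.0) + 0.4 * gen_noise(4, 200, seed=34)),
    ]
    return [(name, preprocess(x, FS)) for name, x in raw]


@pytest.fixture(scope="session")
def sine_pair():
    """Equal-amplitude 5 Hz and 1 Hz preprocessed sinusoids, 8 s."""
    return preprocess(_sine(8, 5.0), FS), preprocess(_sine(8, 1.0), FS)


@pytest.fixture(scope="session")
def noise_segment():
    rng = np.random.default_rng(99)
    return preprocess(rng.normal(0, 200, size=8 * FS), FS)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_segment(samples, rhythm="VF", patient="p0", duration=4, label=None, vt_rate=None):
    from shockml.records import EcgSegment

    return EcgSegment(
        patient_id=patient,
        samples=samples,
        duration=duration,
        source_rhythm=rhythm,
        label=label,
        vt_rate=vt_rate,
    )
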