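"""Conditioning chain, segmentation and exclusion-rule behaviour."""

import numpy as np
import pytest

from shockml.preprocess import (
    estimate_rate_bpm,
    label_and_filter,
    preprocess,
    preprocess_record,
    segment_record,
    segmentation_audit,
)
from shockml.records import FS, EcgRecord, InvalidInputError, RhythmInterval
from shockml.synthetic import gen_organized, gen_vf

from .conftest import _sine, make_segment
from .oracles import oracle_filter_gain


class TestFilterChain:
    def test_dc_rejection_is_exact(self):
        """Any constant level is annihilated by mean subtraction + high-pass."""
        out = preprocess(np.full(1000, 137.0), 250)
        assert np.abs(out).max() < 1e-9

    def test_passband_gain_matches_designed_response(self):
        """10 Hz tone comes out with the composite |H_MA H_HP H_LP| gain,
        evaluated numerically from the designed filters."""
        x = _sine(8, 10.0, amp=1.0)
        y = preprocess(x, 250)
        mid = slice(2 * FS, 6 * FS)
        gain = np.sqrt(np.mean(y[mid] ** 2) / np.mean(x[mid] ** 2))
        assert gain == pytest.approx(oracle_filter_gain(10.0), rel=0.01)

    def test_stopband_attenuates_above_cutoff(self):
        """45 Hz sits beyond the 30 Hz low-pass corner."""
        mid = slice(2 * FS, 6 * FS)
        a10 = np.abs(preprocess(_sine(8, 10.0, 1.0), 250)[mid]).max()
        a45 = np.abs(preprocess(_sine(8, 45.0, 1.0), 250)[mid]).max()
        assert a45 < a10

    def test_idempotent_on_band_limited_signal(self):
        """Re-filtering an already conditioned band-limited signal changes
        it by under 2% RMS."""
        x = _sine(8, 3.0) + 0.5 * _sine(8, 4.0) + 0.25 * _sine(8, 5.0)
        once = preprocess(x, 250)
        twice = preprocess(once, 250)
        mid = slice(FS, -FS)  # steady state, clear of filter edge transients
        rel = np.linalg.norm(twice[mid] - once[mid]) / np.linalg.norm(once[mid])
        assert rel < 0.02

    def test_resampling_preserves_duration(self):
        t = np.arange(4000) / 500.0
        out = preprocess(np.sin(2 * np.pi * 5 * t), 500)
        assert out.size == 2000  # 8 s at 250 Hz

    @pytest.mark.parametrize("bad", [np.array([]), np.zeros((2, 2))])
    def test_invalid_signal_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            preprocess(bad, 250)

    def test_invalid_rate_rejected(self):
        with pytest.raises(InvalidInputError):
            preprocess(np.ones(100), -1)
        with pytest.raises(InvalidInputError):
            preprocess(np.ones(100), 360)


def _record(intervals, total_s, patient="p1"):
    rng = np.random.default_rng(7)
    samples = rng.normal(0, 100, size=int(total_s * FS))
    return EcgRecord(
        patient_id=patient,
        fs=FS,
        samples=samples,
        annotations=[RhythmInterval(*iv) for iv in intervals],
    )


class TestSegmentation:
    def test_single_rhythm_minute_gives_fifteen_windows(self):
        rec = _record([(0.0, 60.0, "NSR")], 60.0)
        assert len(segment_record(rec, 4)) == 15

    def test_ten_second_excerpt_ratio(self):
        """A 10-s single-rhythm excerpt yields two 4-s and one 8-s window,
        the 2:1 ratio segment accounting relies on."""
        rec = _record([(0.0, 10.0, "PEA")], 10.0)
        assert len(segment_record(rec, 4)) == 2
        assert len(segment_record(rec, 8)) == 1

    def test_interval_shorter_than_window_yields_nothing(self):
        rec = _record([(0.0, 3.0, "NSR")], 5.0)
        assert segment_record(rec, 4) == []

    def test_windows_never_span_annotations(self):
        rec = _record([(0.0, 6.0, "NSR"), (6.0, 12.0, "VF")], 12.0)
        segs = segment_record(rec, 4)
        # only one window fits in each 6-s interval
        assert [s.source_rhythm for s in segs] == ["NSR", "VF"]
        assert [s.start for s in segs] == [0.0, 6.0]

    def test_windows_disjoint_and_inside_annotations(self):
        rec = _record([(0.0, 17.5, "NSR"), (17.5, 30.0, "SVT")], 30.0)
        segs = segment_record(rec, 4)
        spans = sorted((s.start, s.start + s.duration) for s in segs)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 <= b0
        for s in segs:
            ann = next(a for a in rec.annotations if a.rhythm == s.source_rhythm
                       and a.start <= s.start)
            assert s.start + s.duration <= ann.end + 1e-9

    def test_audit_matches_hand_counts(self):
        """Global tiling of a 24-s record with a transition at 10 s:
        windows [0,4),[4,8) single; [8,12) spans the boundary; [12,16),
        [16,20),[20,24) single."""
        rec = _record([(0.0, 10.0, "NSR"), (10.0, 24.0, "VF")], 24.0)
        audit = segmentation_audit(rec, 4)
        assert audit == {
            "windows": 6,
            "single_rhythm": 5,
            "transition": 1,
            "remainder_intervals": 2,
        }


class TestLabelAndFilter:
    def test_fine_vf_excluded(self):
        seg = make_segment(_sine(4, 5.0, amp=75.0), rhythm="VF")  # 150 µV p2p
        kept, audit = label_and_filter([seg])
        assert kept == [] and audit.excluded["fine VF"] == 1

    def test_slow_vt_excluded_fast_vt_kept(self):
        slow = make_segment(_sine(4, 4.0, amp=400.0), rhythm="VT", vt_rate=140)
        fast = make_segment(_sine(4, 4.0, amp=400.0), rhythm="VT", vt_rate=160)
        kept, audit = label_and_filter([slow, fast])
        assert audit.excluded["slow VT"] == 1
        assert len(kept) == 1 and kept[0].label == 1

    def test_low_amplitude_organized_excluded_as_asystole(self):
        seg = make_segment(_sine(4, 2.0, amp=40.0), rhythm="NSR")  # 80 µV p2p
        kept, audit = label_and_filter([seg])
        assert kept == [] and audit.excluded["AS"] == 1

    def test_noise_and_annotated_asystole_excluded(self):
        segs = [
            make_segment(_sine(4, 3.0, amp=300.0), rhythm="NOISE"),
            make_segment(_sine(4, 3.0, amp=300.0), rhythm="AS"),
        ]
        kept, audit = label_and_filter(segs)
        assert kept == []
        assert audit.excluded["noise"] == 1 and audit.excluded["AS"] == 1

    def test_unknown_rhythm_is_loud(self):
        seg = make_segment(_sine(4, 3.0, amp=300.0), rhythm="VF")
        seg.source_rhythm = "MYSTERY"
        with pytest.raises(InvalidInputError, match="MYSTERY"):
            label_and_filter([seg])

    def test_retained_amplitudes_respect_floors(self, rng):
        """Every retained segment has p2p >= 100 µV; retained VF >= 200 µV."""
        segs = []
        for amp in (60, 120, 250, 600):
            segs.append(make_segment(_sine(4, 4.0, amp=amp / 2), rhythm="VF",
                                     patient=f"v{amp}"))
            segs.append(make_segment(_sine(4, 2.0, amp=amp / 2), rhythm="PEA",
                                     patient=f"p{amp}"))
        kept, _ = label_and_filter(segs)
        for s in kept:
            p2p = np.ptp(s.samples)
            assert p2p >= 100.0
            if s.source_rhythm == "VF":
                assert p2p >= 200.0

    def test_shock_label_mapping(self):
        vf = make_segment(_sine(8, 4.0, amp=400.0), rhythm="VF", duration=8)
        nsr = make_segment(_sine(8, 2.0, amp=400.0), rhythm="NSR", duration=8)
        kept, _ = label_and_filter([vf, nsr])
        assert [s.label for s in kept] == [1, -1]


class TestRateEstimate:
    def test_bradycardia_peak_count(self):
        x = gen_organized(8, 15, 140, aberrant=True, seed=2)
        assert estimate_rate_bpm(x) == pytest.approx(15.0, abs=1.0)

    def test_tachycardia_rate_within_tolerance(self):
        x = gen_organized(8, 160, 80, seed=3)
        assert estimate_rate_bpm(x) == pytest.approx(160.0, abs=5.0)


def test_preprocess_record_keeps_annotations():
    rec = _record([(0.0, 10.0, "VF")], 10.0)
    pre = preprocess_record(rec)
    assert pre.fs == FS
    assert [a.rhythm for a in pre.annotations] == ["VF"]
    assert pre.samples.size == rec.samples.size


def test_vf_generator_segments_survive_exclusions():
    """Coarse generated VF passes the amplitude floor after filtering."""
    x = preprocess(gen_vf(8, 500, 4.0, seed=1), 250)
    seg = make_segment(x, rhythm="VF", duration=8)
    kept, _ = label_and_filter([seg])
    assert len(kept) == 1
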