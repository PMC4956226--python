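"""Synthetic generator contracts: spectral targets, beat counts, corpus
structure, reproducibility and the separability dial."""

from dataclasses import replace

import numpy as np
import pytest

from shockml.features import build_dataset, compute_features
from shockml.preprocess import (
    estimate_rate_bpm,
    label_and_filter,
    preprocess_record,
    segment_record,
)
from shockml.records import FS, InvalidInputError
from shockml.synthetic import (
    OHCA_LIKE,
    PUBLIC_LIKE,
    PopulationProfile,
    gen_corpus,
    gen_organized,
    gen_vf,
    make_planted_features,
)


class TestVfGenerator:
    def test_spectral_peak_tracks_requested_frequency(self):
        x = gen_vf(8, 400, 3.5, seed=1)
        f = np.fft.rfftfreq(x.size, 1 / FS)
        a = np.abs(np.fft.rfft(x * np.hamming(x.size)))
        assert 3.2 <= f[np.argmax(a)] <= 3.8

    def test_amplitude_realized_within_band(self):
        p2ps = [np.ptp(gen_vf(8, 400, 3.5, seed=s)) for s in range(100)]
        assert min(p2ps) >= 300 and max(p2ps) <= 500

    def test_no_isoelectric_baseline(self):
        """VF never sits flat: every 200 ms window keeps excursion."""
        x = gen_vf(8, 400, 4.0, seed=2)
        w = 50
        mins = [np.ptp(x[i : i + w]) for i in range(0, x.size - w, w)]
        assert min(mins) > 0.02 * np.ptp(x)

    def test_bit_reproducible(self):
        assert np.array_equal(gen_vf(4, 300, 5.0, seed=9), gen_vf(4, 300, 5.0, seed=9))

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(InvalidInputError):
            gen_vf(4, 300, 8.5, seed=0)


class TestOrganizedGenerator:
    def test_extreme_bradycardia_beat_count(self):
        """15 bpm over 8 s is exactly two QRS complexes."""
        x = gen_organized(8, 15, 140, aberrant=True, seed=2)
        assert estimate_rate_bpm(x) * 8 / 60 == pytest.approx(2.0, abs=0.01)

    def test_tachycardia_rate_recovered(self):
        x = gen_organized(8, 160, 80, seed=3)
        assert estimate_rate_bpm(x) == pytest.approx(160, abs=5)

    def test_bit_reproducible(self):
        a = gen_organized(4, 75, 100, seed=4)
        b = gen_organized(4, 75, 100, seed=4)
        assert np.array_equal(a, b)

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(InvalidInputError):
            gen_organized(4, 5, 100, seed=0)


def _pipeline_segments(corpus, duration=4):
    segs = []
    for rec in corpus.records:
        segs.extend(segment_record(preprocess_record(rec), duration))
    return label_and_filter(segs)


class TestCorpus:
    def test_all_vf_profile_yields_only_shockable(self):
        prof = replace(
            PUBLIC_LIKE, name="vf_only",
            prevalence={"VF": 1.0}, transition_prob=0.0, noise_epoch_prob=0.0,
        )
        kept, _ = _pipeline_segments(gen_corpus(prof, 6, 1, seed=1, record_duration_s=24))
        assert kept and all(s.label == 1 for s in kept)

    def test_noise_prevalence_reflected_in_exclusions(self):
        """With 20% of records pure noise, about 20% of candidate windows
        are excluded as noise (binomial tolerance)."""
        prof = replace(
            PUBLIC_LIKE, name="noisy",
            prevalence={"VF": 0.5, "NSR": 0.3, "NOISE": 0.2},
            transition_prob=0.0, noise_epoch_prob=0.0,
        )
        corpus = gen_corpus(prof, 20, 2, seed=2, record_duration_s=24)
        kept, audit = _pipeline_segments(corpus)
        total = audit.retained + sum(audit.excluded.values())
        frac = audit.excluded.get("noise", 0) / total
        assert 0.08 <= frac <= 0.35

    def test_corpus_regeneration_is_bit_identical(self):
        a = gen_corpus(OHCA_LIKE, 4, 2, seed=3, record_duration_s=24)
        b = gen_corpus(OHCA_LIKE, 4, 2, seed=3, record_duration_s=24)
        for ra, rb in zip(a.records, b.records):
            assert ra.patient_id == rb.patient_id
            assert np.array_equal(ra.samples, rb.samples)
            assert ra.annotations == rb.annotations

    def test_annotations_tile_records_exactly(self):
        corpus = gen_corpus(OHCA_LIKE, 5, 2, seed=4, record_duration_s=30)
        for rec in corpus.records:
            assert rec.annotations[0].start == 0.0
            for a, b in zip(rec.annotations, rec.annotations[1:]):
                assert a.end == b.start
            assert rec.annotations[-1].end == pytest.approx(rec.duration)

    def test_prevalences_must_sum_to_one(self):
        with pytest.raises(InvalidInputError):
            PopulationProfile(
                name="bad", prevalence={"VF": 0.5, "NSR": 0.4},
                vf_amp_uv=(100, 200), vf_f0_hz=(2, 4), nsh_rate_bpm=(40, 100),
                qrs_width_ms=(80, 120), aberrant_prob=0.1,
                organized_amp_uv=(500, 1000), noise_sd_uv=10.0,
                noise_epoch_prob=0.0, transition_prob=0.0, separability=1.0,
            )

    def test_patient_structure_in_rate_linked_features(self):
        """Within-patient spread of the binary-signal edge rate is smaller
        than the spread across patients (persistent per-patient rates), the
        property that makes patient-wise resampling matter."""
        prof = replace(
            OHCA_LIKE, name="pea_only",
            prevalence={"PEA": 1.0}, transition_prob=0.0, noise_epoch_prob=0.0,
        )
        corpus = gen_corpus(prof, 8, 3, seed=5, record_duration_s=24)
        kept, _ = _pipeline_segments(corpus)
        by_patient: dict = {}
        for s in kept:
            by_patient.setdefault(s.patient_id, []).append(
                compute_features(s)["Frqbin"]
            )
        within = np.mean([np.var(v) for v in by_patient.values() if len(v) > 1])
        between = np.var([np.mean(v) for v in by_patient.values()])
        assert within < between


class TestSeparabilityDial:
    def _ber(self, separability, seed):
        from shockml.classifiers import ModelSpec, fit, predict
        from shockml.evaluation import metrics, patient_split
        from shockml.features import standardize

        prof = replace(PUBLIC_LIKE, name="dial", separability=separability)
        corpus = gen_corpus(prof, 10, 1, seed=seed, record_duration_s=32)
        kept, _ = _pipeline_segments(corpus)
        ds = build_dataset(kept, 4)
        tr_ids, te_ids = patient_split(ds.patients, 0.7, seed=seed)
        train, test = ds.subset_patients(tr_ids), ds.subset_patients(te_ids)
        if len(set(train.y)) < 2 or len(set(test.y)) < 2:
            return None
        train_z, test_z = standardize(train, test)
        model = fit(ModelSpec("L1LR"), {"lam": 0.01}, train_z, seed=0)
        return metrics(test_z.y, predict(model, test_z.X)).ber

    def test_lower_separability_never_helps(self):
        """Across 3 knob levels x 10 seeds, shrinking the separability knob
        never decreases pipeline BER (at most one violation tolerated)."""
        levels = (1.0, 0.4, 0.15)
        violations = comparisons = 0
        for seed in range(10):
            bers = [self._ber(level, seed) for level in levels]
            for hi, lo in zip(bers, bers[1:]):
                if hi is None or lo is None:
                    continue
                comparisons += 1
                if lo < hi - 1e-9:
                    violations += 1
        assert comparisons >= 10
        assert violations <= 1


def test_planted_features_structure():
    ds = make_planted_features(
        n_informative=2, n_noise=3, patients_per_class=5,
        segments_per_patient=2, effect=4.0, seed=0,
    )
    assert len(ds) == 20
    assert ds.feature_names == ["inf1", "inf2", "noise1", "noise2", "noise3"]
    # informative columns separate the class means by roughly the effect
    gap = ds.X["inf1"][ds.y == 1].mean() - ds.X["inf1"][ds.y == -1].mean()
    assert gap > 2.0
    # patients are single-class
    for pid in np.unique(ds.patients):
        assert len(set(ds.y[ds.patients == pid])) == 1
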