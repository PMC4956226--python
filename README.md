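# shockml

Detection of shockable cardiac rhythms — ventricular fibrillation (VF) and
rapid ventricular tachycardia (VT) — from short surface-ECG segments, as a
tested, reusable study pipeline. This is the analysis problem at the heart of
the shock-advice algorithm (SAA) in an automated external defibrillator: given
a 4-s or 8-s artifact-free single-rhythm ECG window, decide shock (+1) or
no-shock (−1), with sensitivity (Se) on shockable rhythms and specificity (Sp)
on non-shockable rhythms held to AHA-style standards.

The package is for biomedical-signal and ML researchers who want to develop or
audit VF-detection features and classifiers with sound evaluation protocol:
patient-level train/test splits, patient-wise bootstrap uncertainty, and
embedded feature selection — all runnable end-to-end on a synthetic ECG
generator, with WFDB/CSV readers for real recordings.

## What it computes

For each conditioned segment **x** (250 Hz, ~1–30 Hz band) a 30-feature
vector is computed — temporal (TCI, TCSC, Exp, Expmod, MAV, Count1–3, x1, x2,
bCP), spectral (vFleak, M, A1–A3, x3–x5, bWT, bW), time–frequency (Li) and
complexity measures (CM, CVbin, abin, Frqbin, Kurt, PSR, HILB, SamEn) — and
fed to five classifiers (L1-regularized logistic regression, bagging, random
forest, boosting, SVM) over a labelled dataset
Z = {(**x**ᵢ, yᵢ)}, yᵢ ∈ {Sh: +1, NSh: −1}.

Performance is summarized by the balanced error rate

    BER = 1 − ½ (Se + Sp),

estimated with **patient-wise bootstrap** (B = 500 resamples drawing N
patients with replacement from the N test patients), and models are compared
with paired bootstrap differences Δθ (significant iff the 95% percentile CI
excludes zero). Feature subsets come from bootstrap recursive elimination
ranked by boosting importance (BSTsel) or |wₖ| of the L1 logistic regression
(L1-LRsel), with the subset size Kₛ chosen by the one-standard-error rule and
the final subset scored by selection frequency.

Segments are labelled under the usual arrest-rhythm conventions: noise,
asystole-level windows (peak-to-peak < 100 µV or < 12 bpm), fine VF
(< 200 µV) and slow VT (< 150 bpm) are excluded before the Sh/NSh decision.

## Worked example

Run the whole protocol on a synthetic arrest-like (OHCA-flavour) population:

```python
from shockml import RunConfig, run_study, report

config = RunConfig(
    source="ohca_like",          # synthetic arrest-like population
    durations=(4,),
    algorithms=("L1LR", "SVM"),
    B=100,                       # evaluation bootstrap resamples
    selection_method="L1LRsel",
    selection_B=10,
    seed=7,
    n_patients=24,
    records_per_patient=2,
    record_duration_s=40.0,
    grids={"L1LR": {"lam": [0.003, 0.01, 0.1]},
           "SVM": {"C": [1.0, 100.0], "gamma": [0.01, 0.1]}},
)
bundle = run_study(config)
print(report(bundle))
```

prints

```
=== 4-s segments ===
  exclusions: {'retained': 422, 'excluded': {'AS': 40, 'noise': 13}}
  L1LRsel: K_s=1 (min at k=5), subset: Count2
  L1LR  Se  95.2  Sp  86.4  BER   9.2
        subset dBER -5.4 (-19.0, +3.7)
  SVM   Se 100.0  Sp  81.0  BER   9.5
        subset dBER -7.4 (-29.0, +4.2)
```

Reading this: of the candidate 4-s windows, 422 survived the exclusion rules
(40 asystole-level, 13 noise). The L1-LR-ranked elimination chose a 1-feature
subset by the one-SE rule (the out-of-bag BER minimum sat at 5 features).
On the held-out test patients the L1LR model detects 95.2% of shockable
segments and rejects 86.4% of non-shockable ones (bootstrap means), a BER of
9.2% — the arrest-like profile is deliberately hard; the same configuration
on `source="public_like"` (Holter-archive flavour) typically lands near BER
0–2%. The `subset dBER` line is the paired subset-vs-all-features comparison
with its 95% CI; here the interval covers zero, so the 1-feature model is
not significantly different from the 30-feature one on this corpus.

The same stages are available individually (`shockml.preprocess`,
`shockml.features`, `shockml.classifiers`, `shockml.evaluation`,
`shockml.selection`, `shockml.synthetic`), and as a CLI:

```bash
shockml simulate --profile ohca_like --n-patients 10 --out recs/
shockml extract-features --records recs/ --duration 4 --out features.csv
shockml select-features --features features.csv --method BSTsel
shockml run-study --config study.json
```

where `study.json` holds the `RunConfig` fields, e.g.

```json
{
  "source": "public_like",
  "durations": [4, 8],
  "algorithms": ["L1LR", "BST", "SVM"],
  "B": 500,
  "selection_method": "BSTsel",
  "selection_B": 50,
  "seed": 42,
  "n_patients": 30,
  "records_per_patient": 2,
  "record_duration_s": 60.0,
  "out_dir": "results/"
}
```

`source` may also name a directory of record CSVs (`time_s,uv` with a
`.ann.csv` annotation sidecar) produced by `simulate` or converted from
WFDB records via `shockml.io.read_wfdb_record`.

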