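# Methods

`shockml` implements a complete shockable-rhythm (Sh: VF and rapid VT vs NSh:
organized non-shockable rhythm) detection study pipeline for short surface-ECG
segments, of the kind used to design and audit shock-advice algorithms in
automated external defibrillators: signal conditioning and AHA-style segment
labelling, a 30-feature parametrization, five classifier harnesses with
patient-grouped model selection, patient-wise bootstrap evaluation, and
bootstrap-embedded recursive feature elimination with a one-standard-error
subset rule. Everything runs end-to-end on a synthetic ECG generator, so the
whole protocol is exercisable and testable without access to clinical
recordings.

## Signal conditioning

Input ECG (µV) at 250 or 500 Hz; 500 Hz input is decimated by 2 behind an
anti-alias filter. The chain is the standard AED monitor bandwidth (~1–30 Hz):

1. mean subtraction;
2. 5-tap centred moving average (smoothing);
3. 1 Hz second-order Butterworth high-pass (drift suppression);
4. 30 Hz 4th-order Butterworth low-pass.

IIR stages run forward–backward (zero phase) so segment morphology is not
skewed. The high-pass is second- rather than first-order: with a first-order
section applied zero-phase, passband droop at 3–6 Hz reaches 4–10%, which
breaks re-filtering stability (we require `preprocess∘preprocess` to agree
with `preprocess` within 2% RMS on band-limited signals, measured away from
the filter edge transients); the second-order section keeps the composite
deviation under ~1.8% across 3–5 Hz while preserving drift suppression.

## Segmentation and labelling

Records carry non-overlapping single-rhythm annotation intervals. Analysis
windows of 4 or 8 s are tiled left-aligned inside each interval (half-open
`[t, t+d)`, trailing remainders dropped), so no window ever spans a rhythm
transition; `segmentation_audit` additionally accounts for the windows a
global tiling would lose to transitions, for hand-checkable bookkeeping.

Exclusion rules, applied in order on the conditioned signal (a switch allows
applying the amplitude rules to raw windows instead):

| rule | threshold | rationale |
|---|---|---|
| noise | annotated | artifact windows are not analyzable |
| asystole-level | peak-to-peak < 100 µV or rate < 12 bpm | handled before the Sh/NSh decision in deployed devices |
| fine VF | VF with peak-to-peak < 200 µV | intermediate rhythm, shock benefit unclear |
| slow VT | VT rate < 150 bpm | intermediate rhythm |

Retained segments get labels +1 (VF, VT ≥ 150 bpm, flutter) and −1 (NSR, SVT,
PEA, PR, other organized rhythms). Unknown rhythm labels raise; every
exclusion is tallied by reason, never silent. The rate used by the exclusion
logic is a simple peak counter (|x| peaks above 40% of the window maximum,
200 ms refractory); annotated VT rates take precedence.

## Features

Thirty features per segment, computed on the conditioned 250 Hz signal. The
constants live in `shockml/features/constants.py`; each block cites the
literature the definition comes from, and every feature is pinned to an
independently coded brute-force oracle at 1e-9 on a 20-fixture bank.

* **Temporal** — TCI (threshold-crossing interval, 1-s stages, 20% relative
  threshold, boundary-fraction corrections); TCSC (fraction above a 0.2
  relative threshold in cosine-tapered 3-s sub-windows); Exp (crossings of a
  3-s-constant exponential envelope anchored at the global maximum); Expmod
  (lift events of a resetting 0.2-s envelope); MAV (mean absolute value of
  max-normalized 2-s sub-windows); Count1–3 (amplitude bins of the 40-ms
  smoothed |x|: ≥0.5·max, ≥mean, ≤0.2·max — raw counts, normalized later);
  x1, x2 (mean and SD of the 13–16.5 Hz band-passed |signal| relative to its
  maximum); bCP (fraction of slope samples ≥ half the maximum slope).
* **Spectral** — vFleak (VF-filter leakage: comb residual at the estimated
  half mean period); M, A1, A2, A3 (normalized first spectral moment and
  amplitude shares below F/2, around 0.7–1.4 F, and in harmonic bands
  kF ± 0.3F for k = 2..8, with the dominant peak F searched in 0.5–9 Hz and
  the analysis band capped at min(20 F, 30 Hz)); x3, x4, x5 (relative power
  in 13–16.5, 6.5–13 and 16.5–30 Hz over 0.5–30 Hz); bWT and bW (wavelet
  approximation-band and high-band energy shares).
* **Time–frequency** — Li: energy share of the ~2–7.8 Hz wavelet detail
  bands (the VF band).
* **Complexity** — CM (normalized Lempel–Ziv complexity of the
  mean-binarized signal, Kaspar–Schuster parsing); CVbin/abin/Frqbin
  (coefficient of variation of per-second areas, area, and edge rate of the
  0.2-relative-threshold binary signal); Kurt (sample kurtosis m4/m2²);
  PSR and HILB (fraction of visited cells in a 40×40 occupancy grid of the
  0.5-s delay embedding / the analytic-signal phase plane); SamEn (sample
  entropy, m = 2, r = 0.2·SD, Chebyshev distance, self-matches excluded).

Wavelet features use a compact periodized orthonormal Daubechies-4 filter
bank (zero-padding to the next power of two, 6 levels) written out in the
package so the exact convention is pinned by the oracle tests; orthonormality
makes the band energies an exact partition of signal energy.

Design notes. bCP, bWT and bW are only loosely characterized in the
literature as slope-domain and wavelet baseline/band content measures; the
implementations above are this package's documented readings, swappable at
the function level. Kurt is computed on the ECG samples, not on the binary
signal (the kurtosis of a 0/1 sequence is a deterministic function of its
mean and would duplicate abin). Count bin edges and the x1–x5 statistics are
likewise documented conventions.

After computation, Count1–3 are divided by the window sample count and the
seven right-skewed nonnegative features (Kurt, M, A1, x1, x3, x5, Count3)
pass through log(1+v) — fixed, strictly monotone, order-preserving.
Standardization to zero mean / unit variance (population SD) uses training
rows only; constant training columns are mapped to zero with a warning.

A note on invariances: because every threshold is relative to the segment's
own max/mean/SD, the feature set is amplitude-invariant by design —
discrimination rests on waveform *shape* (sustained oscillation vs sparse
spikes), spectral concentration and complexity, which is exactly what makes
it robust to electrode gain. Frequency-type features (Frqbin, TCI, M) are
covariant with time-axis dilation, asserted as ordering tests on sinusoid
pairs. The naive expectation that a faster sinusoid spends more relative time
above threshold is false (the fraction is frequency-invariant for pure
tones); the discriminative contrast tested is oscillation-vs-QRS-train.

## Classifiers

Five algorithms, optimizers delegated to scikit-learn; the package owns the
protocol: L1-regularized logistic regression (liblinear), bagged trees,
random forest (p = ⌊√K⌋ = 5 features per split at K = 30), AdaBoost-style
boosting of depth-limited trees (exponential reweighting, weighted vote),
and an RBF-kernel SVM. Default tuning grids: λ ∈ 10⁻⁴…10¹ (20 log points);
C ∈ 10⁻²…10³, γ ∈ 10⁻³…10¹; boosting depth {1,2,3} × M {100,300,500};
tree-depth grids for the bagged ensembles scored by out-of-bag BER; B = 300
trees fixed (performance is insensitive once large). Cross-validation is
10-fold *grouped by patient* — no patient ever straddles folds — scored by
balanced error rate. When every validation fold misses a class (which
happens on small corpora where each patient contributes a single rhythm),
the out-of-fold predictions are pooled and scored once instead of averaging
per-fold BERs; tuning raises if even the pooled score is undefined. All estimators are seeded; predictions map decision
scores through sign with ties (score exactly 0) going to +1.

The single-feature maximum-likelihood classifier places its threshold where
the two class-conditional densities cross: Gaussian KDE with Silverman
bandwidth, crossing located as the argmin of |f(x|Sh) − f(x|NSh)| on a
2000-point grid *between the two class means* (a whole-support scan would
find spurious minima in the far tails where both densities vanish); polarity
puts the class with the larger mean above the threshold. Two constant
identical samples have no crossing and raise.

## Evaluation

Se = detected fraction of shockable segments, Sp = correctly rejected
fraction of non-shockable, BER = 100 − (Se+Sp)/2 (percent; the identity is
exact by construction and asserted at print time). Patients are split
80/20 at the patient level. Bootstrap distributions are patient-wise:
each of B = 500 resamples draws N patients with replacement from the N
evaluated patients and pools their segments (duplicates included), which
keeps within-patient dependence intact and leaves ≈ 1−(1−1/N)^N ≈ 63% of
patients distinct per resample. Resamples missing a class are recorded as
undefined and excluded from summaries, never silently dropped. Paired model
comparisons share patient draws by construction (one master seed spawning
per-resample substreams), so a self-comparison is identically zero and
swapping the models negates the difference distribution exactly; the
percentile 2.5/97.5 interval decides significance (significant iff 0 is
outside). BCa intervals were considered and left out: the percentile
interval is what the shared-draw pairing makes exactly reproducible from
the stored resamples.

## Feature selection

`rfe_bootstrap` runs patient-wise bootstrap recursive elimination: per
resample, fit the ranking model (boosting importance for BSTsel, |w_k| for
L1LRsel) on the in-bag patients, drop the least important feature, repeat to
k = 1, scoring every subset size on the out-of-bag patients' segments.
Ranking hyperparameters are tuned once and reused across resamples
(per-resample retuning is configurable but off by default). Resamples whose
in-bag or out-of-bag patients miss a class are redrawn and logged.

The subset size K_s is the smallest whose mean out-of-bag BER lies within
one standard error of the minimum. "Standard error" is the SD of the B
out-of-bag BER values at the minimizing size (the quantity per-size error
bars show); the SD/√B variant is available behind a flag and is always at
least as permissive toward larger subsets. The final subset takes the K_s
features with the highest selection counts (times retained into the size-K_s
survivor set across resamples), ties broken by mean elimination step, then
name. K_s ≤ argmin holds by construction and is asserted property-style.

## Synthetic data

The generator is phenomenological — controllable amplitude/spectral/
morphological structure, not cardiac electrophysiology — because that is
what the analysis consumes.

* `gen_vf`: band-limited stochastic oscillation — four sinusoids clustered
  around a bounded-drift instantaneous frequency near f₀ with random phases,
  a mild second harmonic and slow amplitude modulation; spectral peak within
  ±0.3 Hz of f₀, realized peak-to-peak within ~±20% of the requested µV.
* `gen_organized`: biphasic Gaussian-derivative QRS wavelets at the
  requested rate with RR jitter; low-amplitude T-like bumps for narrow-QRS
  rhythms below 150 bpm; aberrant morphology adds a delayed opposite lobe.
  The first beat sits at RR/4, so beat counts over a window are exact
  (15 bpm ⇒ 2 beats in 8 s).
* `gen_noise`: band-limited Gaussian noise plus 0.3 Hz baseline wander.

Two population profiles fix the study conditions. `public_like` (Holter
archive flavour): VF 400–1500 µV at 3.5–6.5 Hz, organized rhythms 50–160 bpm
with narrow QRS, 15 µV noise, separability 1.0. `ohca_like` (minutes into
untreated arrest): VF 150–600 µV at 2.0–4.5 Hz, PEA-dominant organized
rhythms 10–120 bpm with 40% wide/aberrant QRS, 40 µV noise, separability
0.5. These ranges are package conventions motivated by the phenomenology of
arrest rhythms (VF amplitude and frequency decay over untreated minutes;
PEA is frequently bradycardic wide-QRS or fast pseudo-PEA).

The separability knob (0 < s ≤ 1) is the class-overlap dial: measurement
noise scales as noise_sd/s, and every patient draws a persistent "hardness"
h ∈ (1−s)·[0.7, 1] that moves them toward the class boundary — VF drifts
slow/low-amplitude (kept above the fine-VF exclusion floor so the hard
shockable cases stay in the analyzed set) and acquires isolated QRS-like
complexes; PEA drifts fast/wide and rides a fibrillatory baseline. These
two borderline morphologies are the canonical misclassification modes of
real arrest ECG. Patients persist their morphology parameters across
records, which is what makes intra-patient segments more alike than
inter-patient ones and hence patient-wise resampling meaningful (asserted
directly on generated features).

What the generator does *not* emulate: CPR compression artifacts, electrode
motion transients, 12-lead morphology, device saturation, and true agonal
rhythm dynamics. Passing tests therefore demonstrate that the *pipeline*
behaves correctly and that the qualitative population ordering (arrest-like
harder than Holter-like, needing at least as many features) is reproduced
under the stated conditions — not clinical-grade detector performance.

`make_planted_features` provides feature-level fixtures with patient random
intercepts and a planted class signal, used for classifier sanity ceilings
and selection-recovery tests; the planted effect (2.0 within-patient SDs per
informative feature) is set so one informative feature is genuinely
insufficient and two are nearly sufficient, making subset-size recovery a
real test of the one-SE rule rather than a formality.

## Problem sizes and determinism

Default API sizes mirror the full protocol (B = 500 bootstrap, B = 500
selection resamples, tuning grids above); the study orchestrator's
`RunConfig` defaults to 50 selection resamples as a pragmatic middle ground
for interactive runs. The test suite and the acceptance
script run the same code at desk scale — synthetic corpora of ~24 patients
(2 × 40-s records each), selection bootstraps of 10 resamples, B = 100
evaluation resamples, 4-s windows; B = 500 is kept where the property under
test concerns the resampling distribution itself. Replicated qualitative
checks use 20 seeded replicates. All randomness flows from named
SeedSequence substreams of one master seed; corpora regenerate
bit-identically, and rerunning a study config reproduces every number.

Known limitations: the arrest-like profile's difficulty is synthetic and
calibrated at desk scale, so absolute Se/Sp/BER values are not comparable to
clinical studies; tiny corpora can produce degenerate splits (single-class
test sets), which abort loudly with the failing stage named rather than
being patched over.
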