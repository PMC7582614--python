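# Methods

This note records the models, numerical choices and open-design decisions
behind `ppgbp`, in the order the pipeline runs.

## Synthetic data model

Real pipelines of this kind are trained on ICU waveform corpora in which an
arterial line supplies per-cycle SBP/DBP labels. The package instead ships a
generator whose output has the same *structure* with fully known ground
truth.

Each cardiac cycle of duration T is a sum of two positive Gaussian lobes on
a zero baseline: a systolic lobe of amplitude A centred at 0.28 T (width
0.11 T) and a dicrotic lobe of amplitude A·r centred at 0.62 T (width
0.09 T), where r ∈ (0, 1) is the notch-relative intensity. The dip between
the lobes plays the role of the dicrotic notch. Defaults emulate a clean
125 Hz finger PPG at 75 bpm for 60 s; per-cycle jitter (heart rate sd
3 bpm, relative amplitude sd 0.1, notch-intensity sd 0.08) provides the
morphological variability that drives the labels. Additive nuisance
components: sinusoidal baseline wander (amplitude 0.1, 0.2 Hz — below the
0.5 Hz band where respiration-like drift lives), sinusoidal interference
(amplitude 0.03 at 20 Hz, above the 8 Hz cut) and white noise (sd 0.01).

Labels are an affine map from the per-cycle morphology triple
(heart rate, amplitude, r) to mmHg: by default
SBP = 95 + 0.2·hr + 5·A + 25·r and DBP = 60 + 0.1·hr + 2·A + 12·r, giving
~124/74 mmHg with a few mmHg of spread — a realistic normotensive record.
Optional Gaussian label noise models measurement error. The map's positive
pulse-pressure margin guarantees SBP > DBP; the generator raises if a
custom map violates this. The ABP channel is a per-cycle rescaled copy of
the clean pulse train whose maximum/minimum over the half-open cycle span
equal the mapped SBP/DBP, so label extraction is exactly invertible on
clean data.

Ground-truth fiducials are located on the clean (noise- and wander-free)
pulse train with the same geometric definitions the detector must satisfy
(valley = argmin between consecutive systolic maxima, notch = largest local
maximum of the second derivative between peak and offset). With overlapping
lobe tails the true inter-peak minimum sits a few samples away from the
nominal cycle boundary, so nominal boundaries would be the wrong oracle for
sample-accurate checks.

What the generator does **not** emulate: reflected-wave physiology,
arrhythmia and ectopic beats, motion artefacts, sensor saturation, or
subject-level structure (cycles are exchangeable, so train/test splits leak
no subject identity by construction). Passing tests therefore demonstrate
pipeline correctness — that each stage recovers what the previous stage
encoded — not clinical accuracy on human data.

For regressor tests a second, tabular generator draws equicorrelated
standard-normal features (pairwise correlation 0.3) and maps them affinely
to labels; with zero label noise the task has a zero-error solution, making
convergence targets exact.

## Preprocessing

Band-limiting is a hard spectral gate implemented with the real FFT: bins
with frequency strictly above the cut (default 8 Hz, inclusive bound kept)
are zeroed and the signal restored by the inverse transform. Operating on
the half-spectrum zeroes conjugate pairs together, so the output is exactly
real. The gate is idempotent by construction. No high-pass is applied by
default — the method's stated band starts at 0 Hz — but a configurable low
cut is available, and baseline wander below the high cut otherwise survives
preprocessing (the per-record min–max normalization and the adaptive peak
threshold are what keep detection robust to it). Derivatives use central
differences with one-sided ends (`np.gradient`), scaled to per-second
units; the scheme is second-order accurate at no extra cost.

Min–max normalization rejects constant segments explicitly rather than
returning NaNs.

## Fiducial detection

Systolic peaks: candidate regions are maximal runs where the normalized PPG
strictly exceeds its centred moving average (window 0.75 s); each region's
argmax is a candidate. Two guards make this robust on realistic shapes:
candidates whose excess over the moving average is below half the
90th-percentile excess are dropped (dicrotic waves can poke above the
average on slow rhythms), and candidates closer than 0.33 s (180 bpm) are
merged keeping the taller. Valleys are the argmin strictly between
consecutive peaks; all argmin/argmax ties resolve to the earliest index for
determinism. The notch is the largest sdPPG local maximum strictly between
peak and offset (earliest among equals); a cycle with no such local maximum
is flagged notch-absent rather than given a fabricated landmark.

Cycle spans are half-open `[onset, next_onset)` in 0-based record
coordinates; stored fragments include the closing valley sample so the
offset landmark is addressable. Plausibility bounds for abnormal-cycle
removal (SBP ∈ [80, 180], DBP ∈ [60, 130], pulse pressure ≥ 20 mmHg,
duration ∈ [0.33, 2] s, complete ordered fiducials) are explicit stand-ins
for the prescreening conventions of the ICU-corpus literature and are fully
configurable; every rule is evaluated on every cycle, so the surviving set
is independent of rule order and the removal log attributes each dropped
cycle to every rule it violated.

## Features

Times are index differences over f_s; slopes are intensity differences over
time differences between the named landmarks; areas are trapezoidal
integrals of the named signal (normalized intensity × seconds). t1–t4 are
the durations of the spans bounding S1–S4 (onset → max-slope → peak →
notch → offset): this is the only reading under which
RSD = (t1+t2+t3)/t4 and the systolic/diastolic duty-cycle ratios
RSC + RDC = 1 are dimensionally coherent. Derivative-signal features use
that signal's own cycle-local landmarks (fragment argmax/argmin), the only
anchors available on dPPG/sdPPG; t5/t7 are the dPPG/sdPPG ascending
durations and t6/t8 the descending ones. Notch-dependent features are NaN
when the notch is absent, as is any ratio with a vanishing denominator;
cycles with missing values among the candidate features are dropped (and
counted) before training, since the network needs complete vectors.

Standardization uses the population sd (ddof = 0, configurable) and retains
(μ, σ) per feature for exact inversion and for reuse at prediction time.
Z-scores are unbounded; no clipping to [−1, 1] is applied.

## The γ index

γ compares the empirical distribution of a standardized feature with the
standard normal on a fixed grid: step 10⁻ᵏ, span ±C (k = 1, C = 3 → 61
points). The empirical mass at grid label v is the fraction of samples in
the half-open bin [v, v + 10⁻ᵏ) (an epsilon nudge of 10⁻⁹ keeps values
sitting on a bin edge, up to float representation error, in their own bin);
the reference mass is Φ(v+10⁻ᵏ) − Φ(v); γ is the mean absolute difference
over the grid. Mass outside ±C is ignored, not renormalized. This pairing
is the one reading under which γ → 0 on an exact standard-normal sample
(the convergence property the index exists for); pairing rounded-to-v
masses with [v, v+10⁻ᵏ) integrals instead leaves a systematic offset of
~0.0065 that never vanishes. γ requires standardized input (|mean| ≤ 0.05,
|sd − 1| ≤ 0.05) and refuses otherwise; property tests may bypass the check
deliberately.

Selection ranks finite-γ features ascending (ties by name), takes the 32
lowest, and applies balanced overrides — by default force in S1/S2 (low γ,
long-established pressure correlates) in place of sdAS/sdDS. Features with
non-finite γ (the unstable ratio features on the reference corpus) are
hard-excluded from ranking. The reference per-feature γ table from the
~2.17-million-cycle corpus ships in `ppgbp.reference`; the default
overrides reproduce its published 32-feature set exactly, and no overrides
reproduce the plain lowest-32 set.

## Regressor

Architecture: input (32) → 2048 → 4096 → 8192 → 2048 → 2, ReLU on hidden
layers, identity output, per-layer O = act(WI + b). Widths are
configurable; tests and examples use 32/32 networks, which suffice for the
synthetic tasks and keep runtimes in seconds.

Training choices left open by the method description, fixed here and echoed
into the run manifest: loss is MSE over the 2-dim output (same optimum as
RMSE, stabler gradients; RMSE and MAE are the monitored/reported metrics);
"512 batches" is read as mini-batch size 512; Nadam (Adam with Nesterov
momentum) with learning rate 2·10⁻³, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸; He
initialization, zero biases; at most 500 epochs with early stopping on
validation RMSE (patience 10), best-validation weights retained. Inputs
*and targets* are z-scored internally from the training split (predictions
un-scaled to mmHg): without target scaling, an Adam-family step size of
~10⁻³ cannot move the output layer to the ~100 mmHg operating point within
any reasonable budget. Non-finite losses abort with a diagnostic rather
than silently producing NaN weights.

The 70/20/10 split is by cycle, not by subject, mirroring the method's own
procedure; on real multi-subject data this overstates accuracy (cycle-level
leakage), which is why the splitter takes an explicit seed and fractions so
subject-wise protocols can be layered on top.

## Evaluation

error = estimate − truth everywhere, including the Bland–Altman difference;
threshold comparisons are inclusive; sds use the population convention
matching the feature module (configurable ddof). The BHS grade is the best
grade whose three thresholds are all met. Pearson's r is computed from the
deviation-product formula and clipped to [−1, 1] against rounding; it
requires n ≥ 2 and nonzero variances. Every metric is cross-checked in the
test suite against independent loop-based recomputations.

## Problem sizes used in tests

The suite exercises: 1000 random generator configs for the SBP > DBP and
cycle-count invariants (4–8 s records); 100 random noise-free configs at
125 Hz for sample-accurate fiducial recovery (±3 samples); 10⁶-sample
columns for γ convergence; 100 random small networks for forward-pass
oracle equivalence; 1000 random trials for evaluation-report oracle
equivalence; and n = 10⁴ cycles for regressor parameter recovery (reduced
widths 32/32, 200 epochs), where noiseless labels must reach < 1 mmHg
validation RMSE and 3 mmHg label noise must land in [2.4, 3.8] mmHg. The
full suite runs in well under a minute on one CPU.

## Known limitations

- The pulse model has two lobes and no reflected-wave fine structure; notch
  detection on real PPG (flat notches, arrhythmia) is harder than on this
  geometry.
- The published headline accuracy figures of the large-corpus study are not
  reproducible here by construction — they require the external clinical
  database; the package verifies the machinery (grading logic, selection
  logic, estimator convergence), not those numbers.
- The moving-average peak detector assumes a dominant systolic wave per
  cycle; it has no signal-quality index and will produce garbage-in
  garbage-out on severely corrupted records (the abnormal-cycle filter is
  the only backstop).
- Training is single-threaded NumPy; the full-width architecture
  (2048/4096/8192/2048) trains, but at desk scale it is meant for
  demonstration, not large-corpus throughput.
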