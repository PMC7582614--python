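# ppgbp — cuffless blood-pressure estimation from PPG morphology

`ppgbp` implements a complete, testable pipeline for estimating systolic and
diastolic blood pressure (SBP/DBP) from a photoplethysmogram (PPG) alone —
no ECG channel, no cuff. It is aimed at biosignal researchers who want the
classical morphology-feature approach as a reproducible library: every stage
is an importable function, every intermediate artifact is plain CSV, and a
synthetic generator with known ground truth makes the whole chain verifiable
without access to clinical waveform databases.

## The method

Given a PPG record x[n] sampled at f_s (default 125 Hz):

1. **Preprocess** — zero all DFT components above 8 Hz and invert the
   transform (removes high-frequency noise), min–max normalize each record
   to [0, 1], and compute the first and second derivatives (dPPG, sdPPG).
2. **Fiducial detection** — systolic peaks by adaptive moving-average
   thresholding; onset/offset valleys as the minimum between consecutive
   peaks; slope extrema from dPPG; the dicrotic notch as the largest local
   maximum of sdPPG between the systolic peak and the offset. Cycles run
   valley to valley; implausible cycles (SBP ∉ [80, 180] mmHg,
   DBP ∉ [60, 130] mmHg, pulse pressure < 20 mmHg, duration ∉ [0.33, 2] s,
   incomplete fiducials) are removed and logged.
3. **Features** — 59 morphological descriptors per cycle (heart rate,
   segment durations t1–t8, slopes AS/DS, areas S1–S4/AA/DA, intensities
   PI/NI/VI, and their ratios, on PPG and both derivatives), then per-feature
   z-scoring y′ = (y − μ)/σ.
4. **Feature ranking (γ index)** — for each standardized feature, γ is the
   mean absolute difference between its empirical bin masses and the
   standard-normal bin masses on a 61-point grid spanning ±3 sd (step 0.1):

   γ = (1/m) Σ_v | f(v) − (Φ(v+0.1) − Φ(v)) |

   Lower γ = more normal-shaped. Selection keeps the 32 lowest-γ features,
   with S1/S2 swapped in for sdAS/sdDS by default; on the reference γ table
   shipped with the package this reproduces the published 32-feature set.
5. **Regression** — a fully connected network, 32 inputs → hidden layers
   2048/4096/8192/2048 (ReLU) → 2 linear outputs (SBP, DBP), trained with
   Nadam on mini-batches of 512 under a 70/20/10 train/test/validation
   split. Widths are configurable; desk-scale runs use small networks.
6. **Grading** — RMSE, MAE, Pearson r, Bland–Altman limits of agreement
   (mean ± 1.96 sd of differences), the AAMI criterion (|mean error| ≤ 5 and
   SD ≤ 8 mmHg) and the BHS grade from the cumulative percentages of
   |error| ≤ 5/10/15 mmHg (A = 60/85/95, B = 50/75/90, C = 40/65/85, else D).

## Worked example

`examples/04_train_and_grade.py` trains a reduced-width network on 10,000
synthetic cycles whose labels are an affine function of the features plus
3 mmHg Gaussian noise — so ~3 mmHg is the best achievable RMSE:

```
split 10000 cycles -> train 7000, test 2000, val 1000
trained 121 epochs; best validation RMSE 3.27 mmHg (label-noise floor is 3 mmHg)
SBP: RMSE 3.21 mmHg, MAE 2.56 mmHg, ME -0.20 +- 3.21 mmHg
     AAMI pass (|ME| <= 5, SD <= 8); BHS grade A (87.5% / 99.8% / 100.0% of |err| <= 5/10/15 mmHg)
     Pearson r 0.971, LOA (-6.49, 6.09) mmHg
DBP: RMSE 3.14 mmHg, MAE 2.51 mmHg, ME -0.11 +- 3.14 mmHg
     AAMI pass (|ME| <= 5, SD <= 8); BHS grade A (88.7% / 99.9% / 100.0% of |err| <= 5/10/15 mmHg)
     Pearson r 0.897, LOA (-6.27, 6.04) mmHg
```

The network reaches the noise floor (RMSE ≈ 3.2 vs the 3 mmHg injected
noise), passes AAMI on both targets, and grades A — i.e., the estimator
recovered the underlying feature→pressure map, and the residual error is the
label noise itself. The other examples cover simulation (`01`), fiducial
recovery against ground truth (`02`), γ ranking and reproduction of the
published 32-feature selection (`03`), and the full pipeline with all CSV
artifacts (`05`).

A thin CLI mirrors the stages
(`ppgbp simulate | preprocess | segment | extract-features |
select-features | train | predict | evaluate | run`); see `ppgbp --help`.

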