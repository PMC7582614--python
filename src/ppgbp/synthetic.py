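"""Synthetic PPG/ABP generator with known ground truth.

Real cuffless-BP pipelines are trained on ICU waveform corpora where the
arterial line provides per-cycle SBP/DBP labels.  That data cannot ship with
a library, so this module emulates its essential structure: a quasi-periodic
pulse train in which every cycle has a systolic wave, a dicrotic (secondary)
wave separated from it by a notch, slow baseline wander, high-frequency
noise, and per-cycle blood-pressure labels that are a *known* function of the
cycle's morphology.  Because the mapping from morphology to pressure is known
and configurable, every downstream stage -- fiducial detection, feature
extraction, feature ranking, regression -- can be tested against ground
truth instead of against itself.

Pulse model
-----------
Each cardiac cycle of duration ``T`` is the sum of two positive Gaussian
lobes on a zero baseline: a systolic lobe of amplitude ``A`` centred at a
fixed fraction of the cycle, and a dicrotic lobe of amplitude ``A * r``
(``r`` = notch_relative_intensity) centred later in the cycle.  The dip
between the lobes plays the role of the dicrotic notch; in this pipeline the
notch is localized as the secondary peak of the second derivative, which for
this shape sits in that dip.  Heart rate, amplitude and ``r`` jitter from
cycle to cycle, and the per-cycle triple (heart rate, amplitude, r) is
mapped affinely to (SBP, DBP) in mmHg, optionally plus Gaussian label noise.

The ground-truth table reports, per cycle, the sample indices of the six
fiducial landmarks measured on the *clean* pulse train (no wander, no
noise), the SBP/DBP labels, and the morphology parameters.  Landmarks use
the same geometric definitions the detector must satisfy -- valley = argmin
between consecutive systolic maxima, notch = largest second-derivative local
maximum between peak and offset -- because with overlapping lobe tails the
true inter-peak minimum sits a few samples away from the nominal cycle
boundary.

What this generator does *not* emulate: reflected-wave physiology, arrhythmia,
motion artefacts, sensor saturation, or subject-level structure (every cycle
is exchangeable).  Conclusions drawn from it are about the pipeline's
correctness, not about clinical accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import WaveformRecord

__all__ = [
    "BPMap",
    "SynthConfig",
    "generate_record",
    "generate_feature_dataset",
    "default_affine_map",
]


@dataclass
class BPMap:
    """Affine map from per-cycle morphology (hr_bpm, amplitude, r) to mmHg.

    SBP = sbp_intercept + sbp_coef . (hr, amplitude, r), likewise DBP.
    Defaults give SBP ~ 124 and DBP ~ 74 mmHg at the generator defaults.
    """

    sbp_intercept: float = 95.0
    sbp_coef: tuple[float, float, float] = (0.2, 5.0, 25.0)
    dbp_intercept: float = 60.0
    dbp_coef: tuple[float, float, float] = (0.1, 2.0, 12.0)

    def __call__(self, hr_bpm: float, amplitude: float, r: float) -> tuple[float, float]:
        m = np.array([hr_bpm, amplitude, r])
        sbp = self.sbp_intercept + float(np.dot(self.sbp_coef, m))
        dbp = self.dbp_intercept + float(np.dot(self.dbp_coef, m))
        return sbp, dbp


@dataclass
class SynthConfig:
    """Generator configuration; defaults emulate a clean 125 Hz finger PPG."""

    sampling_rate_hz: float = 125.0
    duration_s: float = 60.0
    heart_rate_bpm: float = 75.0
    hr_jitter_sd_bpm: float = 3.0
    systolic_amplitude: float = 1.0
    amplitude_jitter_sd: float = 0.1
    notch_relative_intensity: float = 0.35
    notch_intensity_jitter_sd: float = 0.08
    notch_delay_fraction: float = 0.62
    systolic_center_fraction: float = 0.28
    systolic_width_fraction: float = 0.11
    dicrotic_width_fraction: float = 0.09
    wander_amplitude: float = 0.1
    wander_freq_hz: float = 0.2
    noise_amplitude: float = 0.03
    noise_freq_hz: float = 20.0
    white_noise_sd: float = 0.01
    bp_map: BPMap = field(default_factory=BPMap)
    label_noise_sd_mmHg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sampling rate and duration must be positive")
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart_rate_bpm must be positive")
        if not 0 < self.notch_relative_intensity < 1:
            raise ValueError("notch_relative_intensity must be in (0, 1)")
        if not 0 < self.notch_delay_fraction < 1:
            raise ValueError("notch_delay_fraction must be in (0, 1)")
        if self.notch_delay_fraction <= self.systolic_center_fraction:
            raise ValueError(
                "notch_delay_fraction must lie after the systolic peak fraction"
            )
        if self.wander_amplitude > 0 and not 0 < self.wander_freq_hz < 0.5:
            raise ValueError("wander_freq_hz must be in (0, 0.5)")
        if self.noise_amplitude > 0 and self.noise_freq_hz <= 8:
            raise ValueError("noise_freq_hz must exceed 8 Hz")
        if self.label_noise_sd_mmHg < 0:
            raise ValueError("label_noise_sd_mmHg must be nonnegative")


def _gaussian(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict-left, non-strict-right interior local maxima."""
    if x.size < 3:
        return np.array([], dtype=int)
    interior = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])) + 1
    return interior


def _clean_pulse_train(
    t: np.ndarray, cycles: list[dict], config: SynthConfig
) -> np.ndarray:
    clean = np.zeros_like(t)
    for cyc in cycles:
        T = cyc["duration_s"]
        c_sys = cyc["onset_time_s"] + config.systolic_center_fraction * T
        c_dic = cyc["onset_time_s"] + config.notch_delay_fraction * T
        w_sys = config.systolic_width_fraction * T
        w_dic = config.dicrotic_width_fraction * T
        # only touch samples within +-5 sigma of the wider lobe
        lo = max(cyc["onset_time_s"] - 0.6 * T, t[0])
        hi = min(cyc["onset_time_s"] + 1.6 * T, t[-1])
        i0, i1 = np.searchsorted(t, [lo, hi])
        ts = t[i0:i1]
        clean[i0:i1] += cyc["amplitude"] * (
            _gaussian(ts, c_sys, w_sys)
            + cyc["r"] * _gaussian(ts, c_dic, w_dic)
        )
    return clean


def _ground_truth(
    clean: np.ndarray, cycles: list[dict], fs: float
) -> pd.DataFrame:
    """Locate per-cycle fiducials on the clean pulse train."""
    n = clean.size
    dclean = np.gradient(clean, 1.0 / fs)
    sdclean = np.gradient(dclean, 1.0 / fs)

    # systolic maxima within nominal cycle windows
    peaks = []
    for cyc in cycles:
        a = int(round(cyc["onset_time_s"] * fs))
        b = min(int(round((cyc["onset_time_s"] + cyc["duration_s"]) * fs)), n)
        peaks.append(a + int(np.argmax(clean[a:b])))

    onsets = [int(np.argmin(clean[: peaks[0] + 1]))]
    for j in range(1, len(peaks)):
        span = clean[peaks[j - 1] : peaks[j] + 1]
        onsets.append(peaks[j - 1] + int(np.argmin(span)))
    last_off = peaks[-1] + int(np.argmin(clean[peaks[-1] :]))
    offsets = onsets[1:] + [last_off]

    rows = []
    for j, cyc in enumerate(cycles):
        on, pk, off = onsets[j], peaks[j], offsets[j]
        rise = dclean[on : pk + 1]
        max_slope = on + int(np.argmax(rise)) if rise.size else on
        fall = dclean[pk : off + 1]
        min_slope = pk + int(np.argmin(fall)) if fall.size else pk
        window = sdclean[pk + 1 : off]
        cands = _local_maxima(window)
        if cands.size:
            notch = pk + 1 + int(cands[np.argmax(window[cands])])
        else:
            notch = -1
        rows.append(
            {
                "cycle_index": j,
                "onset_idx": on,
                "max_slope_idx": max_slope,
                "systolic_peak_idx": pk,
                "dicrotic_notch_idx": notch,
                "min_slope_idx": min_slope,
                "offset_idx": off,
                "hr_bpm": 60.0 / cyc["duration_s"],
                "amplitude": cyc["amplitude"],
                "notch_intensity": cyc["r"],
                "sbp_mmHg": cyc["sbp"],
                "dbp_mmHg": cyc["dbp"],
            }
        )
    return pd.DataFrame(rows)


def _synthesize_abp(
    clean: np.ndarray, truth: pd.DataFrame
) -> np.ndarray:
    """ABP as a per-cycle rescaled copy of the clean pulse train.

    Within each half-open cycle span [onset, offset) the clean waveform is
    mapped so its maximum is the cycle's SBP and its minimum the DBP, making
    label extraction exactly invertible on clean data (spans are half-open
    so the shared valley sample belongs to exactly one cycle).
    """
    abp = np.full(clean.shape, np.nan)
    for row in truth.itertuples():
        a, b = int(row.onset_idx), int(row.offset_idx)
        seg = clean[a:b]
        lo, hi = seg.min(), seg.max()
        if hi <= lo:
            continue
        abp[a:b] = row.dbp_mmHg + (row.sbp_mmHg - row.dbp_mmHg) * (seg - lo) / (hi - lo)
    # edge-pad outside the first/last cycle
    valid = np.flatnonzero(~np.isnan(abp))
    if valid.size:
        abp[: valid[0]] = abp[valid[0]]
        abp[valid[-1] + 1 :] = abp[valid[-1]]
    else:
        abp[:] = 0.0
    return abp


def generate_record(
    config: SynthConfig,
) -> tuple[WaveformRecord, pd.DataFrame]:
    """Generate one PPG(+ABP) record and its per-cycle ground-truth table.

    Returns
    -------
    record
        The noisy waveform (clean pulse train + wander + noise) with the
        synthetic ABP channel attached.
    truth
        One row per complete cycle: fiducial sample indices on the clean
        train (``dicrotic_notch_idx`` is -1 where no secondary wave exists),
        morphology parameters, and SBP/DBP labels in mmHg.

    Identical config (including seed) yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    cycles: list[dict] = []
    tau = 0.0
    while True:
        hr = config.heart_rate_bpm + rng.normal(0.0, config.hr_jitter_sd_bpm)
        hr = max(hr, 20.0)
        T = 60.0 / hr
        if tau + T > config.duration_s + 1e-12:
            break
        amp = config.systolic_amplitude * max(
            1.0 + rng.normal(0.0, config.amplitude_jitter_sd), 0.2
        )
        r = float(
            np.clip(
                config.notch_relative_intensity
                + rng.normal(0.0, config.notch_intensity_jitter_sd),
                0.05,
                0.9,
            )
        )
        sbp, dbp = config.bp_map(60.0 / T, amp, r)
        if config.label_noise_sd_mmHg > 0:
            sbp += rng.normal(0.0, config.label_noise_sd_mmHg)
            dbp += rng.normal(0.0, config.label_noise_sd_mmHg)
        if sbp <= dbp:
            raise ValueError(
                "bp_map produced SBP <= DBP; adjust the map or jitter scales"
            )
        cycles.append(
            dict(onset_time_s=tau, duration_s=T, amplitude=amp, r=r, sbp=sbp, dbp=dbp)
        )
        tau += T
    if not cycles:
        raise ValueError("duration too short to contain a single cycle")

    clean = _clean_pulse_train(t, cycles, config)
    truth = _ground_truth(clean, cycles, fs)
    abp = _synthesize_abp(clean, truth)

    signal = clean.copy()
    if config.wander_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal = signal + config.wander_amplitude * np.sin(
            2 * np.pi * config.wander_freq_hz * t + phase
        )
    if config.noise_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal = signal + config.noise_amplitude * np.sin(
            2 * np.pi * config.noise_freq_hz * t + phase
        )
    if config.white_noise_sd > 0:
        signal = signal + rng.normal(0.0, config.white_noise_sd, size=n)

    record = WaveformRecord(
        samples=signal,
        sampling_rate_hz=fs,
        abp_samples=abp,
        record_id=f"synth-seed{config.seed}",
    )
    return record, truth


def default_affine_map(
    n_features: int, n_informative: int = 8
) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Default (sbp_coef, sbp_intercept, dbp_coef, dbp_intercept).

    The first ``n_informative`` features carry linearly decaying weights;
    the rest have zero weight.  With unit-variance features the implied SBP
    spread is a realistic ~7 mmHg.
    """
    sbp_coef = np.zeros(n_features)
    sbp_coef[:n_informative] = np.linspace(4.0, 1.0, n_informative)
    dbp_coef = 0.5 * sbp_coef
    return sbp_coef, 125.0, dbp_coef, 75.0


def generate_feature_dataset(
    n_cycles: int,
    n_features: int = 32,
    sbp_coef: np.ndarray | None = None,
    sbp_intercept: float = 125.0,
    dbp_coef: np.ndarray | None = None,
    dbp_intercept: float = 75.0,
    label_noise_sd_mmHg: float = 0.0,
    feature_corr: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a tabular dataset with labels affine in the features.

    Features are equicorrelated standard Gaussians (pairwise correlation
    ``feature_corr``); labels are ``intercept + X @ coef + N(0, sd^2)`` per
    target.  Useful for regressor parameter-recovery tests: with zero label
    noise, least squares on (X, y) has zero residual by construction.

    Returns ``(X, y)`` with ``X`` of shape (n_cycles, n_features) and ``y``
    of shape (n_cycles, 2) holding (SBP, DBP) in mmHg.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if label_noise_sd_mmHg < 0:
        raise ValueError("label_noise_sd_mmHg must be nonnegative")
    if not 0 <= feature_corr < 1:
        raise ValueError("feature_corr must be in [0, 1)")
    if sbp_coef is None or dbp_coef is None:
        d_sbp, d_sbp_i, d_dbp, d_dbp_i = default_affine_map(n_features)
        if sbp_coef is None:
            sbp_coef, sbp_intercept = d_sbp, d_sbp_i
        if dbp_coef is None:
            dbp_coef, dbp_intercept = d_dbp, d_dbp_i
    sbp_coef = np.asarray(sbp_coef, dtype=float)
    dbp_coef = np.asarray(dbp_coef, dtype=float)
    if sbp_coef.shape != (n_features,) or dbp_coef.shape != (n_features,):
        raise ValueError("coefficient vectors must have length n_features")

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_cycles, n_features))
    if feature_corr > 0:
        shared = rng.standard_normal((n_cycles, 1))
        x = np.sqrt(1 - feature_corr) * z + np.sqrt(feature_corr) * shared
    else:
        x = z
    y = np.column_stack(
        [sbp_intercept + x @ sbp_coef, dbp_intercept + x @ dbp_coef]
    )
    if label_noise_sd_mmHg > 0:
        y = y + rng.normal(0.0, label_noise_sd_mmHg, size=y.shape)
    return x, y
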