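"""PPG preprocessing: FFT band-limiting, min-max normalization, derivatives.

A raw photoplethysmogram carries two nuisance components on top of the
cardiac pulse train: slow baseline wander (respiration and sensor drift,
below ~0.5 Hz in frequency but removed here only if a low cut is requested)
and high-frequency noise (mains interference, motion, quantization, above
~8 Hz).  The cardiac information of interest lives below 8 Hz, so the
cleaning step is a hard spectral gate: transform with the FFT, zero every
bin above the cut-off (symmetrically, so the inverse transform stays real),
and transform back.

After band-limiting, each record is min-max normalized to [0, 1] so that
intensity-based features are comparable across sensors and subjects, and
the first and second time derivatives (dPPG, sdPPG) are computed -- the
derivative contours are where inflection landmarks such as the dicrotic
notch are easiest to localize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class WaveformRecord:
    """A sampled PPG trace, optionally with an aligned ABP channel.

    Parameters
    ----------
    samples
        PPG amplitudes in arbitrary units, uniformly sampled.
    sampling_rate_hz
        Sampling rate in Hz (the common clinical waveform rate is 125 Hz).
    abp_samples
        Optional arterial blood pressure channel in mmHg, sample-aligned
        with ``samples``; used only as the label source for SBP/DBP.
    record_id
        Free-text identifier.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    abp_samples: np.ndarray | None = None
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.abp_samples is not None:
            self.abp_samples = np.asarray(self.abp_samples, dtype=float)
            if self.abp_samples.shape != self.samples.shape:
                raise ValueError("abp_samples must align with samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate_hz


@dataclass
class PreprocessedRecord:
    """Band-limited, normalized PPG with its first two derivatives."""

    ppg: np.ndarray
    dppg: np.ndarray
    sdppg: np.ndarray
    sampling_rate_hz: float
    abp_samples: np.ndarray | None = None
    record_id: str = ""


def bandlimit(
    record: WaveformRecord,
    high_cut_hz: float = 8.0,
    low_cut_hz: float = 0.0,
) -> WaveformRecord:
    """Zero all DFT components above ``high_cut_hz`` and restore by IFFT.

    The cut is inclusive: components at exactly ``high_cut_hz`` are kept.
    Conjugate bin pairs are zeroed together (a consequence of operating on
    the half-spectrum via the real FFT), so the output is real.  An optional
    ``low_cut_hz`` > 0 additionally removes components strictly below that
    frequency; the default 0 removes nothing at the low end.

    Raises
    ------
    ValueError
        If the signal is empty/too short or ``high_cut_hz`` is at or above
        the Nyquist frequency.
    """
    x = np.asarray(record.samples, dtype=float)
    if x.size < 2:
        raise ValueError("signal must contain at least 2 samples")
    nyquist = record.sampling_rate_hz / 2.0
    if high_cut_hz >= nyquist:
        raise ValueError(
            f"high_cut_hz ({high_cut_hz}) must be below Nyquist ({nyquist})"
        )
    if low_cut_hz < 0 or low_cut_hz >= high_cut_hz:
        raise ValueError("low_cut_hz must satisfy 0 <= low_cut < high_cut")

    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / record.sampling_rate_hz)
    keep = freqs <= high_cut_hz
    if low_cut_hz > 0:
        keep &= freqs >= low_cut_hz
    spectrum[~keep] = 0.0
    filtered = np.fft.irfft(spectrum, n=x.size)
    return WaveformRecord(
        samples=filtered,
        sampling_rate_hz=record.sampling_rate_hz,
        abp_samples=record.abp_samples,
        record_id=record.record_id,
    )


def minmax_normalize(segment: np.ndarray) -> np.ndarray:
    """Map a segment onto [0, 1] via (x - min) / (max - min).

    Order-preserving; the minimum maps to exactly 0 and the maximum to 1.

    Raises
    ------
    ValueError
        If the segment is shorter than 2 samples or constant (zero range).
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ValueError("segment must contain at least 2 samples")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("cannot normalize a constant segment (max == min)")
    return (x - lo) / (hi - lo)


def derivatives(
    ppg: np.ndarray, sampling_rate_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivatives by central differences, in units per second.

    One-sided differences are used at the endpoints.  The second derivative
    is the same scheme applied to the first derivative, so both outputs have
    the input's length.
    """
    x = np.asarray(ppg, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    dt = 1.0 / sampling_rate_hz
    dppg = np.gradient(x, dt)
    sdppg = np.gradient(dppg, dt)
    return dppg, sdppg


def preprocess_record(
    record: WaveformRecord,
    high_cut_hz: float = 8.0,
    low_cut_hz: float = 0.0,
) -> PreprocessedRecord:
    """Band-limit, min-max normalize, and differentiate one record."""
    filtered = bandlimit(record, high_cut_hz=high_cut_hz, low_cut_hz=low_cut_hz)
    ppg = minmax_normalize(filtered.samples)
    dppg, sdppg = derivatives(ppg, record.sampling_rate_hz)
    return PreprocessedRecord(
        ppg=ppg,
        dppg=dppg,
        sdppg=sdppg,
        sampling_rate_hz=record.sampling_rate_hz,
        abp_samples=record.abp_samples,
        record_id=record.record_id,
    )
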