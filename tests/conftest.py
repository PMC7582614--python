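import numpy as np
import pytest

from ppgbp.fiducials import CycleSegment, FiducialSet
from ppgbp.preprocess import preprocess_record
from ppgbp.synthetic import SynthConfig, generate_record


@pytest.fixture(scope="session")
def clean_config() -> SynthConfig:
    """Noise-free, wander-free 30 s record at ~72 bpm."""
    return SynthConfig(
        duration_s=30.0,
        heart_rate_bpm=72.0,
        wander_amplitude=0.0,
        noise_amplitude=0.0,
        white_noise_sd=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def clean_record(clean_config):
    return generate_record(clean_config)


@pytest.fixture(scope="session")
def clean_segments(clean_record):
    record, truth = clean_record
    pre = preprocess_record(record)
    from ppgbp.fiducials import detect_systolic_peaks, detect_valleys, partition_cycles

    peaks = detect_systolic_peaks(pre.ppg, pre.sampling_rate_hz)
    valleys = detect_valleys(pre.ppg, peaks)
    return partition_cycles(pre, valleys)


@pytest.fixture()
def toy_cycle() -> CycleSegment:
    """20-sample piecewise-linear cycle with hand-placed fiducials at 10 Hz.

    Rise 0 -> 1 over samples 0..5, fall 1 -> 0.3 over 5..12, then
    0.3 -> 0.02 over 12..19.  Hand-computed trapezoids (dx = 0.1 s):
    S1 (0..2) = 0.04, S2 (2..5) = 0.21, AA (0..5) = 0.25, DA (5..19) = 0.567,
    AS = (1 - 0) / 0.5 s = 2.0 per second.
    """
    fs = 10.0
    ppg = np.concatenate(
        [
            np.linspace(0.0, 1.0, 6),
            np.linspace(1.0, 0.3, 8)[1:],
            np.linspace(0.3, 0.02, 8)[1:],
        ]
    )
    assert len(ppg) == 20
    dppg = np.gradient(ppg, 1.0 / fs)
    sdppg = np.gradient(dppg, 1.0 / fs)
    fids = FiducialSet(
        onset_idx=0,
        max_slope_idx=2,
        systolic_peak_idx=5,
        min_slope_idx=8,
        dicrotic_notch_idx=12,
        offset_idx=19,
    )
    return CycleSegment(
        ppg_fragment=ppg,
        dppg_fragment=dppg,
        sdppg_fragment=sdppg,
        fiducials=fids,
        sampling_rate_hz=fs,
        sbp_mmHg=120.0,
        dbp_mmHg=80.0,
    )
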