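"""Fiducial detection, partitioning, label extraction, plausibility filtering."""

import dataclasses
import math

import numpy as np
import pytest

from ppgbp.fiducials import (
    AbnormalCycleCriteria,
    detect_dicrotic_notch,
    detect_slope_extrema,
    detect_systolic_peaks,
    detect_valleys,
    extract_bp_labels,
    partition_cycles,
    remove_abnormal_cycles,
    segment_record,
)
from ppgbp.preprocess import preprocess_record
from ppgbp.synthetic import SynthConfig, generate_record


class TestPeaks:
    def test_recovers_ground_truth_on_clean_record(self, clean_record):
        record, truth = clean_record
        pre = preprocess_record(record)
        peaks = detect_systolic_peaks(pre.ppg, pre.sampling_rate_hz)
        assert len(peaks) == len(truth)
        assert np.abs(peaks - truth.systolic_peak_idx.to_numpy()).max() <= 2

    def test_flat_signal_yields_empty(self):
        assert detect_systolic_peaks(np.zeros(1000), 125.0).size == 0

    def test_two_cycle_record(self):
        cfg = SynthConfig(
            duration_s=2.2, heart_rate_bpm=60, hr_jitter_sd_bpm=0,
            wander_amplitude=0, noise_amplitude=0, white_noise_sd=0, seed=9,
        )
        rec, truth = generate_record(cfg)
        pre = preprocess_record(rec)
        peaks = detect_systolic_peaks(pre.ppg, pre.sampling_rate_hz)
        assert len(peaks) == 2 == len(truth)


class TestValleys:
    def test_ground_truth_onsets(self, clean_record):
        record, truth = clean_record
        pre = preprocess_record(record)
        peaks = detect_systolic_peaks(pre.ppg, pre.sampling_rate_hz)
        valleys = detect_valleys(pre.ppg, peaks)
        assert len(valleys) == len(peaks) - 1
        expected = truth.onset_idx.to_numpy()[1:]
        assert np.abs(valleys - expected).max() <= 2

    def test_v_shape_vertex(self):
        x = np.concatenate([np.linspace(1, 0, 50), np.linspace(0, 1, 50)])
        valleys = detect_valleys(x, np.array([0, 99]))
        assert valleys.tolist() == [49]

    def test_tie_resolves_to_earliest(self):
        x = np.array([1.0, 0.0, 0.5, 0.0, 1.0])
        assert detect_valleys(x, np.array([0, 4])).tolist() == [1]

    def test_requires_two_peaks(self):
        with pytest.raises(ValueError):
            detect_valleys(np.zeros(10), np.array([3]))


class TestSlopeExtrema:
    def test_logistic_inflection(self):
        fs = 125.0
        t = np.arange(200) / fs
        center = 0.8
        x = 1.0 / (1.0 + np.exp(-(t - center) * 20))
        d = np.gradient(x, 1 / fs)
        max_slope, _ = detect_slope_extrema(x, d, (0, 199))
        assert abs(max_slope - int(center * fs)) <= 1

    def test_triangle_pulse_limbs(self):
        x = np.concatenate([np.linspace(0, 1, 30), np.linspace(1, 0, 30)[1:]])
        d = np.gradient(x)
        max_slope, min_slope = detect_slope_extrema(x, d, (0, len(x) - 1))
        peak = int(np.argmax(x))
        assert max_slope < peak < min_slope

    def test_matches_generator_steepest_ascent(self, clean_record):
        record, truth = clean_record
        pre = preprocess_record(record)
        for row in truth.iloc[1:-1].itertuples():
            ms, _ = detect_slope_extrema(
                pre.ppg, pre.dppg, (row.onset_idx, row.offset_idx)
            )
            assert abs(ms - row.max_slope_idx) <= 2

    def test_degenerate_span_rejected(self):
        with pytest.raises(ValueError):
            detect_slope_extrema(np.zeros(10), np.zeros(10), (4, 5))


class TestNotch:
    def test_matches_generator_ground_truth(self, clean_record):
        record, truth = clean_record
        pre = preprocess_record(record)
        for row in truth.iloc[1:-1].itertuples():
            pk = row.onset_idx + int(
                np.argmax(pre.ppg[row.onset_idx : row.offset_idx])
            )
            notch = detect_dicrotic_notch(pre.sdppg, pk, row.offset_idx)
            assert notch is not None
            assert abs(notch - row.dicrotic_notch_idx) <= 3

    def test_absent_without_secondary_wave(self):
        # single smooth lobe: sdPPG has no local max on the downslope
        t = np.linspace(-3, 3, 200)
        x = np.exp(-0.5 * t**2)
        sd = np.gradient(np.gradient(x))
        peak = int(np.argmax(x))
        # search only the concave fall-off just after the peak
        assert detect_dicrotic_notch(sd, peak, peak + 40) is None

    def test_larger_of_two_local_maxima_wins(self):
        sd = np.zeros(50)
        sd[20] = 1.0  # local max
        sd[35] = 2.0  # larger local max
        assert detect_dicrotic_notch(sd, 10, 45) == 35

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            detect_dicrotic_notch(np.zeros(10), 5, 6)


class TestPartition:
    def test_segment_count_and_reconstruction(self, clean_record):
        record, _ = clean_record
        pre = preprocess_record(record)
        peaks = detect_systolic_peaks(pre.ppg, pre.sampling_rate_hz)
        valleys = detect_valleys(pre.ppg, peaks)
        segments = partition_cycles(pre, valleys)
        assert len(segments) == len(valleys) - 1
        # concatenating fragments minus shared endpoints rebuilds the span
        rebuilt = np.concatenate(
            [seg.ppg_fragment[:-1] for seg in segments]
            + [segments[-1].ppg_fragment[-1:]]
        )
        np.testing.assert_array_equal(rebuilt, pre.ppg[valleys[0] : valleys[-1] + 1])

    def test_each_segment_max_is_its_systolic_peak(self, clean_segments):
        for seg in clean_segments:
            assert int(np.argmax(seg.ppg_fragment)) == seg.fiducials.systolic_peak_idx

    def test_fiducial_ordering_invariant(self, clean_segments):
        for seg in clean_segments:
            assert seg.fiducials.is_ordered()

    def test_needs_two_valleys(self, clean_record):
        record, _ = clean_record
        pre = preprocess_record(record)
        with pytest.raises(ValueError):
            partition_cycles(pre, np.array([5]))


class TestLabels:
    def test_synthetic_abp_roundtrip(self, clean_record):
        record, truth = clean_record
        for row in truth.iloc[1:-1].itertuples():
            sbp, dbp = extract_bp_labels(
                record.abp_samples, (row.onset_idx, row.offset_idx)
            )
            assert sbp == pytest.approx(row.sbp_mmHg, abs=0.5)
            assert dbp == pytest.approx(row.dbp_mmHg, abs=0.5)

    def test_constant_abp_rejected(self):
        with pytest.raises(ValueError):
            extract_bp_labels(np.full(100, 90.0), (10, 50))

    def test_missing_abp_rejected(self):
        with pytest.raises(ValueError):
            extract_bp_labels(None, (0, 10))


class TestAbnormalRemoval:
    def test_clean_synthetic_set_untouched(self, clean_segments):
        kept, log = remove_abnormal_cycles(clean_segments)
        assert len(kept) == len(clean_segments)
        assert sum(log.values()) == 0

    def test_injected_sbp_outlier_removed_and_logged(self, clean_segments):
        bad = dataclasses.replace(clean_segments[0], sbp_mmHg=250.0)
        kept, log = remove_abnormal_cycles([bad] + clean_segments[1:])
        assert len(kept) == len(clean_segments) - 1
        assert log["sbp_range"] == 1

    def test_overlong_cycle_removed(self, clean_segments):
        seg = clean_segments[0]
        fids = dataclasses.replace(
            seg.fiducials, offset_idx=seg.fiducials.onset_idx + 250
        )
        slow = dataclasses.replace(seg, fiducials=fids)  # 2 s at 125 Hz
        crit = AbnormalCycleCriteria(cycle_duration_range_s=(0.3, 1.5))
        kept, log = remove_abnormal_cycles([slow], crit)
        assert kept == [] and log["cycle_duration"] == 1

    def test_contradictory_bounds_rejected(self):
        with pytest.raises(ValueError):
            AbnormalCycleCriteria(sbp_range_mmHg=(180.0, 80.0))

    def test_filtering_is_order_independent(self, clean_segments):
        rng = np.random.default_rng(0)
        pool = list(clean_segments)
        pool[3] = dataclasses.replace(pool[3], sbp_mmHg=260.0)
        pool[5] = dataclasses.replace(pool[5], dbp_mmHg=20.0)
        kept_a, _ = remove_abnormal_cycles(pool)
        shuffled = [pool[i] for i in rng.permutation(len(pool))]
        kept_b, _ = remove_abnormal_cycles(shuffled)
        assert {id(s) for s in kept_a} == {id(s) for s in kept_b}


def test_segment_record_empty_on_featureless_signal():
    from ppgbp.preprocess import PreprocessedRecord

    pre = PreprocessedRecord(
        ppg=np.zeros(1000), dppg=np.zeros(1000), sdppg=np.zeros(1000),
        sampling_rate_hz=125.0,
    )
    segments, info = segment_record(pre)
    assert segments == [] and info["n_peaks"] == 0
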