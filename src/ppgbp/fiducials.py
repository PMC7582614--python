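"""Per-cycle fiducial detection, cycle partitioning, and abnormal-cycle removal.

The landmark vocabulary for one cardiac cycle of PPG:

* onset / offset -- the valleys bounding the cycle (one cycle runs valley to
  valley between consecutive systolic peaks);
* systolic peak -- the cycle's global maximum;
* max / min slope -- extrema of the first derivative (steepest rise before
  the peak, steepest fall after it);
* dicrotic notch -- the secondary inflection on the downslope marking aortic
  valve closure, localized as the largest local maximum of the second
  derivative (sdPPG) strictly between the systolic peak and the offset.

Systolic peaks are found with an adaptive moving-average threshold: regions
where the signal exceeds its windowed moving average are peak candidates,
each region contributing its argmax.  Candidates whose excess over the
moving average is small (dicrotic waves poking above the average) are
rejected, and candidates closer together than a plausible inter-beat
interval are merged keeping the taller one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "FiducialSet",
    "CycleSegment",
    "AbnormalCycleCriteria",
    "detect_systolic_peaks",
    "detect_valleys",
    "detect_slope_extrema",
    "detect_dicrotic_notch",
    "build_fiducials",
    "partition_cycles",
    "extract_bp_labels",
    "remove_abnormal_cycles",
    "segment_record",
]


@dataclass
class FiducialSet:
    """Sample indices of one cycle's landmarks (0-based, record coordinates).

    ``dicrotic_notch_idx`` is None when the cycle shows no secondary wave.
    Ordering invariant: onset < max_slope < systolic_peak < notch < offset,
    with min_slope strictly between peak and offset.
    """

    onset_idx: int
    max_slope_idx: int
    systolic_peak_idx: int
    min_slope_idx: int
    dicrotic_notch_idx: int | None
    offset_idx: int

    def is_ordered(self) -> bool:
        chain = [self.onset_idx, self.max_slope_idx, self.systolic_peak_idx]
        if self.dicrotic_notch_idx is not None:
            chain.append(self.dicrotic_notch_idx)
        chain.append(self.offset_idx)
        ordered = all(a < b for a, b in zip(chain, chain[1:]))
        return ordered and self.systolic_peak_idx < self.min_slope_idx <= self.offset_idx

    def shifted(self, delta: int) -> "FiducialSet":
        notch = (
            None if self.dicrotic_notch_idx is None else self.dicrotic_notch_idx + delta
        )
        return FiducialSet(
            onset_idx=self.onset_idx + delta,
            max_slope_idx=self.max_slope_idx + delta,
            systolic_peak_idx=self.systolic_peak_idx + delta,
            min_slope_idx=self.min_slope_idx + delta,
            dicrotic_notch_idx=notch,
            offset_idx=self.offset_idx + delta,
        )


@dataclass
class CycleSegment:
    """One cardiac cycle: signal fragments, fragment-local fiducials, labels.

    Fragments span onset valley to next onset valley, half-open in record
    coordinates but stored inclusive of the closing valley sample so the
    offset landmark is addressable.  ``sbp_mmHg``/``dbp_mmHg`` are NaN when
    no ABP channel was available.
    """

    ppg_fragment: np.ndarray
    dppg_fragment: np.ndarray
    sdppg_fragment: np.ndarray
    fiducials: FiducialSet
    sampling_rate_hz: float
    sbp_mmHg: float = math.nan
    dbp_mmHg: float = math.nan
    start_idx: int = 0
    record_id: str = ""

    @property
    def duration_s(self) -> float:
        return (
            self.fiducials.offset_idx - self.fiducials.onset_idx
        ) / self.sampling_rate_hz


def detect_systolic_peaks(
    ppg: np.ndarray,
    sampling_rate_hz: float,
    ma_window_s: float = 0.75,
    min_interval_s: float = 0.33,
    min_excess_frac: float = 0.5,
) -> np.ndarray:
    """Systolic peak indices via moving-average adaptive thresholding.

    Candidate regions are maximal runs where the signal strictly exceeds its
    centred moving average (window ``ma_window_s``); each region's argmax is
    a candidate peak.  Candidates whose excess over the moving average falls
    below ``min_excess_frac`` times the 90th-percentile excess are dropped
    (these are typically dicrotic waves), then candidates closer than
    ``min_interval_s`` are merged keeping the taller.  A flat or featureless
    signal yields an empty array.
    """
    x = np.asarray(ppg, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int)
    win = max(int(round(ma_window_s * sampling_rate_hz)), 3)
    ma = uniform_filter1d(x, size=win, mode="nearest")
    mask = x > ma
    if not mask.any():
        return np.array([], dtype=int)

    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks], [idx[-1]]])

    cands = np.array(
        [s + int(np.argmax(x[s : e + 1])) for s, e in zip(run_starts, run_ends)],
        dtype=int,
    )
    excess = x[cands] - ma[cands]
    if cands.size > 1:
        thresh = min_excess_frac * np.percentile(excess, 90)
        cands = cands[excess >= thresh]
    if cands.size == 0:
        return cands

    min_gap = min_interval_s * sampling_rate_hz
    kept: list[int] = [int(cands[0])]
    for c in cands[1:]:
        if c - kept[-1] < min_gap:
            if x[c] > x[kept[-1]]:
                kept[-1] = int(c)
        else:
            kept.append(int(c))
    return np.asarray(kept, dtype=int)


def detect_valleys(ppg: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Onset/offset valleys: argmin strictly between consecutive peaks.

    Returns one valley per consecutive peak pair (length = len(peaks) - 1).
    Ties resolve to the earliest index.
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < 2:
        raise ValueError("need at least 2 peaks to locate valleys")
    x = np.asarray(ppg, dtype=float)
    valleys = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        span = x[a + 1 : b]
        if span.size == 0:
            raise ValueError(f"no samples between peaks {a} and {b}")
        valleys.append(a + 1 + int(np.argmin(span)))
    return np.asarray(valleys, dtype=int)


def detect_slope_extrema(
    ppg: np.ndarray, dppg: np.ndarray, span: tuple[int, int]
) -> tuple[int, int]:
    """(max_slope_idx, min_slope_idx) of dPPG within a cycle span.

    The maximum slope is searched on the rising limb (onset to systolic
    peak) and the minimum slope on the falling limb (peak to offset), so the
    max-slope landmark always precedes the peak.
    """
    a, b = span
    if b - a < 3:
        raise ValueError("degenerate cycle span")
    x = np.asarray(ppg, dtype=float)
    d = np.asarray(dppg, dtype=float)
    peak = a + int(np.argmax(x[a:b]))
    rising = d[a : peak + 1]
    falling = d[peak : b + 1]
    if rising.size == 0 or falling.size == 0:
        raise ValueError("cycle span does not bracket its systolic peak")
    max_slope = a + int(np.argmax(rising))
    min_slope = peak + int(np.argmin(falling))
    return max_slope, min_slope


def _local_maxima(x: np.ndarray) -> np.ndarray:
    if x.size < 3:
        return np.array([], dtype=int)
    return np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])) + 1


def detect_dicrotic_notch(
    sdppg: np.ndarray, systolic_peak_idx: int, offset_idx: int
) -> int | None:
    """Dicrotic notch = largest sdPPG local maximum strictly inside (peak, offset).

    Returns None (notch absent) when the window holds no local maximum, e.g.
    for cycles without a secondary wave.  Among equal maxima the earliest
    wins.
    """
    if offset_idx - systolic_peak_idx < 2:
        raise ValueError("empty notch search window")
    window = np.asarray(sdppg, dtype=float)[systolic_peak_idx + 1 : offset_idx]
    cands = _local_maxima(window)
    if cands.size == 0:
        return None
    best = cands[int(np.argmax(window[cands]))]
    return systolic_peak_idx + 1 + int(best)


def build_fiducials(
    ppg: np.ndarray,
    dppg: np.ndarray,
    sdppg: np.ndarray,
    span: tuple[int, int],
) -> FiducialSet:
    """Assemble the full fiducial set for one valley-to-valley span."""
    a, b = span
    x = np.asarray(ppg, dtype=float)
    peak = a + int(np.argmax(x[a:b]))
    max_slope, min_slope = detect_slope_extrema(ppg, dppg, span)
    notch = detect_dicrotic_notch(sdppg, peak, b)
    return FiducialSet(
        onset_idx=a,
        max_slope_idx=max_slope,
        systolic_peak_idx=peak,
        min_slope_idx=min_slope,
        dicrotic_notch_idx=notch,
        offset_idx=b,
    )


def extract_bp_labels(
    abp_samples: np.ndarray | None, span: tuple[int, int]
) -> tuple[float, float]:
    """Per-cycle labels from the ABP channel: SBP = max, DBP = min.

    The span is half-open [onset, offset): the closing valley sample belongs
    to the next cycle.
    """
    if abp_samples is None:
        raise ValueError("record has no ABP channel to extract labels from")
    a, b = span
    seg = np.asarray(abp_samples, dtype=float)[a:b]
    if seg.size == 0:
        raise ValueError("empty cycle span")
    sbp, dbp = float(seg.max()), float(seg.min())
    if sbp <= dbp:
        raise ValueError("degenerate ABP: SBP <= DBP over the cycle span")
    return sbp, dbp


def partition_cycles(
    pre,
    valleys: np.ndarray,
    record_id: str = "",
) -> list[CycleSegment]:
    """Slice a preprocessed record into valley-to-valley cycle segments.

    For each consecutive valley pair a segment is emitted carrying the
    PPG/dPPG/sdPPG fragments (inclusive of the closing valley), the fiducial
    set re-indexed to fragment coordinates, and SBP/DBP labels when the
    record has an ABP channel.  Cycles whose fiducials cannot be ordered
    (no detectable peak structure) are skipped.
    """
    valleys = np.asarray(valleys, dtype=int)
    if valleys.size < 2:
        raise ValueError("need at least 2 valleys to partition")
    segments: list[CycleSegment] = []
    for a, b in zip(valleys[:-1], valleys[1:]):
        fids = build_fiducials(pre.ppg, pre.dppg, pre.sdppg, (int(a), int(b)))
        if pre.abp_samples is not None:
            sbp, dbp = extract_bp_labels(pre.abp_samples, (int(a), int(b)))
        else:
            sbp = dbp = math.nan
        segments.append(
            CycleSegment(
                ppg_fragment=pre.ppg[a : b + 1].copy(),
                dppg_fragment=pre.dppg[a : b + 1].copy(),
                sdppg_fragment=pre.sdppg[a : b + 1].copy(),
                fiducials=fids.shifted(-int(a)),
                sampling_rate_hz=pre.sampling_rate_hz,
                sbp_mmHg=sbp,
                dbp_mmHg=dbp,
                start_idx=int(a),
                record_id=record_id,
            )
        )
    return segments


@dataclass
class AbnormalCycleCriteria:
    """Physiological plausibility bounds for keeping a cycle.

    Defaults mirror the usual ICU-waveform prescreening: label ranges that
    exclude artefactual pressures, a minimum pulse pressure, a plausible
    cycle duration, and a complete ordered fiducial set.  All bounds are
    configurable.
    """

    sbp_range_mmHg: tuple[float, float] = (80.0, 180.0)
    dbp_range_mmHg: tuple[float, float] = (60.0, 130.0)
    min_pulse_pressure_mmHg: float = 20.0
    cycle_duration_range_s: tuple[float, float] = (0.33, 2.0)
    require_all_fiducials: bool = True

    def __post_init__(self) -> None:
        for name in ("sbp_range_mmHg", "dbp_range_mmHg", "cycle_duration_range_s"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"contradictory bounds in {name}: {lo} > {hi}")


def _violations(seg: CycleSegment, crit: AbnormalCycleCriteria) -> list[str]:
    rules = []
    if not math.isnan(seg.sbp_mmHg):
        if not crit.sbp_range_mmHg[0] <= seg.sbp_mmHg <= crit.sbp_range_mmHg[1]:
            rules.append("sbp_range")
        if not crit.dbp_range_mmHg[0] <= seg.dbp_mmHg <= crit.dbp_range_mmHg[1]:
            rules.append("dbp_range")
        if seg.sbp_mmHg - seg.dbp_mmHg < crit.min_pulse_pressure_mmHg:
            rules.append("pulse_pressure")
    lo, hi = crit.cycle_duration_range_s
    if not lo <= seg.duration_s <= hi:
        rules.append("cycle_duration")
    if crit.require_all_fiducials:
        if seg.fiducials.dicrotic_notch_idx is None or not seg.fiducials.is_ordered():
            rules.append("fiducials")
    return rules


def remove_abnormal_cycles(
    segments: list[CycleSegment],
    criteria: AbnormalCycleCriteria | None = None,
) -> tuple[list[CycleSegment], dict[str, int]]:
    """Drop segments violating any plausibility rule.

    Returns the surviving segments (original order) and a log counting, per
    rule, how many removed segments violated it (a segment violating several
    rules is counted under each).  The surviving set is independent of rule
    application order because every rule is evaluated on every segment.
    """
    crit = criteria or AbnormalCycleCriteria()
    log = {
        "sbp_range": 0,
        "dbp_range": 0,
        "pulse_pressure": 0,
        "cycle_duration": 0,
        "fiducials": 0,
    }
    kept: list[CycleSegment] = []
    for seg in segments:
        rules = _violations(seg, crit)
        if rules:
            for r in rules:
                log[r] += 1
        else:
            kept.append(seg)
    return kept, log


def segment_record(
    pre,
    criteria: AbnormalCycleCriteria | None = None,
    record_id: str = "",
    **peak_kwargs,
) -> tuple[list[CycleSegment], dict]:
    """Full segmentation step: peaks -> valleys -> partition -> plausibility filter.

    Returns the surviving segments and an info dict with detection counts
    and the per-rule removal log.
    """
    peaks = detect_systolic_peaks(pre.ppg, pre.sampling_rate_hz, **peak_kwargs)
    if peaks.size < 2:
        return [], {"n_peaks": int(peaks.size), "n_cycles": 0, "removed": {}}
    valleys = detect_valleys(pre.ppg, peaks)
    if valleys.size < 2:
        return [], {"n_peaks": int(peaks.size), "n_cycles": 0, "removed": {}}
    segments = partition_cycles(pre, valleys, record_id=record_id)
    kept, log = remove_abnormal_cycles(segments, criteria)
    info = {
        "n_peaks": int(peaks.size),
        "n_cycles": len(segments),
        "n_kept": len(kept),
        "removed": log,
    }
    return kept, info
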