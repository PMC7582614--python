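"""Morphological features of one PPG cycle and dataset-level standardization.

Each cardiac cycle yields 59 scalar descriptors of the pulse shape, computed
on the normalized PPG and on its first (dPPG) and second (sdPPG)
derivatives.  The naming convention follows the cuffless-BP literature:

* ``hr`` -- heart rate, 60 / cycle duration;
* ``t1..t4`` -- durations of the four spans bounding the areas ``S1..S4``
  (onset -> max slope -> systolic peak -> dicrotic notch -> offset) on PPG;
  ``t5/t7`` and ``t6/t8`` are the ascending/descending durations on dPPG and
  sdPPG respectively;
* ``AS/DS`` -- ascending/descending slopes (intensity difference over time
  between the named landmarks); ``d``/``sd`` prefixes apply the analogous
  formula to the derivative signal using its own cycle-local landmarks
  (peak = fragment argmax, valley = fragment argmin);
* ``S1..S4``, ``AA``, ``DA`` -- trapezoidal areas under the named signal
  between the named landmarks (normalized intensity x seconds);
* ``PI/NI/AID/DID/VI`` -- intensities read at the named landmarks;
* ratio features: ``RAAD = AA/DA``, ``PIR`` = peak/onset intensity,
  ``RIPV`` = peak/valley intensity, ``AI = NI/PI``, ``AI1 = (PI-NI)/PI``,
  ``RtArea = (S1+S2+S3)/S4``, ``RSD = (t1+t2+t3)/t4``,
  ``RSC = t4/(t1+t2+t3+t4)``, ``RDC = (t1+t2+t3)/(t1+t2+t3+t4)``;
* ``Slope_a`` -- slope from systolic peak to dicrotic notch.

Features that need the dicrotic notch (t3, t4, S3, S4, RtArea, NI, AI, AI1,
Slope_a, RSD, RSC, RDC) are NaN when the notch is absent, as is any feature
whose denominator vanishes.  Before model training every feature is z-scored
across the dataset (population standard deviation), and the (mean, sd) pair
is retained so the transform can be inverted and reused at prediction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fiducials import CycleSegment

__all__ = [
    "FEATURE_NAMES",
    "NOTCH_DEPENDENT",
    "compute_features",
    "compute_feature_matrix",
    "StandardizedFeatureMatrix",
    "standardize",
]

FEATURE_NAMES: tuple[str, ...] = (
    "hr", "t1", "t2", "t3", "t4", "t5", "t6", "t7", "t8",
    "AS", "dAS", "sdAS", "DS", "dDS", "sdDS",
    "S1", "S2",
    "AA", "dAA", "sdAA", "DA", "dDA", "sdDA",
    "RAAD", "dRAAD", "sdRAAD",
    "PI", "dPI", "sdPI", "dVI", "sdVI",
    "AID", "dAID", "sdAID", "dDID", "sdDID",
    "PIR", "dPIR", "sdPIR", "dRIPV", "sdRIPV",
    "AT", "dAT", "sdAT", "DT", "dDT", "sdDT",
    "dTVO", "sdTVO",
    "Slope_a", "S3", "S4", "RtArea",
    "NI", "AI", "AI1", "RSD", "RSC", "RDC",
)

#: features undefined when the dicrotic notch is absent
NOTCH_DEPENDENT: frozenset[str] = frozenset(
    {"t3", "t4", "S3", "S4", "RtArea", "NI", "AI", "AI1",
     "Slope_a", "RSD", "RSC", "RDC"}
)


def _div(num: float, den: float) -> float:
    return num / den if den != 0 else math.nan


def _area(y: np.ndarray, i: int, j: int, fs: float) -> float:
    """Trapezoidal area under y between sample indices i and j (i <= j)."""
    if j <= i:
        return math.nan
    return float(np.trapezoid(y[i : j + 1], dx=1.0 / fs))


def _slope(y: np.ndarray, i: int, j: int, fs: float) -> float:
    if j == i:
        return math.nan
    return float((y[j] - y[i]) * fs / (j - i))


def _derived_signal_features(y: np.ndarray, fs: float, prefix: str) -> dict[str, float]:
    """Shape features of a derivative fragment using its own landmarks."""
    end = len(y) - 1
    pk = int(np.argmax(y))
    vl = int(np.argmin(y))
    out = {
        f"{prefix}AS": _slope(y, 0, pk, fs),
        f"{prefix}DS": _slope(y, pk, end, fs),
        f"{prefix}AA": _area(y, 0, pk, fs),
        f"{prefix}DA": _area(y, pk, end, fs),
        f"{prefix}PI": float(y[pk]),
        f"{prefix}VI": float(y[vl]),
        f"{prefix}AID": float(y[pk] - y[0]),
        f"{prefix}DID": float(y[end] - y[pk]),
        f"{prefix}PIR": _div(float(y[pk]), float(y[0])),
        f"{prefix}RIPV": _div(float(y[pk]), float(y[vl])),
        f"{prefix}AT": pk / fs,
        f"{prefix}DT": (end - pk) / fs,
        f"{prefix}TVO": (end - vl) / fs,
        f"{prefix}_asc_dur": pk / fs,
        f"{prefix}_desc_dur": (end - pk) / fs,
    }
    out[f"{prefix}RAAD"] = _div(out[f"{prefix}AA"], out[f"{prefix}DA"])
    return out


def compute_features(segment: CycleSegment) -> dict[str, float]:
    """The 59 morphological features of one cycle, in canonical order.

    Notch-dependent features are NaN when the segment has no dicrotic notch;
    ratio features are NaN when their denominator vanishes.
    """
    fs = segment.sampling_rate_hz
    ppg = segment.ppg_fragment
    f = segment.fiducials
    on, ms, pk, of = f.onset_idx, f.max_slope_idx, f.systolic_peak_idx, f.offset_idx
    nt = f.dicrotic_notch_idx
    has_notch = nt is not None

    duration_s = (of - on) / fs
    out: dict[str, float] = dict.fromkeys(FEATURE_NAMES, math.nan)
    out["hr"] = _div(60.0, duration_s)

    out["t1"] = (ms - on) / fs
    out["t2"] = (pk - ms) / fs
    out["AT"] = (pk - on) / fs
    out["DT"] = (of - pk) / fs

    out["AS"] = _slope(ppg, on, pk, fs)
    out["DS"] = _slope(ppg, pk, of, fs)
    out["S1"] = _area(ppg, on, ms, fs)
    out["S2"] = _area(ppg, ms, pk, fs)
    out["AA"] = _area(ppg, on, pk, fs)
    out["DA"] = _area(ppg, pk, of, fs)
    out["RAAD"] = _div(out["AA"], out["DA"])
    out["PI"] = float(ppg[pk])
    out["AID"] = float(ppg[pk] - ppg[on])
    out["PIR"] = _div(float(ppg[pk]), float(ppg[on]))

    if has_notch:
        out["t3"] = (nt - pk) / fs
        out["t4"] = (of - nt) / fs
        out["S3"] = _area(ppg, pk, nt, fs)
        out["S4"] = _area(ppg, nt, of, fs)
        out["RtArea"] = _div(out["S1"] + out["S2"] + out["S3"], out["S4"])
        out["NI"] = float(ppg[nt])
        out["AI"] = _div(out["NI"], out["PI"])
        out["AI1"] = _div(out["PI"] - out["NI"], out["PI"])
        out["Slope_a"] = _slope(ppg, pk, nt, fs)
        systolic = out["t1"] + out["t2"] + out["t3"]
        out["RSD"] = _div(systolic, out["t4"])
        out["RSC"] = _div(out["t4"], systolic + out["t4"])
        out["RDC"] = _div(systolic, systolic + out["t4"])

    d = _derived_signal_features(segment.dppg_fragment, fs, "d")
    sd = _derived_signal_features(segment.sdppg_fragment, fs, "sd")
    for key in ("AS", "DS", "AA", "DA", "RAAD", "PI", "VI", "AID", "DID",
                "PIR", "RIPV", "AT", "DT", "TVO"):
        out[f"d{key}"] = d[f"d{key}"]
        out[f"sd{key}"] = sd[f"sd{key}"]
    out["t5"] = d["d_asc_dur"]
    out["t6"] = d["d_desc_dur"]
    out["t7"] = sd["sd_asc_dur"]
    out["t8"] = sd["sd_desc_dur"]
    return out


def compute_feature_matrix(segments: list[CycleSegment]) -> pd.DataFrame:
    """Feature matrix (one row per cycle) plus ``sbp_mmHg``/``dbp_mmHg`` labels."""
    rows = []
    for seg in segments:
        row = compute_features(seg)
        row["sbp_mmHg"] = seg.sbp_mmHg
        row["dbp_mmHg"] = seg.dbp_mmHg
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["sbp_mmHg", "dbp_mmHg"])


@dataclass
class StandardizedFeatureMatrix:
    """Z-scored feature columns with the (mean, sd) pairs that invert them."""

    values: pd.DataFrame
    mean: pd.Series
    sd: pd.Series

    def inverse(self) -> pd.DataFrame:
        return self.values * self.sd + self.mean

    def transform(self, new: pd.DataFrame) -> pd.DataFrame:
        """Apply the stored fit-time standardization to new data."""
        return (new[self.mean.index] - self.mean) / self.sd


def standardize(matrix: pd.DataFrame, ddof: int = 0) -> StandardizedFeatureMatrix:
    """Z-score each column: (y - mean) / sd, population sd by default.

    Raises
    ------
    ValueError
        If fewer than 2 rows are given or any column has zero variance (the
        error names the offending feature).
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 cycles to standardize")
    mean = matrix.mean()
    sd = matrix.std(ddof=ddof)
    dead = sd[sd == 0]
    if len(dead):
        raise ValueError(f"zero-variance feature(s): {', '.join(dead.index)}")
    return StandardizedFeatureMatrix(values=(matrix - mean) / sd, mean=mean, sd=sd)
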