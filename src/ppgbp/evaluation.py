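"""Agreement statistics and device-grading standards for BP estimates.

Given paired arrays of ground-truth and estimated pressures (mmHg), this
module computes the error metrics conventionally reported for cuffless BP
models:

* RMSE and MAE of the estimate against the truth;
* the AAMI criterion: a device passes when |mean error| <= 5 mmHg and the
  error SD <= 8 mmHg;
* the BHS grade: cumulative percentages of absolute errors at or below
  5 / 10 / 15 mmHg, graded A (60/85/95), B (50/75/90), C (40/65/85), else D
  -- a grade is awarded only when all three thresholds are met;
* Pearson's correlation coefficient between truth and estimate;
* Bland-Altman limits of agreement, mean difference +- 1.96 SD.

The error sign convention throughout is ``error = estimate - truth``; the
Bland-Altman difference uses the same.  Threshold comparisons are inclusive.
Standard deviations use the population convention by default (``ddof=0``),
configurable per call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "rmse",
    "mae",
    "aami_check",
    "bhs_cumulative_percentages",
    "bhs_grade",
    "pearson_r",
    "bland_altman",
    "TargetReport",
    "EvalReport",
    "evaluate",
]

#: BHS grade thresholds: minimum cumulative % of |error| <= 5 / 10 / 15 mmHg
BHS_THRESHOLDS: dict[str, tuple[float, float, float]] = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}

AAMI_MAX_MEAN_ERROR = 5.0
AAMI_MAX_SD_ERROR = 8.0


def _paired(truth, estimate) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("truth and estimate must be 1-d arrays of equal length")
    if t.size == 0:
        raise ValueError("empty arrays")
    return t, e


def rmse(truth, estimate) -> float:
    """Root mean square error, sqrt(mean((estimate - truth)^2)), in mmHg."""
    t, e = _paired(truth, estimate)
    return float(np.sqrt(np.mean((e - t) ** 2)))


def mae(truth, estimate) -> float:
    """Mean absolute error, mean(|estimate - truth|), in mmHg."""
    t, e = _paired(truth, estimate)
    return float(np.mean(np.abs(e - t)))


def aami_check(errors, ddof: int = 0) -> tuple[float, float, bool]:
    """(mean error, SD of error, pass flag) under the AAMI criterion.

    Passes when |mean| <= 5 mmHg and SD <= 8 mmHg.
    """
    err = np.asarray(errors, dtype=float)
    if err.size == 0:
        raise ValueError("empty error array")
    me = float(np.mean(err))
    sd = float(np.std(err, ddof=ddof)) if err.size > ddof else 0.0
    ok = abs(me) <= AAMI_MAX_MEAN_ERROR and sd <= AAMI_MAX_SD_ERROR
    return me, sd, ok


def bhs_cumulative_percentages(errors) -> tuple[float, float, float]:
    """Percentages of |error| <= 5, 10, 15 mmHg (inclusive)."""
    err = np.abs(np.asarray(errors, dtype=float))
    if err.size == 0:
        raise ValueError("empty error array")
    return tuple(float(100.0 * np.mean(err <= thr)) for thr in (5.0, 10.0, 15.0))


def bhs_grade(cum_pct_5: float, cum_pct_10: float, cum_pct_15: float) -> str:
    """Best BHS grade whose three thresholds are all met; 'D' if none.

    The inputs must be monotone percentages in [0, 100].
    """
    pcts = (cum_pct_5, cum_pct_10, cum_pct_15)
    if not all(0.0 <= p <= 100.0 for p in pcts):
        raise ValueError("percentages must lie in [0, 100]")
    if not (cum_pct_5 <= cum_pct_10 <= cum_pct_15):
        raise ValueError("cumulative percentages must be non-decreasing")
    for grade in ("A", "B", "C"):
        if all(p >= thr for p, thr in zip(pcts, BHS_THRESHOLDS[grade])):
            return grade
    return "D"


def pearson_r(x, y, ddof: int = 0) -> float:
    """Pearson's correlation coefficient, in [-1, 1].

    Computed as mean of the products of deviations over the product of the
    standard deviations; requires at least 2 points and nonzero variances.
    """
    xa, ya = _paired(x, y)
    if xa.size < 2:
        raise ValueError("need at least 2 points")
    sx, sy = np.std(xa, ddof=ddof), np.std(ya, ddof=ddof)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    n_eff = xa.size - ddof
    r = float(np.sum((xa - xa.mean()) * (ya - ya.mean())) / (n_eff * sx * sy))
    return float(np.clip(r, -1.0, 1.0))


def bland_altman(
    truth, estimate, ddof: int = 0
) -> tuple[float, float, float, float]:
    """(mean difference, LOA low, LOA high, % of points within the LOA).

    Differences are ``estimate - truth``; the limits of agreement are
    mean +- 1.96 SD.  Boundary points count as within.
    """
    t, e = _paired(truth, estimate)
    if t.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = e - t
    mu = float(np.mean(diff))
    sd = float(np.std(diff, ddof=ddof))
    lo, hi = mu - 1.96 * sd, mu + 1.96 * sd
    within = float(100.0 * np.mean((diff >= lo) & (diff <= hi)))
    return mu, lo, hi, within


@dataclass
class TargetReport:
    """All agreement statistics for one pressure target (SBP or DBP)."""

    rmse_mmHg: float
    mae_mmHg: float
    mean_error_mmHg: float
    sd_error_mmHg: float
    pearson_r: float
    loa_low_mmHg: float
    loa_high_mmHg: float
    pct_within_loa: float
    cum_pct_5: float
    cum_pct_10: float
    cum_pct_15: float
    bhs_grade: str
    aami_pass: bool


@dataclass
class EvalReport:
    sbp: TargetReport
    dbp: TargetReport
    n: int


def _evaluate_target(truth, estimate, ddof: int) -> TargetReport:
    t, e = _paired(truth, estimate)
    if t.size < 2:
        raise ValueError("need at least 2 pairs to evaluate")
    err = e - t
    me, sd, ok = aami_check(err, ddof=ddof)
    p5, p10, p15 = bhs_cumulative_percentages(err)
    mu, lo, hi, within = bland_altman(t, e, ddof=ddof)
    return TargetReport(
        rmse_mmHg=rmse(t, e),
        mae_mmHg=mae(t, e),
        mean_error_mmHg=me,
        sd_error_mmHg=sd,
        pearson_r=pearson_r(t, e, ddof=ddof),
        loa_low_mmHg=lo,
        loa_high_mmHg=hi,
        pct_within_loa=within,
        cum_pct_5=p5,
        cum_pct_10=p10,
        cum_pct_15=p15,
        bhs_grade=bhs_grade(p5, p10, p15),
        aami_pass=ok,
    )


def evaluate(
    truth_sbp, truth_dbp, est_sbp, est_dbp, ddof: int = 0
) -> EvalReport:
    """Full agreement report for paired SBP and DBP records."""
    sbp = _evaluate_target(truth_sbp, est_sbp, ddof)
    dbp = _evaluate_target(truth_dbp, est_dbp, ddof)
    return EvalReport(sbp=sbp, dbp=dbp, n=len(np.asarray(truth_sbp)))
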