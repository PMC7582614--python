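"""Agreement metrics vs brute-force oracles; grading worked examples."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgbp.evaluation import (
    aami_check,
    bhs_cumulative_percentages,
    bhs_grade,
    bland_altman,
    evaluate,
    mae,
    pearson_r,
    rmse,
)


def brute_force_report(truth, est):
    """Loop-based recomputation of every metric (independent of numpy idioms)."""
    n = len(truth)
    errs = [est[i] - truth[i] for i in range(n)]
    out = {}
    out["rmse"] = math.sqrt(sum(e * e for e in errs) / n)
    out["mae"] = sum(abs(e) for e in errs) / n
    me = sum(errs) / n
    sd = math.sqrt(sum((e - me) ** 2 for e in errs) / n)
    out["me"], out["sd"] = me, sd
    out["aami"] = abs(me) <= 5.0 and sd <= 8.0
    for thr in (5, 10, 15):
        out[f"p{thr}"] = 100.0 * sum(1 for e in errs if abs(e) <= thr) / n
    mx = sum(truth) / n
    my = sum(est) / n
    sx = math.sqrt(sum((t - mx) ** 2 for t in truth) / n)
    sy = math.sqrt(sum((e - my) ** 2 for e in est) / n)
    out["r"] = sum((t - mx) * (e - my) for t, e in zip(truth, est)) / (n * sx * sy)
    out["loa_low"], out["loa_high"] = me - 1.96 * sd, me + 1.96 * sd
    out["within"] = (
        100.0
        * sum(1 for e in errs if out["loa_low"] <= e <= out["loa_high"])
        / n
    )
    return out


class TestErrorMetrics:
    def test_identical_arrays(self):
        x = np.array([100.0, 120.0, 80.0])
        assert rmse(x, x) == 0.0 and mae(x, x) == 0.0

    def test_symmetric_errors(self):
        assert rmse([100, 100], [103, 97]) == pytest.approx(3.0)
        assert mae([100, 100], [103, 97]) == pytest.approx(3.0)

    def test_hand_arithmetic(self):
        assert mae([100, 100], [100, 104]) == pytest.approx(2.0)
        assert rmse([100, 100], [100, 104]) == pytest.approx(math.sqrt(8.0))

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            mae([], [])


class TestAAMI:
    def test_published_model_errors_pass(self):
        # reported SBP ME/SD 3.21/3.35 and DBP 2.23/2.44 both satisfy the standard
        for me_sd in ((3.21, 3.35), (2.23, 2.44)):
            errs = np.array([me_sd[0] - me_sd[1], me_sd[0] + me_sd[1]])
            me, sd, ok = aami_check(errs)
            assert me == pytest.approx(me_sd[0])
            assert sd == pytest.approx(me_sd[1])
            assert ok

    def test_zero_errors_pass(self):
        assert aami_check(np.zeros(10)) == (0.0, 0.0, True)

    def test_constant_bias_six_fails_on_mean(self):
        me, sd, ok = aami_check(np.full(20, 6.0))
        assert me == 6.0 and sd == 0.0 and not ok

    def test_large_spread_fails_on_sd(self):
        rng = np.random.default_rng(0)
        _, sd, ok = aami_check(rng.normal(0, 12, size=5000))
        assert sd > 8 and not ok


class TestBHS:
    @pytest.mark.parametrize(
        "pcts,grade",
        [
            ((80.63, 95.86, 98.78), "A"),
            ((90.19, 98.29, 99.59), "A"),
            ((60.0, 85.0, 95.0), "A"),
            ((59.9, 99.0, 99.0), "B"),
            ((50.0, 75.0, 90.0), "B"),
            ((45.0, 70.0, 86.0), "C"),
            ((39.0, 64.0, 84.0), "D"),
        ],
    )
    def test_grading_table(self, pcts, grade):
        assert bhs_grade(*pcts) == grade

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            bhs_grade(80.0, 70.0, 90.0)
        with pytest.raises(ValueError):
            bhs_grade(-1.0, 50.0, 60.0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.tuples(
            st.floats(0, 100), st.floats(0, 100), st.floats(0, 100)
        ).map(sorted),
        st.floats(0, 20),
    )
    def test_raising_percentages_never_worsens_grade(self, pcts, bump):
        p5, p10, p15 = pcts
        order = "DCBA"
        g1 = bhs_grade(p5, p10, p15)
        g2 = bhs_grade(
            min(p5 + bump, 100.0), min(p10 + bump, 100.0), min(p15 + bump, 100.0)
        )
        assert order.index(g2) >= order.index(g1)

    def test_cumulative_percentages_inclusive_thresholds(self):
        errs = np.array([5.0, -10.0, 15.0, 16.0])
        assert bhs_cumulative_percentages(errs) == (25.0, 50.0, 75.0)


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.arange(10.0)
        assert pearson_r(x, -2 * x + 7) == pytest.approx(-1.0)

    def test_hand_computed_three_points(self):
        x, y = [1.0, 2.0, 3.0], [1.0, 2.0, 4.0]
        # direct formula: cov/(sx sy) with population sds
        expected = (
            sum((a - 2.0) * (b - 7 / 3) for a, b in zip(x, y))
            / (3 * np.std(x) * np.std(y))
        )
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(pearson_r(x, y), np.corrcoef(x, y)[0, 1], atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identical_arrays(self):
        x = np.array([100.0, 110.0, 120.0])
        mu, lo, hi, within = bland_altman(x, x)
        assert (mu, lo, hi, within) == (0.0, 0.0, 0.0, 100.0)

    def test_normal_differences_cover_95_percent(self):
        rng = np.random.default_rng(8)
        truth = np.full(10**5, 100.0)
        est = truth + rng.standard_normal(10**5)
        *_, within = bland_altman(truth, est)
        assert within == pytest.approx(95.0, abs=0.5)

    def test_constant_difference(self):
        truth = np.array([100.0, 110.0])
        mu, lo, hi, _ = bland_altman(truth, truth + 4.0)
        assert mu == lo == hi == 4.0


class TestEvaluate:
    def test_perfect_predictions(self):
        rng = np.random.default_rng(3)
        sbp = rng.normal(120, 10, 200)
        dbp = rng.normal(80, 7, 200)
        rep = evaluate(sbp, dbp, sbp, dbp)
        for tgt in (rep.sbp, rep.dbp):
            assert tgt.bhs_grade == "A" and tgt.aami_pass
            assert tgt.pearson_r == pytest.approx(1.0)
            assert tgt.cum_pct_5 == 100.0

    def test_matches_brute_force_on_random_trials(self):
        """Every report field vs an independent loop-based recomputation."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(10, 80))
            truth = rng.normal(120, 15, n)
            est = truth + rng.normal(
                rng.uniform(-6, 6), rng.uniform(0.5, 10), n
            )
            oracle = brute_force_report(truth.tolist(), est.tolist())
            rep = evaluate(truth, truth * 0.6, est, truth * 0.6 + 1.0).sbp
            assert rep.rmse_mmHg == pytest.approx(oracle["rmse"], abs=1e-9)
            assert rep.mae_mmHg == pytest.approx(oracle["mae"], abs=1e-9)
            assert rep.mean_error_mmHg == pytest.approx(oracle["me"], abs=1e-9)
            assert rep.sd_error_mmHg == pytest.approx(oracle["sd"], abs=1e-9)
            assert rep.pearson_r == pytest.approx(oracle["r"], abs=1e-9)
            assert rep.loa_low_mmHg == pytest.approx(oracle["loa_low"], abs=1e-9)
            assert rep.loa_high_mmHg == pytest.approx(oracle["loa_high"], abs=1e-9)
            assert rep.cum_pct_5 == pytest.approx(oracle["p5"], abs=1e-9)
            assert rep.cum_pct_10 == pytest.approx(oracle["p10"], abs=1e-9)
            assert rep.cum_pct_15 == pytest.approx(oracle["p15"], abs=1e-9)
            assert rep.pct_within_loa == pytest.approx(oracle["within"], abs=1e-9)
            assert rep.aami_pass == oracle["aami"]

    def test_monotone_cumulative_percentages(self):
        rng = np.random.default_rng(5)
        truth = rng.normal(120, 10, 500)
        est = truth + rng.normal(0, 6, 500)
        rep = evaluate(truth, truth, est, truth).sbp
        assert 0 <= rep.cum_pct_5 <= rep.cum_pct_10 <= rep.cum_pct_15 <= 100
        assert rep.rmse_mmHg >= rep.mae_mmHg >= 0
        assert rep.loa_low_mmHg <= rep.loa_high_mmHg

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            evaluate([120.0], [80.0], [121.0], [81.0])
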