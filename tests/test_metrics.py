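"""Agreement battery against ANOVA/pingouin oracles and hand arithmetic."""

import numpy as np
import pandas as pd
import pytest

from aacscore.metrics import (PairedScores, bland_altman,
                              boundary_distance_error, bootstrap_ci,
                              classification_report, evaluate, icc_2_1,
                              mean_bde, paired_tests, regression_fit_metrics,
                              tost_equivalence)


def anova_icc21(gt, pred):
    """Independent ICC(2,1) from the raw two-way ANOVA sums of squares."""
    x = np.column_stack([gt, pred]).astype(float)
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = (((x - x.mean(axis=1, keepdims=True)
             - x.mean(axis=0, keepdims=True) + grand)) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


@pytest.fixture
def toy_pairs():
    return PairedScores(pred=np.array([1.0, 9.0, 21.0]),
                        gt=np.array([0.0, 10.0, 20.0]))


class TestICC:
    def test_perfect_agreement_is_one(self):
        x = np.array([1.0, 5.0, 9.0, 14.0, 20.0])
        icc, _ = icc_2_1(PairedScores(x, x))
        assert icc == pytest.approx(1.0)

    def test_anticorrelated_toy_matches_anova_oracle(self):
        gt = np.array([1.0, 5.0, 3.0])
        pred = np.array([5.0, 1.0, 3.0])
        icc, _ = icc_2_1(PairedScores(pred, gt))
        assert icc == pytest.approx(anova_icc21(gt, pred), abs=1e-10)

    def test_random_sets_match_anova_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            gt = rng.integers(0, 25, n).astype(float)
            pred = np.clip(gt + rng.normal(0, 3, n), 0, 24)
            icc, _ = icc_2_1(PairedScores(pred, gt))
            assert icc == pytest.approx(anova_icc21(gt, pred), abs=1e-8)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        gt = rng.integers(0, 25, 30).astype(float)
        pred = np.clip(gt + rng.normal(0, 2, 30), 0, 24)
        icc, ci = icc_2_1(PairedScores(pred, gt))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(30), 2),
            "rater": np.tile(["gt", "pred"], 30),
            "score": np.column_stack([gt, pred]).ravel(),
        })
        res = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score").set_index("Type")
        # absolute-agreement single-measures row (naming varies by version)
        key = "ICC2" if "ICC2" in res.index else "ICC(A,1)"
        row = res.loc[key]
        ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
        assert icc == pytest.approx(row["ICC"], abs=1e-8)
        assert ci[0] == pytest.approx(row[ci_col][0], abs=6e-3)
        assert ci[1] == pytest.approx(row[ci_col][1], abs=6e-3)

    def test_constant_offset_penalized_vs_pearson(self):
        rng = np.random.default_rng(2)
        gt = rng.integers(0, 20, 40).astype(float)
        pred = gt + 3.0
        icc, _ = icc_2_1(PairedScores(pred, gt))
        assert icc < np.corrcoef(pred, gt)[0, 1]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1(PairedScores(np.zeros(5), np.zeros(5)))


class TestRegressionFit:
    def test_perfect_prediction(self):
        x = np.array([0.0, 10.0, 20.0])
        assert regression_fit_metrics(PairedScores(x, x)) == (0.0, 1.0, 1.0)

    def test_hand_computed_toy(self, toy_pairs):
        mae, r2, rho = regression_fit_metrics(toy_pairs)
        assert mae == pytest.approx(1.0)
        # SS_res = 1 + 1 + 1 = 3; SS_tot = 100 + 0 + 100 = 200
        assert r2 == pytest.approx(1.0 - 3.0 / 200.0)
        assert rho == pytest.approx(1.0)

    def test_reversed_ranking(self):
        gt = np.array([1.0, 5.0, 9.0, 13.0])
        _, _, rho = regression_fit_metrics(PairedScores(gt[::-1], gt))
        assert rho == pytest.approx(-1.0)

    def test_constant_gt_rejected(self):
        with pytest.raises(ValueError, match="R"):
            regression_fit_metrics(PairedScores(np.arange(4.0),
                                                np.full(4, 2.0)))


class TestBlandAltman:
    def test_identical_pairs(self):
        x = np.arange(5.0)
        assert bland_altman(PairedScores(x, x)) == (0.0, 0.0, 0.0)

    def test_alternating_differences(self):
        gt = np.zeros(4)
        pred = np.array([1.0, -1.0, 1.0, -1.0])
        bias, lo, hi = bland_altman(PairedScores(pred, gt))
        sd = 2.0 / np.sqrt(3.0)  # sample SD of (+1,-1,+1,-1)
        assert bias == 0.0
        assert lo == pytest.approx(-1.96 * sd)
        assert hi == pytest.approx(1.96 * sd)

    def test_positive_bias_when_pred_above_gt(self):
        gt = np.arange(6.0)
        bias, lo, hi = bland_altman(PairedScores(gt + 2.0, gt))
        assert bias == pytest.approx(2.0)
        assert lo <= bias <= hi


class TestPairedTests:
    def test_symmetric_differences_not_significant(self):
        gt = np.arange(10.0)
        pred = gt + np.array([1, -1] * 5, dtype=float)
        p, sig, thr = paired_tests(PairedScores(pred, gt))
        assert p > 0.5
        assert not sig

    def test_bonferroni_threshold(self):
        gt = np.arange(10.0)
        _, _, thr = paired_tests(PairedScores(gt + 1.0, gt),
                                 alpha=0.05, n_comparisons=3)
        assert round(thr, 3) == 0.017

    def test_all_zero_differences_flagged(self):
        x = np.arange(8.0)
        with pytest.warns(UserWarning, match="zero"):
            p, sig, _ = paired_tests(PairedScores(x, x))
        assert p == 1.0 and not sig


class TestTOST:
    def test_centered_differences_equivalent(self):
        rng = np.random.default_rng(0)
        gt = rng.integers(0, 20, 30).astype(float)
        pred = gt + rng.choice([-0.2, 0.0, 0.2], 30)
        ok, _, _ = tost_equivalence(PairedScores(pred, gt), 0.5)
        assert ok

    def test_shifted_differences_not_equivalent(self):
        gt = np.arange(12.0)
        ok, _, _ = tost_equivalence(PairedScores(gt + 2.0, gt), 1.0)
        assert not ok

    def test_nesting_half_point_implies_one_point(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            gt = rng.integers(0, 20, 25).astype(float)
            pred = gt + rng.normal(0, 0.6, 25)
            pairs = PairedScores(pred, gt)
            ok_half, _, _ = tost_equivalence(pairs, 0.5)
            ok_one, _, _ = tost_equivalence(pairs, 1.0)
            if ok_half:
                assert ok_one

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            tost_equivalence(PairedScores(np.arange(8.0), np.arange(8.0)),
                             0.0)


class TestBDE:
    @pytest.mark.parametrize("pred,gt,expected", [
        (14, 20, 2.0),   # gt severe, interval 16-24, nearest 16
        (5, 4, 1.0),     # gt no/mild, interval 0-4, nearest 4
        (10, 12, 0.0),   # same severity class
        (0, 24, 16.0),
    ])
    def test_distance_to_true_interval(self, pred, gt, expected):
        assert boundary_distance_error(pred, gt) == expected

    def test_zero_iff_severity_match(self):
        for pred in range(25):
            for gt in range(25):
                bde = boundary_distance_error(pred, gt)
                assert 0 <= bde <= 24
                from aacscore.kauppila import severity_class
                assert (bde == 0) == (severity_class(pred)
                                      == severity_class(gt))

    def test_mean_bde_over_misclassified_only(self):
        pairs = PairedScores(np.array([14.0, 5.0, 10.0]),
                             np.array([20.0, 4.0, 12.0]))
        assert mean_bde(pairs) == pytest.approx(1.5)


class TestClassification:
    def test_perfect_predictions(self):
        gt = np.array([2.0, 10.0, 20.0, 3.0, 8.0, 18.0])
        rep = classification_report(PairedScores(gt, gt))
        assert rep.acc == 100.0
        assert rep.sn == 100.0 and rep.sp == 100.0

    def test_hand_built_confusion(self):
        # truth: 4 no_mild, 4 moderate, 2 severe
        gt = np.array([0, 1, 2, 3, 8, 9, 10, 11, 20, 21], dtype=float)
        pred = np.array([0, 1, 8, 8, 8, 9, 10, 2, 20, 8], dtype=float)
        rep = classification_report(PairedScores(pred, gt))
        expect = np.array([[2, 2, 0], [1, 3, 0], [0, 1, 1]])
        assert np.array_equal(rep.confusion, expect)
        assert rep.acc == pytest.approx(60.0)
        # one-vs-rest by hand: SN = mean(2/4, 3/4, 1/2) = 0.5417
        assert rep.sn == pytest.approx(100 * (2 / 4 + 3 / 4 + 1 / 2) / 3)
        assert rep.ppv == pytest.approx(100 * (2 / 3 + 3 / 6 + 1 / 1) / 3)

    def test_collapsed_predictions_warn_and_exclude(self):
        gt = np.array([2.0, 10.0, 20.0, 3.0])
        pred = np.full(4, 10.0)
        with pytest.warns(UserWarning, match="zero denominator"):
            rep = classification_report(PairedScores(pred, gt))
        assert np.isfinite(rep.ppv)


class TestEvaluate:
    def test_perfect_report(self):
        gt = np.array([1.0, 8.0, 20.0, 4.0, 12.0, 17.0, 9.0, 2.0])
        with pytest.warns(UserWarning, match="zero"):
            rep = evaluate(PairedScores(gt, gt))
        assert rep.mae == 0.0 and rep.r2 == 1.0
        assert rep.icc == pytest.approx(1.0)
        assert rep.classification.acc == 100.0
        assert rep.mean_bde == 0.0
        assert not rep.wilcoxon_significant

    def test_fields_match_individual_operations(self):
        rng = np.random.default_rng(7)
        gt = rng.integers(0, 25, 40).astype(float)
        pred = np.clip(gt + rng.normal(0, 2, 40), 0, 24)
        pairs = PairedScores(pred, gt)
        rep = evaluate(pairs)
        mae, r2, rho = regression_fit_metrics(pairs)
        assert (rep.mae, rep.r2, rep.spearman_rho) == (mae, r2, rho)
        assert rep.icc == icc_2_1(pairs)[0]
        assert (rep.bias, rep.loa_low, rep.loa_high) == bland_altman(pairs)
        assert rep.mean_bde == mean_bde(pairs)
        # serializable
        import json
        parsed = json.loads(rep.to_json())
        assert parsed["n"] == 40
        assert "Spearman" in rep.to_text()

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(8)
        gt = rng.integers(0, 25, 50).astype(float)
        pred = np.clip(gt + rng.normal(0, 2, 50), 0, 24)
        pairs = PairedScores(pred, gt)
        mae = regression_fit_metrics(pairs)[0]
        lo, hi = bootstrap_ci(lambda p: regression_fit_metrics(p)[0],
                              pairs, n_resamples=200, seed=0)
        assert lo <= mae <= hi
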