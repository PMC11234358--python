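import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtafusion import (
    EvaluationReport,
    UndefinedMetricError,
    aupr,
    concordance_index,
    evaluate,
    mcnemar_test,
    mse,
    rm2,
)

from ._oracles import aupr_bruteforce, ci_bruteforce, mcnemar_exact_binomial, rm2_formula


class TestMSE:
    @pytest.mark.parametrize(
        "y, yhat, expected",
        [([1, 2], [1, 2], 0.0), ([0, 0], [1, 1], 1.0), ([1, 2, 3], [2, 2, 2], 2 / 3)],
    )
    def test_worked_values(self, y, yhat, expected):
        assert mse(y, yhat) == pytest.approx(expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length mismatch"):
            mse([1, 2], [1, 2, 3])


class TestConcordanceIndex:
    @pytest.mark.parametrize(
        "y, yhat, expected",
        [
            ([1, 2, 3], [0.1, 0.2, 0.3], 1.0),
            ([1, 2, 3], [0.3, 0.2, 0.1], 0.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 5 / 6),
        ],
    )
    def test_worked_values(self, y, yhat, expected):
        assert concordance_index(y, yhat) == pytest.approx(expected)

    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 51))
            y = rng.normal(size=n)
            # inject true-value and prediction ties
            if n > 4:
                y[: n // 3] = np.round(y[: n // 3], 1)
            yhat = np.round(rng.normal(size=n), 1)
            if np.all(y == y[0]):
                continue
            assert concordance_index(y, yhat) == pytest.approx(ci_bruteforce(y, yhat))

    def test_agrees_with_survival_library(self, rng):
        lifelines = pytest.importorskip("lifelines")
        for _ in range(50):
            n = int(rng.integers(5, 60))
            y = rng.normal(size=n)
            yhat = rng.normal(size=n)
            expected = lifelines.utils.concordance_index(y, yhat)
            assert concordance_index(y, yhat) == pytest.approx(expected)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.normal(size=80)
        yhat = rng.normal(size=80)
        base = concordance_index(y, yhat)
        assert concordance_index(y, np.exp(yhat)) == pytest.approx(base)
        assert concordance_index(y, 3 * yhat + 10) == pytest.approx(base)

    def test_all_equal_truth_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            concordance_index([2, 2, 2], [1, 2, 3])


class TestRm2:
    def test_perfect_predictions_give_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert rm2(y, y) == pytest.approx(1.0)

    def test_worked_value_matches_formula_oracle(self):
        y = [1, 2, 3, 4, 5]
        yhat = [1.1, 2.1, 2.9, 4.2, 4.9]
        assert rm2(y, yhat) == pytest.approx(rm2_formula(y, yhat), abs=1e-10)

    def test_agrees_with_formula_oracle_randomized(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 40))
            y = rng.normal(5, 2, size=n)
            yhat = y + rng.normal(0, rng.uniform(0.01, 2.0), size=n)
            if np.std(y) == 0 or np.std(yhat) == 0:
                continue
            assert rm2(y, yhat) == pytest.approx(rm2_formula(list(y), list(yhat)), abs=1e-10)

    def test_bounded_by_r_squared(self, rng):
        for _ in range(100):
            y = rng.normal(size=20)
            yhat = rng.normal(size=20)
            r2 = np.corrcoef(y, yhat)[0, 1] ** 2
            assert rm2(y, yhat) <= r2 + 1e-12

    def test_constant_sequence_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            rm2([1, 1, 1], [1, 2, 3])


class TestAUPR:
    @pytest.mark.parametrize(
        "labels, scores, expected",
        [
            ([1, 0], [0.9, 0.1], 1.0),
            ([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1], 1.0),
            ([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1], 5 / 6),
        ],
    )
    def test_worked_values(self, labels, scores, expected):
        assert aupr(labels, scores) == pytest.approx(expected)

    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 31))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            scores = rng.normal(size=n)
            assert aupr(labels, scores) == pytest.approx(aupr_bruteforce(list(labels), list(scores)))

    def test_agrees_with_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(50):
            labels = rng.integers(0, 2, size=100)
            scores = rng.normal(size=100)
            if labels.sum() in (0, 100):
                continue
            assert aupr(labels, scores) == pytest.approx(average_precision_score(labels, scores))

    def test_random_scores_approach_prevalence(self, rng):
        vals = []
        for _ in range(1000):
            labels = (rng.random(200) < 0.3).astype(int)
            if labels.sum() in (0, 200):
                continue
            vals.append(aupr(labels, rng.random(200)))
        assert abs(np.mean(vals) - 0.3) < 0.05

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            aupr([1, 1], [0.2, 0.4])


class TestMcNemar:
    def test_balanced_discordance_gives_p_one(self):
        # b = c = 5: exact two-sided p = min(1, 2 P(X<=5 | n=10)) = 1
        labels = np.zeros(10, dtype=int)
        preds_a = np.array([0] * 5 + [1] * 5)
        preds_b = np.array([1] * 5 + [0] * 5)
        assert mcnemar_test(labels, preds_a, preds_b) == pytest.approx(1.0)

    def test_one_sided_discordance_closed_form(self):
        # b = 10, c = 0: exact p = 2 * (1/2)^10
        labels = np.zeros(10, dtype=int)
        preds_a = np.zeros(10, dtype=int)  # all correct
        preds_b = np.ones(10, dtype=int)  # all wrong
        assert mcnemar_test(labels, preds_a, preds_b) == pytest.approx(2 * 0.5**10)

    def test_identical_predictions_give_p_one(self):
        labels = np.array([0, 1, 0, 1])
        preds = np.array([0, 1, 1, 0])
        assert mcnemar_test(labels, preds, preds) == 1.0

    def test_exact_branch_matches_binomial_oracle(self, rng):
        for _ in range(50):
            b = int(rng.integers(0, 12))
            c = int(rng.integers(0, 12))
            if b + c == 0:
                continue
            labels = np.zeros(b + c + 5, dtype=int)
            preds_a = np.concatenate([np.zeros(b), np.ones(c), np.zeros(5)]).astype(int)
            preds_b = np.concatenate([np.ones(b), np.zeros(c), np.zeros(5)]).astype(int)
            assert mcnemar_test(labels, preds_a, preds_b) == pytest.approx(
                mcnemar_exact_binomial(b, c)
            )

    def test_exact_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        b, c = 8, 3
        labels = np.zeros(b + c, dtype=int)
        preds_a = np.concatenate([np.zeros(b), np.ones(c)]).astype(int)
        preds_b = np.concatenate([np.ones(b), np.zeros(c)]).astype(int)
        table = [[0, b], [c, 0]]
        expected = sm_mcnemar(table, exact=True).pvalue
        assert mcnemar_test(labels, preds_a, preds_b) == pytest.approx(expected)

    def test_exact_and_chisquare_branches_agree_near_cutover(self, rng):
        from scipy import stats

        for total in range(20, 31):
            for b in range(5, total - 4):
                c = total - b
                if b == c:
                    # two-sided exact p caps at 1 for balanced discordance;
                    # the chi-square approximation cannot follow the cap
                    continue
                exact = mcnemar_exact_binomial(b, c)
                chi2 = (abs(b - c) - 1.0) ** 2 / (b + c)
                approx = stats.chi2.sf(chi2, df=1)
                assert abs(exact - approx) < 0.02


class TestEvaluate:
    def test_perfect_predictor(self):
        y = np.array([5.0, 6.0, 7.5, 8.0, 9.0])
        report = evaluate(y, y, threshold=7.0)
        assert report.mse == 0.0
        assert report.ci == 1.0
        assert report.rm2 == pytest.approx(1.0)
        assert report.aupr == 1.0
        assert report.threshold == 7.0
        assert report.n == 5

    def test_constant_predictions_hit_undefined_path(self):
        y = np.array([5.0, 6.0, 7.5, 8.0])
        with pytest.raises(UndefinedMetricError, match="rm2"):
            evaluate(y, np.full(4, 6.0), threshold=7.0)

    def test_fold_std_of_constant_metric_is_zero(self):
        y = np.array([5.0, 6.0, 7.5, 8.0, 9.0])
        folds = [{"y_true": y, "y_pred": y}] * 5
        report = evaluate(y, y, threshold=7.0, fold_predictions=folds)
        assert report.std_ci == 0.0
        assert report.std_rm2 == 0.0
        assert report.std_aupr == 0.0

    def test_report_validates_ranges(self):
        with pytest.raises(ValueError):
            EvaluationReport(mse=0.1, ci=1.5, rm2=0.5, aupr=0.5)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.integers(-1000, 1000), min_size=2, max_size=30),
    st.floats(-50, 50),
)
def test_ci_monotone_transform_property(values, shift):
    """CI depends on prediction ranks only (property over random inputs)."""
    y = np.arange(len(values), dtype=float)
    yhat = np.array(values, dtype=float)
    base = concordance_index(y, yhat)
    assert concordance_index(y, yhat + shift) == pytest.approx(base)
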