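import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from scipy.special import expit

from gendiag import codes, score


def matrix_from_counts(carrier_f, carrier_m, noncarrier_f, noncarrier_m,
                       label="A"):
    """2x2-table layout as an indicator matrix."""
    ind = np.r_[np.ones(carrier_f + carrier_m),
                np.zeros(noncarrier_f + noncarrier_m)]
    sex = np.r_[np.ones(carrier_f), np.zeros(carrier_m),
                np.ones(noncarrier_f), np.zeros(noncarrier_m)]
    ids = [f"P{i}" for i in range(len(sex))]
    return codes.CodeIndicatorMatrix(ids, [label], ind[:, None], sex)


def bh_bruteforce(p, alpha):
    """Independent step-up oracle: reject all i <= max{i: p(i) <= i*alpha/m}."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    kmax = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= alpha * i / m:
            kmax = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:kmax]] = True
    return reject


class TestUnivariateScreen:
    def test_or_equals_cross_product_ratio(self):
        m = matrix_from_counts(30, 10, 70, 90)
        res = score.univariate_screen(m)
        assert res.loc[0, "odds_ratio_female"] == pytest.approx(
            (30 * 90) / (10 * 70), rel=1e-12)
        assert res.loc[0, "converged"]

    def test_closed_form_matches_statsmodels_logit(self):
        m = matrix_from_counts(30, 10, 70, 90)
        res = score.univariate_screen(m)
        X = sm.add_constant(m.indicators.astype(float))
        ref = sm.Logit(m.sex.astype(float), X).fit(disp=0)
        assert np.log(res.loc[0, "odds_ratio_female"]) == pytest.approx(
            ref.params[1], abs=1e-6)
        ref0 = sm.Logit(m.sex.astype(float), X[:, :1]).fit(disp=0)
        lrt_ref = 2 * (ref.llf - ref0.llf)
        assert res.loc[0, "lrt"] == pytest.approx(lrt_ref, abs=1e-6)

    def test_sex_neutral_code_or_near_one(self):
        rng = np.random.default_rng(42)
        n = 40_000
        sex = rng.integers(0, 2, n)
        ind = (rng.random(n) < 0.3).astype(float)[:, None]
        m = codes.CodeIndicatorMatrix([f"P{i}" for i in range(n)], ["N"],
                                      ind, sex)
        res = score.univariate_screen(m)
        assert 0.9 < res.loc[0, "odds_ratio_female"] < 1.1

    def test_universal_code_flagged_nonconverged(self):
        m = matrix_from_counts(30, 30, 0, 0)
        res = score.univariate_screen(m)
        assert not res.loc[0, "converged"]
        assert np.isnan(res.loc[0, "p_value"])
        assert not score.adjust_pvalues(res["p_value"]).any()

    def test_zero_column_matrix_gives_empty_result(self):
        m = codes.CodeIndicatorMatrix(["P0"], [], np.zeros((1, 0)), [1])
        assert len(score.univariate_screen(m)) == 0


class TestAdjustPvalues:
    def test_bh_worked_example(self):
        p = [0.001, 0.01, 0.02, 0.04, 0.5]
        assert score.adjust_pvalues(p, 0.05, "bh").tolist() == \
            [True, True, True, True, False]

    def test_all_ones_rejects_nothing(self):
        assert not score.adjust_pvalues([1.0] * 10).any()

    @pytest.mark.parametrize("method", ["bh", "bonferroni"])
    def test_single_pvalue_reduces_to_raw_threshold(self, method):
        assert score.adjust_pvalues([0.04], 0.05, method).tolist() == [True]

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            score.adjust_pvalues([0.01], alpha=1.5)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50),
           st.sampled_from([0.01, 0.05, 0.1]))
    def test_bh_matches_bruteforce_oracle(self, p, alpha):
        assert score.adjust_pvalues(p, alpha, "bh").tolist() == \
            bh_bruteforce(p, alpha).tolist()


class TestSelectCodes:
    def _results(self, pvals):
        return pd.DataFrame({"code": [f"C{i}" for i in range(len(pvals))],
                             "odds_ratio_female": 2.0, "lrt": 5.0,
                             "p_value": pvals, "converged": True})

    def test_requires_significance_in_both_sets(self):
        train = self._results([1e-6, 1e-6, 0.9])
        valid = self._results([1e-6, 0.9, 1e-6])
        assert score.select_codes(train, valid) == ["C0"]

    def test_vocabulary_mismatch_rejected(self):
        train = self._results([0.01])
        valid = self._results([0.01, 0.02])
        with pytest.raises(ValueError, match="vocabular"):
            score.select_codes(train, valid)

    def test_discordant_directions_still_selected(self):
        train = self._results([1e-6])
        valid = self._results([1e-6])
        valid.loc[0, "odds_ratio_female"] = 0.2
        assert score.select_codes(train, valid) == ["C0"]

    def test_null_codes_essentially_never_selected(self, life_table):
        """Global null: two independent screens make a false selection need
        a BH discovery in both sets, so selections are vanishingly rare."""
        from gendiag import synthetic

        catalog = tuple((f"C{j:02d}", 0.1, 0.1) for j in range(100))
        total = 0
        for rep in range(20):
            cfg = synthetic.SimulationConfig(n_patients=2000,
                                             code_catalog=catalog, seed=rep)
            cohort = synthetic.generate_cohort(cfg, life_table)
            tr, va, _ = codes.split_dataset(cohort, seed=rep)
            mt, mv, _ = codes.filter_codes(codes.build_indicator_matrix(tr),
                                           codes.build_indicator_matrix(va))
            sel = score.select_codes(score.univariate_screen(mt),
                                     score.univariate_screen(mv))
            total += len(sel)
        assert total <= 5  # <= 0.25% of 2000 code-screens


class TestScoreModel:
    def test_single_code_model_matches_univariate_or(self):
        m = matrix_from_counts(30, 10, 70, 90)
        model = score.fit_score_model(m, ["A"])
        assert np.exp(model.coefficients[0]) == pytest.approx(
            (30 * 90) / (10 * 70), rel=1e-6)

    def test_coefficient_recovery_ten_codes(self):
        """Fitting the generating 10-code logistic model at n=20000 recovers
        every coefficient within 3 standard errors."""
        rng = np.random.default_rng(12)
        n, k = 20_000, 10
        truth = rng.uniform(-1.2, 1.2, k)
        b0 = -0.2
        X = (rng.random((n, k)) < 0.15).astype(float)
        sex = (rng.random(n) < expit(b0 + X @ truth)).astype(int)
        m = codes.CodeIndicatorMatrix([f"P{i}" for i in range(n)],
                                      [f"C{j}" for j in range(k)], X, sex)
        model = score.fit_score_model(m)
        ref = sm.Logit(sex.astype(float), sm.add_constant(X)).fit(disp=0)
        se = ref.bse[1:]
        assert np.all(np.abs(model.coefficients - truth) < 3 * se)

    def test_independent_codes_multivariate_close_to_univariate(self):
        rng = np.random.default_rng(5)
        n = 40_000
        X = (rng.random((n, 2)) < 0.15).astype(float)
        sex = (rng.random(n) < expit(-0.2 + X @ np.array([0.5, 0.8]))).astype(int)
        m = codes.CodeIndicatorMatrix([f"P{i}" for i in range(n)],
                                      ["C0", "C1"], X, sex)
        multi = score.fit_score_model(m).coefficients
        uni = np.log(score.univariate_screen(m)["odds_ratio_female"].to_numpy())
        # independence keeps marginal and conditional log-odds close
        # (non-collapsibility bias is a few percent at these effect sizes)
        assert np.all(np.abs(multi - uni) < 0.1)

    def test_no_selected_codes_rejected(self):
        m = matrix_from_counts(30, 10, 70, 90)
        with pytest.raises(ValueError, match="no selected codes"):
            score.fit_score_model(m, [])

    def test_separation_raises_informative_error(self):
        ind = np.r_[np.ones(20), np.zeros(20)][:, None]
        sex = np.r_[np.ones(20), np.zeros(20)]
        m = codes.CodeIndicatorMatrix([f"P{i}" for i in range(40)], ["S"],
                                      ind, sex)
        with pytest.raises(ValueError, match="separation|filter"):
            score.fit_score_model(m, ["S"])


class TestComputeScores:
    def _model(self, intercept=0.3, coefs=(0.7, -0.4)):
        return score.GenderScoreModel(["A", "B"], intercept,
                                      np.array(coefs), 100)

    def test_patient_without_selected_codes_scores_at_intercept(self):
        m = codes.CodeIndicatorMatrix(["P0"], ["Z"], np.ones((1, 1)), [0])
        s = score.compute_scores(self._model(), m)
        assert s[0] == pytest.approx(expit(0.3))

    def test_zero_model_scores_half(self):
        m = codes.CodeIndicatorMatrix(["P0", "P1"], ["A"],
                                      np.array([[1], [0]]), [0, 1])
        model = score.GenderScoreModel(["A"], 0.0, np.array([0.0]), 10)
        assert np.allclose(score.compute_scores(model, m), 0.5)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(3)
        ind = rng.integers(0, 2, (50, 2))
        m1 = codes.CodeIndicatorMatrix([f"P{i}" for i in range(50)],
                                       ["A", "B"], ind, np.zeros(50))
        m2 = codes.CodeIndicatorMatrix([f"P{i}" for i in range(50)],
                                       ["B", "A"], ind[:, ::-1], np.zeros(50))
        model = self._model()
        assert np.allclose(score.compute_scores(model, m1),
                           score.compute_scores(model, m2))

    def test_female_enriched_code_raises_scores(self, life_table,
                                                default_cohort):
        m = codes.build_indicator_matrix(default_cohort)
        res = score.univariate_screen(m)
        ok = res[res["converged"]]
        model = score.fit_score_model(
            m, sorted(ok[ok["p_value"] < 1e-4]["code"]))
        s = score.compute_scores(model, m)
        j = m.code_labels.index("Y070")
        carriers = m.indicators[:, j] == 1
        assert s[carriers].mean() > s[~carriers].mean()


class TestSummarizeScores:
    def test_constant_scores_give_constant_quantiles(self):
        out = score.summarize_scores([0.4] * 10, [0, 1] * 5, [25] * 10)
        assert (out["by_sex"][["q1", "median", "q3"]] == 0.4).all().all()

    def test_median_female_above_male_in_differential_cohort(self,
                                                             default_cohort):
        out = score.summarize_scores(default_cohort["gender_score"],
                                     default_cohort["sex"],
                                     default_cohort["age"])
        assert out["by_sex"].loc[1, "median"] >= out["by_sex"].loc[0, "median"]
        assert out["by_sex"].loc[1, "mean"] > out["by_sex"].loc[0, "mean"]

    def test_empty_group_absent_not_zeroed(self):
        out = score.summarize_scores([0.2, 0.6], [0, 0], [25, 37])
        assert list(out["by_sex"].index) == [0]
        assert set(out["by_age_decade"].index) == {20, 30}
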