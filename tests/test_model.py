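"""Logistic engine: ML fitting, prediction, odds ratios, factor tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from edenrisk import EdentulismRiskModel, FINAL_EQUATION, PredictionEquation
from edenrisk.model import fit_logistic_arrays


def _design(x):
    return pd.DataFrame({"intercept": np.ones(len(x)), "x": np.asarray(x, float)})


def _two_by_two(n1, k1, n0, k0):
    """Outcome data for a single binary predictor: k events of n per level."""
    x = np.r_[np.ones(n1), np.zeros(n0)]
    y = np.r_[np.ones(k1), np.zeros(n1 - k1), np.ones(k0), np.zeros(n0 - k0)]
    return _design(x), y


class TestFit:
    def test_saturated_two_by_two_matches_closed_form(self):
        X, y = _two_by_two(20, 5, 20, 2)
        res = EdentulismRiskModel(y, X).fit()
        assert res.converged
        assert res.params["x"] == pytest.approx(np.log(3.0), abs=1e-6)
        assert res.params["intercept"] == pytest.approx(np.log(2 / 18), abs=1e-6)

    def test_intercept_only_balanced_outcome_gives_zero(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        X = pd.DataFrame({"intercept": np.ones(100)})
        res = EdentulismRiskModel(y, X).fit()
        assert res.params["intercept"] == pytest.approx(0.0, abs=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(1, 30), st.integers(1, 30),
                     st.integers(1, 30), st.integers(1, 30)))
    def test_closed_form_on_random_saturated_problems(self, cells):
        """ML fit equals the 2x2 log-odds closed form when all cells >= 1."""
        a, b, c, d = cells  # events/non-events at x=1 and x=0
        X, y = _two_by_two(a + b, a, c + d, c)
        res = EdentulismRiskModel(y, X).fit()
        assert res.params["intercept"] == pytest.approx(np.log(c / d), abs=1e-5)
        assert res.params["x"] == pytest.approx(
            np.log(a / b) - np.log(c / d), abs=1e-5)

    def test_agrees_with_statsmodels_on_cohort_fit(self, small_cohort):
        import statsmodels.api as sm
        from edenrisk import ModelSpec, encode_design

        spec = ModelSpec(("cognition",))
        X = encode_design(small_cohort, spec)
        ours = EdentulismRiskModel.from_cohort(small_cohort, spec).fit()
        ref = sm.Logit(small_cohort.outcome, X).fit(disp=0)
        np.testing.assert_allclose(ours.params.to_numpy(), ref.params.to_numpy(),
                                   atol=1e-6)
        np.testing.assert_allclose(ours.bse.to_numpy(), ref.bse.to_numpy(),
                                   atol=1e-6)
        assert ours.llf == pytest.approx(ref.llf, abs=1e-6)

    def test_separation_flagged_not_silent(self):
        X, y = _two_by_two(10, 10, 10, 0)  # perfect separation
        res = EdentulismRiskModel(y, X).fit()
        assert not res.converged
        with pytest.raises(ValueError):
            res.odds_ratios()

    def test_degenerate_outcome_is_an_error(self):
        X = _design(np.arange(10))
        with pytest.raises(ValueError):
            fit_logistic_arrays(X.to_numpy(), np.zeros(10))
        with pytest.raises(ValueError):
            fit_logistic_arrays(X.to_numpy(), np.ones(10))

    def test_collinear_design_is_an_error(self):
        rng = np.random.default_rng(0)
        x = rng.random(50)
        X = pd.DataFrame({"intercept": 1.0, "x": x, "x2": 2 * x})
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(ValueError, match="singular|dependent"):
            EdentulismRiskModel(y, X).fit()

    def test_covariance_diag_matches_standard_errors(self, small_cohort):
        from edenrisk import ModelSpec

        res = EdentulismRiskModel.from_cohort(small_cohort, ModelSpec()).fit()
        np.testing.assert_allclose(
            res.bse.to_numpy() ** 2, np.diag(res.cov_params().to_numpy()))
        eigs = np.linalg.eigvalsh(res.cov_params().to_numpy())
        assert (eigs > 0).all()


class TestPredictionEquation:
    def test_midpoint_probability(self):
        eq = PredictionEquation(intercept=0.0, coefficients={"x": 1.0})
        assert eq.predict({"x": 0.0})[0] == pytest.approx(0.5)

    def test_all_reference_67_year_old(self):
        row = {t: 0.0 for t in FINAL_EQUATION.terms}
        row["A"] = 6.7
        assert FINAL_EQUATION.linear_predictor(row)[0] == pytest.approx(-3.8074)
        assert FINAL_EQUATION.predict(row)[0] == pytest.approx(0.0217, abs=5e-4)

    def test_maximal_risk_67_year_old(self):
        row = {t: 0.0 for t in FINAL_EQUATION.terms}
        row.update({"A": 6.7, "R1": 1, "G": 1, "E0": 1, "S0": 1, "D": 1, "C": 1})
        assert FINAL_EQUATION.linear_predictor(row)[0] == pytest.approx(0.3606)
        assert FINAL_EQUATION.predict(row)[0] == pytest.approx(0.589, abs=5e-4)

    def test_missing_term_error_names_it(self):
        row = {t: 0.0 for t in FINAL_EQUATION.terms if t != "C"}
        with pytest.raises(ValueError, match="C"):
            FINAL_EQUATION.predict(row)

    def test_probabilities_strictly_inside_unit_interval(self, small_cohort):
        from edenrisk import ModelSpec, encode_design

        p = FINAL_EQUATION.predict(
            encode_design(small_cohort, ModelSpec(("cognition",))))
        assert (p > 0).all() and (p < 1).all()

    def test_prediction_increases_in_positive_indicator(self):
        base = {t: 0.0 for t in FINAL_EQUATION.terms}
        base["A"] = 6.7
        p0 = FINAL_EQUATION.predict(base)[0]
        for term in ("R1", "S0", "D", "C", "E0"):
            bumped = dict(base, **{term: 1.0})
            assert FINAL_EQUATION.predict(bumped)[0] > p0


class TestOddsRatios:
    def test_published_coefficients_reproduce_reported_ors(self):
        expected = {"R1": 1.60, "R2": 1.38, "R3": 0.88, "G": 1.08, "A": 1.17,
                    "E0": 2.48, "E1": 1.91, "S0": 3.53, "S1": 1.48, "D": 2.34,
                    "C": 1.82}
        ors = FINAL_EQUATION.odds_ratios()
        for term, val in expected.items():
            assert round(ors[term], 2) == val

    def test_zero_coefficient_is_unit_odds(self):
        eq = PredictionEquation(intercept=-1.0, coefficients={"x": 0.0})
        assert eq.odds_ratios()["x"] == pytest.approx(1.0)

    def test_log_odds_round_trip(self, small_cohort):
        from edenrisk import ModelSpec

        res = EdentulismRiskModel.from_cohort(small_cohort, ModelSpec()).fit()
        table = res.odds_ratios()
        recovered = np.log(table["odds_ratio"])
        np.testing.assert_allclose(
            recovered.to_numpy(), res.params.drop("intercept").to_numpy(),
            atol=1e-12)

    def test_wald_bounds_use_normal_quantile(self, small_cohort):
        from edenrisk import ModelSpec

        res = EdentulismRiskModel.from_cohort(small_cohort, ModelSpec()).fit()
        table = res.odds_ratios(confidence=0.95)
        term = "S0"
        b, se = res.params[term], res.bse[term]
        assert table.loc[term, "lower"] == pytest.approx(np.exp(b - 1.96 * se),
                                                         rel=1e-4)
        assert table.loc[term, "upper"] == pytest.approx(np.exp(b + 1.96 * se),
                                                         rel=1e-4)


class TestFactorTests:
    def test_g_statistic_matches_hand_computation(self):
        # G = 2*(llf_full - llf_reduced) with closed-form binomial logliks
        a, b, c, d = 12, 18, 5, 25  # events/non-events by level
        X, y = _two_by_two(a + b, a, c + d, c)
        spec_full = EdentulismRiskModel(y, X).fit()
        stat, df, p = _lrt_from_results(spec_full, ["x"])

        def binom_ll(k, n):
            q = k / n
            return k * np.log(q) + (n - k) * np.log(1 - q)

        ll_full = binom_ll(a, a + b) + binom_ll(c, c + d)
        k, n = a + c, a + b + c + d
        ll_null = binom_ll(k, n)
        assert stat == pytest.approx(2 * (ll_full - ll_null), abs=1e-6)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(stat, 1))

    def test_two_level_factor_drops_one_degree_of_freedom(self, small_cohort):
        from edenrisk import ModelSpec

        res = EdentulismRiskModel.from_cohort(
            small_cohort, ModelSpec(("cognition",))).fit()
        _, df, _ = res.lrt_factor("gender")
        assert df == 1
        _, df_race, _ = res.lrt_factor("race")
        assert df_race == 3

    def test_null_predictor_p_values_are_uniform(self):
        """LRT p-values for a null binary factor are U(0,1) (KS check)."""
        rng = np.random.default_rng(42)
        n = 2000
        pvals = []
        for _ in range(200):
            x = (rng.random(n) < 0.4).astype(float)
            y = (rng.random(n) < 0.15).astype(float)  # independent of x
            X = _design(x)
            res = EdentulismRiskModel(y, X).fit()
            _, _, p = _lrt_from_results(res, ["x"])
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_factor_tests_table_covers_all_variables(self, small_cohort):
        from edenrisk import ModelSpec

        spec = ModelSpec(("cognition",))
        res = EdentulismRiskModel.from_cohort(small_cohort, spec).fit()
        table = res.factor_tests()
        assert set(table.index) == set(spec.variables)
        assert (table["p_value"].between(0, 1)).all()


def _lrt_from_results(results, dropped_terms):
    """LRT by explicit refit (independent of the variable-name mapping)."""
    keep = [t for t in results.params.index if t not in dropped_terms]
    reduced = EdentulismRiskModel(
        results.model.endog, results.model.exog[keep]).fit()
    stat = 2.0 * (results.llf - reduced.llf)
    df = len(results.params) - len(keep)
    return stat, df, float(stats.chi2.sf(stat, df))
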