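"""Outcome construction, 25(OH)D categories, logistic fits, FP tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitdmr import (
    OneClassOutcomeError,
    OutcomeSpec,
    build_outcomes,
    categorize_vitd,
    fit_categorical,
    fit_continuous,
    fp_nonlinearity_test,
)


class TestBuildOutcomes:
    """Oracle: exhaustive hand enumeration of the 12-row wave table."""

    def test_baseline_enumeration(self, toy_waves):
        out = build_outcomes(toy_waves, OutcomeSpec("si", "baseline"))
        assert len(out) == 11          # row 10 has missing wave 1
        assert out["outcome"].sum() == 3  # rows 4, 5, 11

    def test_incident_1y_enumeration(self, toy_waves):
        out = build_outcomes(toy_waves, OutcomeSpec("si", "incident_1y"))
        assert len(out) == 6           # rows 0,1,2,3,8,9
        assert out["outcome"].sum() == 3  # rows 1, 3, 9

    def test_incident_2y_enumeration(self, toy_waves):
        # positive if wave 2 and/or wave 3 positive; w2=no,w3=missing is unknown
        out = build_outcomes(toy_waves, OutcomeSpec("si", "incident_2y"))
        assert len(out) == 6           # rows 0,1,2,3,7,9
        assert out["outcome"].sum() == 5

    def test_w2_yes_w3_no_counts_as_case(self, toy_waves):
        out = build_outcomes(toy_waves, OutcomeSpec("si", "incident_2y"))
        assert out.loc[1, "outcome"] == 1  # (no, yes, no)

    def test_baseline_positive_excluded_from_incident(self, toy_waves):
        out = build_outcomes(toy_waves, OutcomeSpec("si", "incident_1y"))
        assert 4 not in out.index and 5 not in out.index

    def test_incident_sets_subset_of_baseline_negatives(self, cohort):
        neg = set(cohort.index[cohort["si_w1"] == 0])
        for horizon in ("incident_1y", "incident_2y"):
            got = set(build_outcomes(cohort, OutcomeSpec("si", horizon)).index)
            assert got <= neg

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            OutcomeSpec("xx", "baseline")
        with pytest.raises(ValueError):
            OutcomeSpec("si", "incident_3y")


class TestCategorizeVitd:
    @pytest.mark.parametrize("value, expected", [
        (19.99, "deficiency"),
        (20.0, "insufficiency"),
        (29.999, "insufficiency"),
        (30.0, "sufficiency"),
        (23.12, "insufficiency"),
    ])
    def test_boundaries(self, value, expected):
        assert categorize_vitd(value) == expected

    @given(st.floats(min_value=0.01, max_value=200.0,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partition(self, x):
        """Every positive concentration maps to exactly one category."""
        cat = categorize_vitd(x)
        assert cat in ("deficiency", "insufficiency", "sufficiency")
        assert (cat == "deficiency") == (x < 20)
        assert (cat == "sufficiency") == (x >= 30)

    def test_counts_sum_to_n(self, cohort):
        cats = categorize_vitd(cohort["vitd"].dropna())
        assert cats.value_counts().sum() == cohort["vitd"].notna().sum()

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            categorize_vitd(0.0)


def _binary_exposure_frame(a, b, c, d):
    """2x2 layout: a=exposed cases, b=exposed controls, c=unexposed cases,
    d=unexposed controls."""
    return pd.DataFrame({
        "outcome": [1] * a + [0] * b + [1] * c + [0] * d,
        "vitd": [1.0] * (a + b) + [0.0] * (c + d),
    })


class TestFitContinuous:
    def test_matches_two_by_two_cross_product(self):
        """Logistic MLE on one binary predictor equals the closed-form
        cross-product odds ratio."""
        df = _binary_exposure_frame(10, 90, 20, 80)
        fit = fit_continuous(df)
        expected = np.log((10 * 80) / (90 * 20))
        assert fit.coef("vitd") == pytest.approx(expected, abs=1e-6)
        or_, lo, hi = fit.odds_ratio("vitd")
        assert lo < or_ < hi

    def test_null_association_or_near_one(self, rng):
        df = pd.DataFrame({"outcome": rng.binomial(1, 0.3, 20000),
                           "vitd": rng.normal(23, 5, 20000)})
        or_, lo, hi = fit_continuous(df).odds_ratio("vitd")
        assert lo < 1 < hi

    def test_one_class_outcome_raises(self):
        df = pd.DataFrame({"outcome": [1] * 30, "vitd": np.linspace(10, 30, 30)})
        with pytest.raises(OneClassOutcomeError):
            fit_continuous(df)

    def test_covariate_adjustment_runs(self, cohort):
        out = build_outcomes(cohort, OutcomeSpec("si", "baseline"))
        fit = fit_continuous(out, ["age", "sex", "depression"])
        assert fit.n == len(out.dropna(subset=["vitd", "age", "sex", "depression"]))
        assert any("vitd" == t for t in fit.terms)


class TestFitCategorical:
    def test_recovers_constructed_or(self, rng):
        """Stratified 2x2 oracle: insufficiency OR built as 0.5 vs
        deficiency is recovered by the dummy-coded logistic fit."""
        n = 4000
        vitd = np.concatenate([
            rng.uniform(10, 19.9, n), rng.uniform(20, 29.9, n), rng.uniform(30, 40, n)])
        p_def = 0.2
        odds_def = p_def / (1 - p_def)
        p_ins = odds_def * 0.5 / (1 + odds_def * 0.5)
        p_suf = odds_def * 0.8 / (1 + odds_def * 0.8)
        p = np.concatenate([np.full(n, p_def), np.full(n, p_ins), np.full(n, p_suf)])
        df = pd.DataFrame({"outcome": rng.binomial(1, p), "vitd": vitd})
        fit = fit_categorical(df)
        or_ins, lo, hi = fit.odds_ratio("vitd_cat[insufficiency]")
        assert lo < 0.5 < hi
        assert or_ins == pytest.approx(0.5, abs=0.12)

    def test_equal_rates_give_or_near_one(self, rng):
        vitd = rng.uniform(10, 40, 6000)
        df = pd.DataFrame({"outcome": rng.binomial(1, 0.25, 6000), "vitd": vitd})
        fit = fit_categorical(df)
        for term in ("vitd_cat[insufficiency]", "vitd_cat[sufficiency]"):
            _, lo, hi = fit.odds_ratio(term)
            assert lo < 1 < hi

    def test_missing_category_reported_not_fitted(self, rng):
        vitd = np.concatenate([rng.uniform(10, 19.9, 500), rng.uniform(20, 29.9, 500)])
        df = pd.DataFrame({"outcome": rng.binomial(1, 0.3, 1000), "vitd": vitd})
        fit = fit_categorical(df)
        assert "sufficiency" in fit.undefined
        assert any("insufficiency" in t for t in fit.terms)


class TestFpNonlinearity:
    def test_loglik_ordering(self, cohort):
        out = build_outcomes(cohort, OutcomeSpec("si", "baseline"))
        fp = fp_nonlinearity_test(out, ["age", "sex"])
        assert fp.loglik_best_d2 >= fp.loglik_best_d1 >= fp.loglik_linear
        assert fp.loglik_linear >= fp.loglik_null
        assert 0 <= fp.p_overall <= 1 and 0 <= fp.p_nonlinear <= 1

    def test_u_shape_detected(self, rng):
        """Strong quadratic logit at n = 5,000 is flagged as non-linear."""
        x = rng.normal(23, 5.8, 5000).clip(5, None)
        eta = -1.0 + 0.02 * (x - 23) ** 2
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        df = pd.DataFrame({"outcome": y, "vitd": x})
        fp = fp_nonlinearity_test(df)
        assert fp.p_nonlinear < 0.05
        assert fp.p_overall < 1e-4

    def test_linear_truth_keeps_power_one_competitive(self, linear_cohort):
        out = build_outcomes(linear_cohort, OutcomeSpec("si", "baseline"))
        fp = fp_nonlinearity_test(out, ["age", "sex"])
        # linear is in the degree-1 family, so its deviance can't beat best d1
        assert fp.loglik_best_d1 >= fp.loglik_linear
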