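"""Instrument-free stratification, LACEs, meta-regression and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from vitdmr import (
    NonlinearMR,
    OutcomeSpec,
    RatioMR,
    build_outcomes,
    compute_laces,
    fp_meta_regression,
    instrument_constancy,
    instrument_free_exposure,
    stratify_deciles,
)
from vitdmr.nonlinear import LaceStratum
from vitdmr.observational import _prepare


class TestInstrumentFreeExposure:
    def test_residuals_orthogonal_to_pgs(self, cohort):
        resid = instrument_free_exposure(cohort)
        pgs = cohort.loc[resid.index, "pgs"].astype(float)
        assert abs(np.corrcoef(resid, pgs)[0, 1]) < 1e-10

    def test_constant_pgs_gives_centred_exposure(self, cohort):
        df = cohort.copy()
        df["pgs"] = 3
        resid = instrument_free_exposure(df, include_age_sex=False)
        expected = df.loc[resid.index, "vitd"].astype(float)
        expected = expected - expected.mean()
        np.testing.assert_allclose(resid, expected, atol=1e-10)

    def test_residual_sd_below_raw_sd(self, cohort):
        """Variance decomposition: removing the PGS share shrinks the SD."""
        resid = instrument_free_exposure(cohort, include_age_sex=False)
        raw = cohort.loc[resid.index, "vitd"].astype(float)
        assert resid.std() < raw.std()


class TestStratifyDeciles:
    def test_equal_strata_when_divisible(self, rng):
        s = pd.Series(rng.normal(size=100))
        lab = stratify_deciles(s, 10)
        assert (lab.value_counts() == 10).all()

    def test_near_equal_partition_1411(self, rng):
        s = pd.Series(rng.normal(size=1411))
        sizes = stratify_deciles(s, 10).value_counts()
        assert sizes.sum() == 1411
        assert set(sizes) <= {141, 142}

    def test_strata_ordered_by_value(self, rng):
        s = pd.Series(rng.normal(size=200))
        lab = stratify_deciles(s, 10)
        means = s.groupby(lab).mean()
        assert means.is_monotonic_increasing

    def test_too_small_sample_raises(self, rng):
        with pytest.raises(ValueError, match="at least 100"):
            stratify_deciles(pd.Series(rng.normal(size=50)), 10)

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            stratify_deciles(pd.Series(np.ones(200)), 10)

    def test_deterministic_given_order(self, rng):
        s = pd.Series(rng.normal(size=150))
        pd.testing.assert_series_equal(stratify_deciles(s), stratify_deciles(s))


def _analysis_set(cohort, spec=OutcomeSpec("si", "baseline")):
    return _prepare(build_outcomes(cohort, spec), ("age", "sex"), ["vitd", "pgs"])


class TestComputeLaces:
    def test_single_stratum_equals_linear_mr(self, cohort):
        """K = 1 degenerates to the whole-sample ratio estimate."""
        sub = _analysis_set(cohort)
        assignment = pd.Series(1, index=sub.index)
        strata = compute_laces(sub, assignment)
        ref = RatioMR(cohort, "si_baseline").fit()
        assert strata[0].lace_j == pytest.approx(ref.beta_iv, rel=1e-9)
        assert strata[0].se_lace_j == pytest.approx(ref.se_iv, rel=1e-9)

    def test_x_means_increase_with_stratum(self, cohort):
        sub = _analysis_set(cohort)
        resid = instrument_free_exposure(sub)
        strata = compute_laces(sub, stratify_deciles(resid))
        x = [s.x_mean for s in strata]
        assert all(a < b for a, b in zip(x, x[1:]))
        assert sum(s.n_j for s in strata) == len(resid)

    def test_one_class_stratum_flagged(self, cohort):
        sub = _analysis_set(cohort).copy()
        resid = instrument_free_exposure(sub)
        assignment = stratify_deciles(resid)
        sub.loc[assignment[assignment == 1].index, "outcome"] = 0
        strata = compute_laces(sub, assignment)
        assert not strata[0].usable and strata[0].reason
        assert all(s.usable for s in strata[1:])


class TestInstrumentConstancy:
    @staticmethod
    def _stratum(i, bx, se, xm):
        return LaceStratum(index=i, n_j=100, n_cases=20, x_mean=xm,
                           beta_x_j=bx, se_x_j=se)

    def test_identical_slopes_give_q_zero_p_one(self):
        strata = [self._stratum(i, -1.0, 0.1, 15 + i) for i in range(10)]
        p_q, _ = instrument_constancy(strata)
        assert p_q == pytest.approx(1.0)

    def test_forced_trend_detected(self):
        strata = [self._stratum(i, -1.0 + 0.2 * i, 0.001, 15 + i) for i in range(10)]
        _, p_trend = instrument_constancy(strata)
        assert p_trend < 1e-10

    def test_requires_three_strata(self):
        with pytest.raises(ValueError):
            instrument_constancy([self._stratum(0, -1, 0.1, 15),
                                  self._stratum(1, -1, 0.1, 16)])


class TestFpMetaRegression:
    @staticmethod
    def _strata(laces, ses, x_means, bx=-1.0, bx_se=0.1):
        return [
            LaceStratum(index=i + 1, n_j=140, n_cases=30, x_mean=float(x),
                        beta_x_j=bx, se_x_j=bx_se, beta_y_j=float(l * bx),
                        se_y_j=float(s * abs(bx)), lace_j=float(l), se_lace_j=float(s))
            for i, (l, s, x) in enumerate(zip(laces, ses, x_means))
        ]

    def test_equal_laces_reduce_to_linear(self):
        """Identical LACEs with equal SEs: Q = 0, p = 1, and the best
        degree-1 FP is the straight line (power 1)."""
        strata = self._strata([0.05] * 10, [0.01] * 10, np.linspace(15, 31, 10))
        res = fp_meta_regression(strata)
        assert res.p_cochran_q == pytest.approx(1.0)
        assert res.p_fp == pytest.approx(1.0)
        assert res.best_fp1_power == 1.0
        assert res.pooled_lace == pytest.approx(0.05)

    def test_strong_gradient_detected(self, rng):
        laces = np.linspace(0.3, -0.3, 10)
        strata = self._strata(laces, [0.01] * 10, np.linspace(15, 31, 10))
        res = fp_meta_regression(strata)
        assert res.p_quadratic < 1e-10
        assert res.p_cochran_q < 1e-10

    def test_unusable_strata_excluded_with_warning(self):
        strata = self._strata([0.05] * 10, [0.01] * 10, np.linspace(15, 31, 10))
        strata[0].usable = False
        with pytest.warns(UserWarning, match="excluded"):
            res = fp_meta_regression(strata)
        assert res.n_excluded_strata == 1

    def test_too_few_strata_raise(self):
        strata = self._strata([0.05] * 3, [0.01] * 3, [15, 20, 25])
        with pytest.raises(ValueError, match=">= 4"):
            fp_meta_regression(strata)


class TestNonlinearMRModel:
    def test_pipeline_runs_on_default_cohort(self, cohort):
        res = NonlinearMR(cohort, "si_baseline").fit()
        assert len(res.strata) == 10
        for p in (res.p_fp, res.p_quadratic, res.p_cochran_q,
                  res.p_q_instrument, res.p_trend_instrument):
            assert 0 <= p <= 1
        assert "pooled LACE" in res.summary()

    def test_linear_truth_pooled_lace_matches_ratio_mr(self, linear_cohort):
        """Under a linear causal model the pooled LACE and the whole-sample
        ratio estimate agree within Monte-Carlo error."""
        nl = NonlinearMR(linear_cohort, "si_baseline").fit()
        lin = RatioMR(linear_cohort, "si_baseline").fit()
        joint = np.hypot(nl.se_pooled_lace, lin.se_iv)
        assert abs(nl.pooled_lace - lin.beta_iv) < 3 * joint

    def test_pgs_shift_invariance(self, cohort):
        """Adding a constant to the PGS changes no test p-value."""
        a = NonlinearMR(cohort, "si_baseline").fit()
        shifted = cohort.assign(pgs=cohort["pgs"] + 5)
        b = NonlinearMR(shifted, "si_baseline").fit()
        assert b.p_fp == pytest.approx(a.p_fp, rel=1e-6)
        assert b.p_quadratic == pytest.approx(a.p_quadratic, rel=1e-6)
        assert b.p_cochran_q == pytest.approx(a.p_cochran_q, rel=1e-6)

    def test_strata_frame_layout(self, cohort):
        res = NonlinearMR(cohort, "sp_baseline").fit()
        frame = res.strata_frame()
        assert {"index", "n_j", "x_mean", "lace_j", "se_lace_j"} <= set(frame.columns)
        assert len(frame) == 10
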