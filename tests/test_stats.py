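import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as hst
from scipy import stats as sps

from camhip.pipeline import table_to_hips
from camhip.stats import (
    SeparationError,
    TwoByTwo,
    ZeroCellError,
    chi_squared,
    cohens_kappa,
    crude_or,
    gee_logistic,
    lins_ccc,
    one_way_anova,
    pearson_r,
    standardize,
    two_sample_t,
)

counts = hst.integers(min_value=1, max_value=500)


class TestCrudeOr:
    def test_balanced_table_is_null(self):
        res = crude_or(TwoByTwo(10, 10, 10, 10))
        assert res.or_ == pytest.approx(1.0)
        assert res.ci_low * res.ci_high == pytest.approx(1.0)  # symmetric on log scale
        assert res.p == pytest.approx(1.0)

    @given(a=counts, b=counts, c=counts, d=counts)
    def test_swapping_exposure_rows_inverts_the_odds_ratio(self, a, b, c, d):
        r1 = crude_or(TwoByTwo(a, b, c, d))
        r2 = crude_or(TwoByTwo(c, d, a, b))
        assert r2.or_ == pytest.approx(1.0 / r1.or_, rel=1e-12)
        assert r2.ci_low == pytest.approx(1.0 / r1.ci_high, rel=1e-12)
        assert r2.ci_high == pytest.approx(1.0 / r1.ci_low, rel=1e-12)
        assert r2.p == pytest.approx(r1.p, rel=1e-9)

    def test_zero_cell_raises_unless_corrected(self):
        with pytest.raises(ZeroCellError, match="cell b"):
            crude_or(TwoByTwo(5, 0, 3, 7))
        res = crude_or(TwoByTwo(5, 0, 3, 7), haldane=True)
        assert res.method == "wald-haldane"
        assert res.or_ == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))


class TestGeeLogistic:
    def test_independence_unadjusted_equals_crude_or(self):
        t = TwoByTwo(30, 25, 14, 40)
        hips = table_to_hips(t)
        fit = gee_logistic(hips, "outcome", ["exposure"], "subject_id",
                           working="independence")
        assert fit.converged
        assert fit.coef("exposure") == pytest.approx(crude_or(t).log_or, abs=1e-6)

    def test_singleton_clusters_make_exchangeable_equal_independence(self, rng):
        n = 200
        df = pd.DataFrame(
            {
                "subject_id": [f"C{i}" for i in range(n)],  # all clusters size 1
                "x": rng.normal(size=n),
            }
        )
        df["y"] = (rng.uniform(size=n) < 1 / (1 + np.exp(-0.5 * df.x))).astype(int)
        f_ind = gee_logistic(df, "y", ["x"], "subject_id", working="independence")
        f_exc = gee_logistic(df, "y", ["x"], "subject_id", working="exchangeable")
        np.testing.assert_allclose(f_exc.coefficients, f_ind.coefficients, atol=1e-10)
        np.testing.assert_allclose(f_exc.robust_se, f_ind.robust_se, atol=1e-10)

    @pytest.mark.parametrize("working,cov_struct", [
        ("independence", sm.cov_struct.Independence),
        ("exchangeable", sm.cov_struct.Exchangeable),
    ])
    def test_matches_statsmodels_oracle(self, working, cov_struct, rng):
        n = 300
        subj = np.repeat(np.arange(n), 2)
        u = np.repeat(rng.normal(0, 1, n), 2)
        x = rng.binomial(1, 0.3, 2 * n)
        age = rng.normal(60, 10, 2 * n)
        y = (rng.uniform(size=2 * n) <
             1 / (1 + np.exp(-(-1.0 + 0.8 * x + 0.02 * (age - 60) + u)))).astype(int)
        df = pd.DataFrame({"subject_id": subj, "x": x, "age": age, "y": y})
        mine = gee_logistic(df, "y", ["x", "age"], "subject_id", working=working)
        ref = sm.GEE.from_formula(
            "y ~ x + age", groups="subject_id", data=df,
            family=sm.families.Binomial(), cov_struct=cov_struct(),
        ).fit()
        np.testing.assert_allclose(mine.coefficients, ref.params.values, atol=1e-7)
        np.testing.assert_allclose(mine.robust_se, ref.bse.values, rtol=1e-6)
        if working == "exchangeable":
            assert mine.alpha_hat == pytest.approx(ref.cov_struct.dep_params, abs=1e-7)

    def test_point_estimate_independent_of_cluster_assignment(self, rng):
        t = TwoByTwo(40, 60, 25, 75)
        hips = table_to_hips(t)
        shuffled = hips.copy()
        shuffled["subject_id"] = rng.permutation(shuffled["subject_id"].to_numpy())
        a = gee_logistic(hips, "outcome", ["exposure"], "subject_id", "independence")
        b = gee_logistic(shuffled, "outcome", ["exposure"], "subject_id", "independence")
        assert a.coef("exposure") == pytest.approx(b.coef("exposure"), abs=1e-8)

    def test_separation_detected(self):
        df = pd.DataFrame(
            {"subject_id": range(40), "x": [0] * 20 + [1] * 20,
             "y": [0] * 20 + [1] * 20}
        )
        with pytest.raises(SeparationError):
            gee_logistic(df, "y", ["x"], "subject_id")

    def test_singular_design_rejected(self):
        df = pd.DataFrame(
            {"subject_id": range(20), "x": np.arange(20.0), "y": [0, 1] * 10}
        )
        df["x2"] = 2 * df["x"]
        with pytest.raises(np.linalg.LinAlgError):
            gee_logistic(df, "y", ["x", "x2"], "subject_id")


class TestAgreementStatistics:
    def test_kappa_perfect_and_hand_computed(self):
        v = np.array([0, 1, 1, 0, 1])
        assert cohens_kappa(v, v) == pytest.approx(1.0)
        # agreement table: 20 both+, 5 r1+/r2-, 10 r1-/r2+, 15 both-
        r1 = [1] * 25 + [0] * 25
        r2 = [1] * 20 + [0] * 5 + [1] * 10 + [0] * 15
        assert cohens_kappa(r1, r2) == pytest.approx(0.40)

    def test_kappa_of_independent_ratings_near_zero(self, rng):
        r1 = rng.binomial(1, 0.4, 20000)
        r2 = rng.binomial(1, 0.6, 20000)
        assert abs(cohens_kappa(r1, r2)) < 0.03

    def test_kappa_undefined_for_constant_raters(self):
        with pytest.raises(ValueError, match="constant"):
            cohens_kappa([1, 1, 1], [1, 1, 1])

    def test_ccc_identity_and_shift_closed_form(self, rng):
        x = rng.normal(50, 10, 500)
        assert lins_ccc(x, x) == pytest.approx(1.0)
        delta = 4.0
        v = x.var()  # population variance, matching the CCC definition
        assert lins_ccc(x, x + delta) == pytest.approx(2 * v / (2 * v + delta**2),
                                                       rel=1e-12)

    @given(hst.integers(0, 2**32 - 1))
    def test_ccc_bounded_by_pearson(self, seed):
        g = np.random.default_rng(seed)
        x = g.normal(size=10)
        y = 0.5 * x + g.normal(size=10)
        assert abs(lins_ccc(x, y)) <= abs(pearson_r(x, y)) + 1e-12

    def test_pearson_exact_cases_and_oracle(self, rng):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 3) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)
        a, b = rng.normal(size=50), rng.normal(size=50)
        brute = ((a - a.mean()) * (b - b.mean())).sum() / math.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        assert pearson_r(a, b) == pytest.approx(brute, abs=1e-12)


class TestClassicalTests:
    def test_chi_squared_hand_computed_and_scipy(self):
        stat, p = chi_squared(TwoByTwo(10, 10, 10, 10))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        stat, p = chi_squared(TwoByTwo(20, 10, 10, 20))
        assert stat == pytest.approx(20.0 / 3.0)
        ref_stat, ref_p, _, _ = sps.chi2_contingency(
            [[20, 10], [10, 20]], correction=False
        )
        assert stat == pytest.approx(ref_stat)
        assert p == pytest.approx(ref_p)

    def test_chi_squared_transpose_invariant(self):
        s1, _ = chi_squared(TwoByTwo(12, 5, 9, 30))
        s2, _ = chi_squared(TwoByTwo(12, 9, 5, 30))
        assert s1 == pytest.approx(s2)

    def test_t_test_matches_scipy(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1.3, 15)
        for welch in (False, True):
            stat, p = two_sample_t(x, y, welch=welch)
            ref = sps.ttest_ind(x, y, equal_var=not welch)
            assert stat == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
        s, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (s, p) == (pytest.approx(0.0), pytest.approx(1.0))
        s, _ = two_sample_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert abs(s) > 5

    def test_anova_hand_computed_and_identities(self, rng):
        F, p = one_way_anova([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert F == pytest.approx(13.5)
        ref = sps.f_oneway([1, 2, 3], [4, 5, 6])
        assert F == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        F0, p0 = one_way_anova([[1.0, 2.0], [1.0, 2.0]])
        assert F0 == pytest.approx(0.0)
        assert p0 == pytest.approx(1.0)
        # with two groups, F equals the square of the pooled t statistic
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        F, _ = one_way_anova([x, y])
        t, _ = two_sample_t(x, y)
        assert F == pytest.approx(t**2, rel=1e-10)

    def test_standardize(self, rng):
        np.testing.assert_allclose(standardize([1.0, 2.0, 3.0]), [-1, 0, 1])
        z = standardize(rng.normal(5, 3, 100))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            standardize([2.0, 2.0, 2.0])
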