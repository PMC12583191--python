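"""E-values, REML meta-analysis, IPW, MICE pooling, metabolite restriction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from expomix.sensitivity import (
    dehp_metabolite_restriction,
    evalue,
    mice_pool,
    random_effects_meta,
    stabilized_ipw,
)


class TestEvalue:
    def test_null_is_one(self):
        assert evalue(1.0).evalue_point == pytest.approx(1.0)

    def test_ci_crossing_null_gives_bound_one(self):
        res = evalue(1.08, ci_low=0.98, ci_high=1.19)
        assert res.evalue_ci_bound == 1.0

    def test_ci_bound_uses_limit_nearer_null(self):
        res = evalue(1.08, ci_low=1.02, ci_high=1.16)
        assert 1.0 < res.evalue_ci_bound < res.evalue_point

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            evalue(0.0)

    @settings(deadline=None, max_examples=60)
    @given(rr=st.floats(1.001, 20.0))
    def test_protective_symmetry(self, rr):
        assert evalue(1.0 / rr).evalue_point == pytest.approx(
            evalue(rr).evalue_point, rel=1e-9)

    @settings(deadline=None, max_examples=60)
    @given(a=st.floats(1.001, 10.0), b=st.floats(1.001, 10.0))
    def test_monotone_above_null(self, a, b):
        lo, hi = sorted([a, b])
        assert evalue(lo).evalue_point <= evalue(hi).evalue_point + 1e-12


class TestMeta:
    def test_identical_estimates_no_heterogeneity(self):
        y = np.full(4, np.log(1.2))
        se = np.full(4, 0.1)
        res = random_effects_meta(y, se)
        assert res.tau2 == pytest.approx(0.0, abs=1e-8)
        assert res.i2 == pytest.approx(0.0)
        assert res.pooled_rr == pytest.approx(1.2)

    def test_single_cohort_pass_through(self):
        res = random_effects_meta(np.array([np.log(1.3)]), np.array([0.2]))
        assert res.pooled_rr == pytest.approx(1.3)
        assert res.tau2 == 0.0

    def test_pooled_within_range_of_cohort_estimates(self, rng):
        y = rng.normal(0.1, 0.2, 6)
        se = rng.uniform(0.05, 0.3, 6)
        res = random_effects_meta(y, se)
        assert np.exp(y.min()) <= res.pooled_rr <= np.exp(y.max())

    def test_homogeneous_data_matches_fixed_effect(self, rng):
        v = rng.uniform(0.01, 0.04, 8)
        y = np.log(1.1) + rng.normal(0, 1, 8) * 0.0  # no heterogeneity
        res = random_effects_meta(y, np.sqrt(v))
        fe = np.sum(y / v) / np.sum(1 / v)
        assert np.log(res.pooled_rr) == pytest.approx(fe, abs=1e-8)

    def test_reml_tau2_recovery(self):
        """REML recovers a known between-cohort variance on average."""
        rng = np.random.default_rng(8)
        tau2_true, k = 0.04, 25
        v = np.full(k, 0.01)
        est = []
        for _ in range(40):
            y = rng.normal(0.1, np.sqrt(v + tau2_true))
            est.append(random_effects_meta(y, np.sqrt(v)).tau2)
        est = np.asarray(est)
        se_mean = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - tau2_true) < 3 * se_mean

    def test_i2_high_under_strong_heterogeneity(self):
        y = np.array([-0.5, 0.0, 0.5, 1.0])
        se = np.full(4, 0.05)
        res = random_effects_meta(y, se)
        assert res.i2 > 90

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            random_effects_meta(np.array([0.1, 0.2]), np.array([0.1, 0.0]))


class TestIpw:
    def test_random_inclusion_weights_near_one(self, rng):
        n = 3000
        cov = pd.DataFrame({"age": rng.normal(30, 5, n),
                            "sex": rng.choice(["m", "f"], n)})
        inc = rng.uniform(size=n) < 0.6
        w = stabilized_ipw(cov, inc)
        wi = w[inc]
        assert np.nanmean(wi) == pytest.approx(1.0, abs=0.05)
        assert wi.std() < 0.1

    def test_mean_stabilized_weight_near_one_under_selection(self, rng):
        n = 3000
        age = rng.normal(30, 5, n)
        p = 1 / (1 + np.exp(-(age - 30) / 5))
        inc = rng.uniform(size=n) < p
        w = stabilized_ipw(pd.DataFrame({"age": age}), inc)
        assert np.nanmean(w[inc]) == pytest.approx(1.0, abs=0.05)

    def test_ipw_corrects_selection_bias(self):
        """Selecting on a confounder biases the unweighted RR; weighting
        by inverse selection probability moves it back toward truth."""
        import statsmodels.api as sm
        rng = np.random.default_rng(70)
        n = 20_000
        u = rng.normal(0, 1, n)  # confounds selection and outcome
        x = rng.normal(0, 1.5, n)
        risk = 0.15 * np.exp(0.0 * x + 0.5 * u)
        y = (rng.uniform(size=n) < np.clip(risk, 0, 1)).astype(int)
        p_sel = 1 / (1 + np.exp(-(1.2 * u + 0.8 * x)))
        inc = rng.uniform(size=n) < p_sel
        w = stabilized_ipw(pd.DataFrame({"u": u, "x": x}), inc)
        X = np.column_stack([np.ones(inc.sum()), x[inc]])
        naive = sm.GLM(y[inc], X, family=sm.families.Poisson()).fit()
        wtd = sm.GLM(y[inc], X, family=sm.families.Poisson(),
                     freq_weights=w[inc]).fit()
        assert abs(wtd.params[1]) < abs(naive.params[1])

    def test_truncation_bounds_weights(self, rng):
        n = 2000
        age = rng.normal(30, 5, n)
        p = 1 / (1 + np.exp(-(age - 30)))
        inc = rng.uniform(size=n) < p
        w = stabilized_ipw(pd.DataFrame({"age": age}), inc,
                           truncate=(5.0, 95.0))
        wi = w[inc]
        w_full = stabilized_ipw(pd.DataFrame({"age": age}), inc,
                                truncate=None)
        assert wi.max() <= np.nanmax(w_full[inc]) + 1e-12
        assert len(np.unique(np.round(wi, 10))) < len(wi)


def _mice_rows(n=1200, miss_rate=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1.5, n)
    z = rng.normal(30, 5, n)
    sex = rng.choice(["m", "f"], n)
    risk = 0.15 * np.exp(0.15 * x + 0.01 * (z - 30))
    y = (rng.uniform(size=n) < np.clip(risk, 0, 1)).astype(int)
    df = pd.DataFrame({"x": x, "z": z, "sex": sex, "status": y})
    if miss_rate:
        df.loc[rng.uniform(size=n) < miss_rate, "z"] = np.nan
    return df


def _fit_logrr(tab):
    import statsmodels.api as sm
    from expomix.gee import build_design
    X = build_design(tab, ["z", "sex"], exposure_col="x")
    fit = sm.GLM(tab["status"], np.asarray(X, dtype=float),
                 family=sm.families.Poisson()).fit(cov_type="HC1")
    return float(fit.params.iloc[1]), float(fit.bse.iloc[1] ** 2)


class TestMice:
    def test_no_missing_equals_complete_fit(self):
        df = _mice_rows()
        pooled = mice_pool(df, ["z", "sex"], _fit_logrr, seed=0)
        est, var = _fit_logrr(df)
        assert pooled["log_rr"] == est
        assert pooled["between_var"] == 0.0

    def test_mcar_missingness_unbiased(self):
        df = _mice_rows(miss_rate=0.05, seed=3)
        complete_est, _ = _fit_logrr(df.dropna())
        pooled = mice_pool(df, ["z", "sex"], _fit_logrr, m=5, iterations=5,
                           seed=3)
        assert pooled["log_rr"] == pytest.approx(complete_est, abs=0.03)

    def test_rubin_variance_decomposition(self):
        df = _mice_rows(miss_rate=0.10, seed=5)
        pooled = mice_pool(df, ["z", "sex"], _fit_logrr, m=5, iterations=5,
                           seed=5)
        assert pooled["between_var"] >= 0.0
        assert pooled["se"] ** 2 >= pooled["within_var"]

    def test_all_missing_rejected(self):
        df = _mice_rows(seed=7)
        df["z"] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            mice_pool(df, ["z", "sex"], _fit_logrr, seed=1)

    def test_majority_missing_warns(self):
        df = _mice_rows(n=300, miss_rate=0.6, seed=9)
        with pytest.warns(UserWarning, match="missing"):
            mice_pool(df, ["z", "sex"], _fit_logrr, m=2, iterations=2, seed=2)


class TestDehpRestriction:
    def _frame(self, rng, zero_mehp=False):
        n = 50
        base = rng.lognormal(0, 1, n)
        df = pd.DataFrame({
            "MEHP": np.zeros(n) + 1e-12 if zero_mehp else 0.3 * base,
            "MEHHP": 1.0 * base,
            "MEOHP": 0.7 * base,
            "MECPP": 1.4 * base,
            "weight": rng.normal(70, 8, n).clip(45),
        })
        return df

    def test_full_set_equals_standard_aggregation(self, registry, rng):
        df = self._frame(rng)
        full = dehp_metabolite_restriction(
            df, registry, ["MEHP", "MEHHP", "MEOHP", "MECPP"], uv=1.6)
        again = dehp_metabolite_restriction(
            df, registry, ["MEHP", "MEHHP", "MEOHP", "MECPP"], uv=1.6)
        pd.testing.assert_series_equal(full, again)

    def test_proportional_metabolite_rescales_only(self, registry, rng):
        """When the dropped metabolite is proportional to the retained
        ones, restriction multiplies every intake by one constant — so
        log2-scale effect estimates are unchanged."""
        df = self._frame(rng)
        full = dehp_metabolite_restriction(
            df, registry, ["MEHP", "MEHHP", "MEOHP", "MECPP"], uv=1.6)
        restr = dehp_metabolite_restriction(
            df, registry, ["MEHHP", "MEOHP", "MECPP"], uv=1.6)
        ratio = (restr / full).to_numpy()
        assert np.allclose(ratio, ratio[0], rtol=1e-10)

    def test_empty_subset_rejected(self, registry, rng):
        with pytest.raises(ValueError, match="empty"):
            dehp_metabolite_restriction(self._frame(rng), registry, [], uv=1.6)
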