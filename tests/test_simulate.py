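"""Synthetic cohort generator: calibration, censoring, dependence, determinism."""

import numpy as np
import pandas as pd
import pytest

from expomix.simulate import (
    CohortSpec,
    apply_lod_censoring,
    generate_covariates_and_missingness,
    generate_exposures,
    simulate_study,
)


def _basic_spec(**kw):
    base = dict(
        cohort_id="T", n_subjects=500, period="prenatal",
        analytes=["A"], exposure_gm={"A": 3.85}, exposure_gsd={"A": 3.78},
        sampling_times=[16.0],
        outcome_baseline_risk={"asthma": 0.146},
        outcome_assessment_ages={"asthma": [2.0, 4.0]},
        seed=1,
    )
    base.update(kw)
    return CohortSpec(**base)


class TestExposures:
    def test_geometric_mean_calibration(self):
        spec = _basic_spec(n_subjects=10_000)
        rng = np.random.default_rng(5)
        s = generate_exposures(spec, rng)
        log_gm = np.log(s["concentration"]).mean()
        se = np.log(3.78) / np.sqrt(10_000)
        assert abs(log_gm - np.log(3.85)) < 3 * se

    def test_gsd_near_one_collapses_to_gm(self):
        spec = _basic_spec(exposure_gsd={"A": 1.0001})
        s = generate_exposures(spec, np.random.default_rng(0))
        assert s["concentration"].std() / s["concentration"].mean() < 1e-3
        assert s["concentration"].mean() == pytest.approx(3.85, rel=1e-3)

    def test_identity_correlation_gives_uncorrelated_logs(self):
        spec = _basic_spec(
            n_subjects=10_000,
            analytes=["A", "B"],
            exposure_gm={"A": 1.0, "B": 2.0},
            exposure_gsd={"A": 3.0, "B": 2.0},
            exposure_log_correlation=np.eye(2),
        )
        s = generate_exposures(spec, np.random.default_rng(7))
        wide = s.pivot_table(index="subject_id", columns="analyte",
                             values="concentration")
        r = np.corrcoef(np.log(wide["A"]), np.log(wide["B"]))[0, 1]
        assert abs(r) < 3 / np.sqrt(10_000) * 1.5

    def test_requested_log_correlation_achieved(self):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        spec = _basic_spec(
            n_subjects=10_000, analytes=["A", "B"],
            exposure_gm={"A": 1.0, "B": 2.0},
            exposure_gsd={"A": 3.0, "B": 2.0},
            exposure_log_correlation=R, exposure_icc=1.0,
        )
        s = generate_exposures(spec, np.random.default_rng(7))
        wide = s.pivot_table(index="subject_id", columns="analyte",
                             values="concentration")
        r = np.corrcoef(np.log(wide["A"]), np.log(wide["B"]))[0, 1]
        assert r == pytest.approx(0.6, abs=0.03)

    def test_non_psd_correlation_rejected(self):
        R = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            _basic_spec(analytes=["A", "B"],
                        exposure_gm={"A": 1.0, "B": 1.0},
                        exposure_gsd={"A": 2.0, "B": 2.0},
                        exposure_log_correlation=R)

    def test_repeated_samples_share_subject_component(self):
        spec = _basic_spec(n_subjects=3000, sampling_times=[16.0, 26.0],
                           exposure_icc=0.6)
        s = generate_exposures(spec, np.random.default_rng(3))
        wide = s.pivot_table(index="subject_id", columns="sampling_time",
                             values="concentration")
        r = np.corrcoef(np.log(wide[16.0]), np.log(wide[26.0]))[0, 1]
        assert r == pytest.approx(0.6, abs=0.05)


class TestCensoring:
    def test_zero_lod_censors_nothing(self):
        spec = _basic_spec()
        s = generate_exposures(spec, np.random.default_rng(1))
        out = apply_lod_censoring(s, {"A": 0.0})
        assert not out["censored"].any()

    def test_lod_at_median_censors_half(self):
        spec = _basic_spec(n_subjects=10_000)
        s = generate_exposures(spec, np.random.default_rng(2))
        out = apply_lod_censoring(s, {"A": 3.85})  # GM = lognormal median
        assert out["censored"].mean() == pytest.approx(0.5, abs=0.02)

    def test_detected_value_preserved_censored_masked(self):
        s = pd.DataFrame({
            "analyte": ["A", "A"], "concentration": [0.5, 0.05],
            "censored": [False, False], "lod": [0.0, 0.0],
        })
        out = apply_lod_censoring(s, {"A": 0.1})
        assert out["concentration"].iloc[0] == 0.5 and not out["censored"].iloc[0]
        assert np.isnan(out["concentration"].iloc[1]) and out["censored"].iloc[1]

    def test_censored_fraction_matches_lognormal_cdf(self):
        from scipy import stats
        spec = _basic_spec(n_subjects=10_000)
        s = generate_exposures(spec, np.random.default_rng(4))
        lod = 1.5
        expected = stats.norm.cdf(
            (np.log(lod) - np.log(3.85)) / np.log(3.78))
        out = apply_lod_censoring(s, {"A": lod})
        assert out["censored"].mean() == pytest.approx(expected, abs=0.02)


class TestOutcomes:
    def test_null_effect_prevalence_matches_baseline(self):
        spec = _basic_spec(n_subjects=8000)
        st = simulate_study(spec, seed=9)
        assert st.outcomes["status"].mean() == pytest.approx(0.146, abs=0.012)

    def test_injected_rr_recovered_by_poisson_regression(self):
        import statsmodels.api as sm
        spec = _basic_spec(n_subjects=20_000,
                           true_log2_rr={("A", "asthma"): np.log(1.5)})
        st = simulate_study(spec, seed=10)
        s = st.urine_samples
        x = np.log2(s.set_index("subject_id")["concentration"])
        tab = st.outcomes.join(x.rename("x"), on="subject_id")
        X = sm.add_constant(tab["x"])
        fit = sm.GLM(tab["status"], X, family=sm.families.Poisson()).fit()
        assert np.exp(fit.params["x"]) == pytest.approx(1.5, abs=0.05)

    def test_within_subject_outcomes_positively_correlated(self):
        spec = _basic_spec(n_subjects=8000, outcome_dependence=0.5)
        st = simulate_study(spec, seed=11)
        wide = st.outcomes.pivot_table(index="subject_id",
                                       columns="age_at_assessment",
                                       values="status")
        r = np.corrcoef(wide[2.0], wide[4.0])[0, 1]
        assert r > 0.1

    def test_no_dependence_gives_independent_repeats(self):
        spec = _basic_spec(n_subjects=8000, outcome_dependence=0.0)
        st = simulate_study(spec, seed=12)
        wide = st.outcomes.pivot_table(index="subject_id",
                                       columns="age_at_assessment",
                                       values="status")
        r = np.corrcoef(wide[2.0], wide[4.0])[0, 1]
        assert abs(r) < 0.05


class TestCovariates:
    def test_sex_frequency_calibrated(self):
        spec = _basic_spec(n_subjects=10_000)
        cov = generate_covariates_and_missingness(
            spec, np.random.default_rng(1))
        assert (cov["sex"] == "male").mean() == pytest.approx(0.509, abs=0.02)

    def test_zero_missingness_complete(self):
        spec = _basic_spec()
        cov = generate_covariates_and_missingness(
            spec, np.random.default_rng(2))
        assert not cov.isna().any().any()

    def test_masking_rate_applied(self):
        spec = _basic_spec(n_subjects=10_000,
                           missingness_rates={"maternal_age": 0.039})
        cov = generate_covariates_and_missingness(
            spec, np.random.default_rng(3))
        assert cov["maternal_age"].isna().mean() == pytest.approx(0.039,
                                                                  abs=0.008)


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        spec = _basic_spec(n_subjects=300)
        a = simulate_study(spec, seed=77)
        b = simulate_study(spec, seed=77)
        pd.testing.assert_frame_equal(a.urine_samples, b.urine_samples)
        pd.testing.assert_frame_equal(a.outcomes, b.outcomes)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)

    def test_different_seed_different_output(self):
        spec = _basic_spec(n_subjects=300)
        a = simulate_study(spec, seed=77)
        b = simulate_study(spec, seed=78)
        assert not a.urine_samples["concentration"].equals(
            b.urine_samples["concentration"])

    def test_subjects_consistent_across_tables(self):
        spec = _basic_spec(n_subjects=100)
        st = simulate_study(spec, seed=1)
        sampled = set(st.urine_samples["subject_id"])
        assert set(st.outcomes["subject_id"]) <= sampled
        assert set(st.covariates["subject_id"]) == sampled


class TestSpecValidation:
    @pytest.mark.parametrize("kw,msg", [
        ({"exposure_gsd": {"A": 0.9}}, "GSD"),
        ({"outcome_baseline_risk": {"asthma": 1.5}}, "baseline risk"),
        ({"missingness_rates": {"sex": 1.0}}, "missingness"),
        ({"period": "perinatal"}, "period"),
        ({"outcome_dependence": 1.0}, "outcome_dependence"),
    ])
    def test_invalid_specs_rejected(self, kw, msg):
        with pytest.raises(ValueError, match=msg):
            _basic_spec(**kw)
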