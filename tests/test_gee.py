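"""Exchangeable GEE, group tests and the repeated-measures power formula."""

import numpy as np
import pytest
from scipy import stats

import afwear as aw
from afwear.gee import ADJUSTMENT_COVARIATES, ModelSpec, build_design
from conftest import make_profile, make_weekly


def gls_oracle(y, X, blocks, rho):
    """Brute-force GLS with an explicit dense block covariance matrix."""
    n = len(y)
    V = np.zeros((n, n))
    for lo, hi in blocks:
        m = hi - lo
        V[lo:hi, lo:hi] = np.full((m, m), rho) + (1 - rho) * np.eye(m)
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


class TestGEEOracles:
    def test_matches_explicit_gls_on_toy_table(self, toy_gee_table):
        """Point estimate equals closed-form GLS at the fitted rho,
        computed by explicit 8x8 matrix algebra."""
        weekly, profiles = toy_gee_table
        fit = aw.fit_gee_exchangeable(weekly, profiles)
        df, cols = build_design(weekly, profiles, ModelSpec())
        X = np.column_stack([np.ones(len(df)), df[cols].to_numpy(float)])
        y = df["mean_hr_bpm"].to_numpy()
        blocks = [(0, 2), (2, 4), (4, 6), (6, 8)]
        beta_gls = gls_oracle(y, X, blocks, fit.rho_hat)
        np.testing.assert_allclose(fit.beta, beta_gls, atol=1e-8)

    def test_rho_zero_equals_ols(self, toy_gee_table):
        weekly, profiles = toy_gee_table
        fit = aw.fit_gee_exchangeable(weekly, profiles, rho_fixed=0.0)
        df, cols = build_design(weekly, profiles, ModelSpec())
        X = np.column_stack([np.ones(len(df)), df[cols].to_numpy(float)])
        beta_ols = np.linalg.lstsq(X, df["mean_hr_bpm"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-10)

    def test_one_observation_per_patient_equals_ols(self):
        weekly = [make_weekly(pid, 1, hr) for pid, hr in
                  zip("ABCDEF", [74, 71, 77, 68, 66, 70])]
        profiles = [make_profile(pid, arm) for pid, arm in
                    zip("ABCDEF", ["digoxin"] * 3 + ["beta_blocker"] * 3)]
        fit = aw.fit_gee_exchangeable(weekly, profiles)
        dig = np.mean([74, 71, 77])
        bb = np.mean([68, 66, 70])
        assert fit.coef("digoxin") == pytest.approx(dig - bb, abs=1e-10)

    def test_matches_statsmodels_gee(self):
        """Independent cross-check against the statsmodels implementation
        of the same estimator."""
        import statsmodels.api as sm
        from statsmodels.genmod.cov_struct import Exchangeable
        profiles, wk = aw.simulate_weekly_cohort(
            aw.CohortConfig(n_patients=30, n_weeks=5, treatment_effect_bpm=1.5),
            seed=13)
        spec = ModelSpec(covariates=("age_centered", "woman"))
        fit = aw.fit_gee_exchangeable(wk, profiles, spec)
        df, cols = build_design(wk, profiles, spec)
        res = sm.GEE(df["mean_hr_bpm"], sm.add_constant(df[cols]),
                     groups=df["patient_id"], family=sm.families.Gaussian(),
                     cov_struct=Exchangeable()).fit()
        np.testing.assert_allclose(fit.beta, res.params.to_numpy(), rtol=1e-6)
        np.testing.assert_allclose(fit.robust_se, res.bse.to_numpy(), rtol=1e-5)
        assert fit.rho_hat == pytest.approx(float(res.cov_struct.dep_params),
                                            rel=1e-6)


class TestGEEProperties:
    def test_week_relabeling_invariance(self, toy_gee_table):
        weekly, profiles = toy_gee_table
        fit = aw.fit_gee_exchangeable(weekly, profiles)
        relabeled = [aw.WeeklySummary(w.patient_id, 3 - w.week_index,
                                      w.mean_hr_bpm, w.total_steps,
                                      w.nonmissing_minutes, w.activity_category)
                     for w in weekly]
        fit2 = aw.fit_gee_exchangeable(relabeled, profiles)
        np.testing.assert_allclose(fit.beta, fit2.beta, atol=1e-10)

    def test_cis_contain_estimate_and_se_nonnegative(self, toy_gee_table):
        weekly, profiles = toy_gee_table
        fit = aw.fit_gee_exchangeable(weekly, profiles)
        assert np.all(fit.robust_se >= 0)
        assert np.all(fit.ci95[:, 0] <= fit.beta)
        assert np.all(fit.beta <= fit.ci95[:, 1])
        np.testing.assert_allclose(fit.ci95[:, 1] - fit.beta,
                                   1.959963984540054 * fit.robust_se)

    def test_singular_design_names_columns(self, toy_gee_table):
        weekly, profiles = toy_gee_table
        # heart_failure is constant (all False) => collinear with intercept
        with pytest.raises(ValueError, match="collinear.*heart_failure"):
            aw.fit_gee_exchangeable(weekly, profiles,
                                    ModelSpec(covariates=("heart_failure",)))

    def test_too_few_patients_per_arm_rejected(self, toy_gee_table):
        weekly, profiles = toy_gee_table
        with pytest.raises(ValueError, match="2 patients per arm"):
            aw.fit_gee_exchangeable(weekly[:4], profiles[:2])


class TestAnalysisSuite:
    def test_five_fits_and_subgroup_bookkeeping(self):
        profiles, wk = aw.simulate_weekly_cohort(
            aw.CohortConfig(n_patients=40, n_weeks=10), seed=17)
        fits = aw.run_analysis_suite(wk, profiles)
        names = [f.spec.name for f in fits]
        assert names[:3] == ["unadjusted", "adjusted", "activity_adjusted"]
        assert all(n.startswith("subgroup:") for n in names[3:])
        for f in fits[3:]:
            cat = f.spec.subgroup
            expect = (wk["activity_category"] == cat).sum()
            assert f.n_weeks_total == expect

    def test_subgroup_threshold_bookkeeping_toy(self):
        wk = [make_weekly("A", 1, 70, steps=10_000),
              make_weekly("B", 1, 71, steps=20_000),
              make_weekly("C", 1, 72, steps=35_000)]
        cats = [w.activity_category for w in wk]
        assert cats == ["low", "minimum_recommended", "recommended"]

    def test_adjusted_close_to_unadjusted_when_covariates_independent(self):
        """Covariates independent of arm and outcome leave the arm
        coefficient essentially unchanged at large n."""
        profiles, wk = aw.simulate_weekly_cohort(
            aw.CohortConfig(n_patients=400, n_weeks=6, treatment_effect_bpm=2.0),
            seed=19)
        f0 = aw.fit_gee_exchangeable(wk, profiles)
        f1 = aw.fit_gee_exchangeable(wk, profiles,
                                     ModelSpec(covariates=ADJUSTMENT_COVARIATES))
        assert abs(f0.coef("digoxin") - f1.coef("digoxin")) < 0.35


class TestGroupDifference:
    def test_identical_samples_kw(self):
        stat, p = aw.group_difference_test([1, 2, 3], [1, 2, 3], normal=False)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_kw_matches_rank_formula(self):
        """x=(1,2,3), y=(4,5,6): H = 12/(6*7) * (6*2^2 + 5^2*... ) = 3.857."""
        stat, _ = aw.group_difference_test([1, 2, 3], [4, 5, 6], normal=False)
        # brute force: ranks 1..6, R1=6, R2=15
        H = 12 / (6 * 7) * (6**2 / 3 + 15**2 / 3) - 3 * 7
        assert stat == pytest.approx(H, abs=1e-3)
        assert stat == pytest.approx(3.857, abs=1e-3)

    def test_t_test_type_i_error(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            aw.group_difference_test(rng.normal(size=20), rng.normal(size=20),
                                     normal=True)[1] < 0.05
            for _ in range(1000))
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            aw.group_difference_test([1, 1], [1, 1], normal=False)


class TestPower:
    def test_reduces_to_classical_formula(self):
        """rho=0, m=1: n = 2 (z_{0.975} + z_{0.9})^2 sd^2 / delta^2."""
        n = aw.power_repeated_measures(2.0, 6.0, 0.0, 1, alpha=0.05, power=0.9)
        z = stats.norm.ppf(0.975) + stats.norm.ppf(0.9)
        assert n == int(np.ceil(2 * z**2 * 36 / 4))

    def test_quadrupling_with_halved_delta(self):
        n1 = aw.power_repeated_measures(2.0, 6.0, 0.5, 10)
        n2 = aw.power_repeated_measures(4.0, 6.0, 0.5, 10)
        assert n1 / n2 == pytest.approx(4.0, rel=0.1)

    def test_analytic_agrees_with_simulation(self):
        """At the analytic n, simulated power is within 0.03 of nominal."""
        n = aw.power_repeated_measures(2.0, 6.0, 0.91, 20, alpha=0.05, power=0.9)
        sim = aw.simulate_power(2.0, 6.0, 0.91, 20, n_per_arm=n, n_sims=2000, seed=1)
        assert abs(sim - 0.9) < 0.03

    def test_trial_parameters_demand_more_than_forty(self):
        """The stated design effect (1 + 19*0.91) makes the standard formula
        ask for far more than 40 per arm at delta 2, sd 6."""
        assert aw.power_repeated_measures(2.0, 6.0, 0.91, 20) > 100

    def test_zero_delta_rejected(self):
        with pytest.raises(ValueError):
            aw.power_repeated_measures(0.0, 6.0, 0.5, 10)
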