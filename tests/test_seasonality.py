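"""Fourier seasonal regression: design, LRT, amplitude/phase, bootstrap."""

import datetime

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seasontl.seasonality import (
    DesignError,
    GRID_DAYS,
    RankDeficiencyError,
    amplitude_closed_form,
    bootstrap_amplitude_ci,
    build_design,
    circular_day_difference,
    conception_angle,
    conception_angles,
    covariate_effect_models,
    fit_gaussian_lm,
    fit_seasonal_model,
    fourier_basis,
    likelihood_ratio_test,
    seasonal_lrt,
    seasonal_summary,
    select_harmonics,
)


def records_from_days(days, y, year=2015, **extra) -> pd.DataFrame:
    """Phenotype table with conception dates at given days-of-year."""
    base = datetime.date(year, 1, 1)
    dates = [base + datetime.timedelta(days=int(d) - 1) for d in days]
    df = pd.DataFrame({"conception_date": pd.to_datetime(dates), "ltl_z": y})
    for k, v in extra.items():
        df[k] = v
    return df


def dense_year(n=365, year=2015):
    days = np.arange(1, n + 1)
    theta = 2 * np.pi * (days - 1) / 365.0
    return days, theta


class TestAngles:
    def test_january_first_is_zero(self):
        assert conception_angle(datetime.date(2015, 1, 1)) == 0.0

    def test_mid_year_matches_formula(self):
        # 2 July 2015 is day 183 of a 365-day year
        got = conception_angle(datetime.date(2015, 7, 2))
        assert got == pytest.approx(2 * np.pi * 182 / 365, rel=1e-12)
        assert got == pytest.approx(3.1330, abs=5e-4)

    def test_december_31_strictly_below_two_pi(self):
        for year in (2015, 2016):  # plain and leap year
            assert conception_angle(datetime.date(year, 12, 31)) < 2 * np.pi

    def test_leap_year_denominator(self):
        got = conception_angle(datetime.date(2016, 12, 31))
        assert got == pytest.approx(2 * np.pi * 365 / 366, rel=1e-12)

    def test_fixed_convention(self):
        got = conception_angle(datetime.date(2015, 7, 2), convention="fixed_365_25")
        assert got == pytest.approx(2 * np.pi * 182 / 365.25, rel=1e-12)

    def test_invalid_date_rejected(self):
        with pytest.raises(DesignError):
            conception_angles(["not-a-date"])


class TestDesign:
    def test_crude_design_shape(self, rng):
        df = records_from_days(rng.integers(1, 366, 10), rng.normal(size=10))
        d = build_design(df, k=1)
        assert d.X.shape == (10, 3)
        assert d.columns == ["const", "sin1", "cos1"]

    def test_covariate_design_shape(self, rng):
        n = 20
        df = records_from_days(
            rng.integers(1, 366, n),
            rng.normal(size=n),
            age=rng.normal(9, 0.2, n),
            sex=rng.choice(["male", "female"], n),
        )
        d = build_design(df, k=1, covariates=["age", "sex"])
        assert d.X.shape == (n, 5)  # const + sin + cos + age + sex[male]
        assert "sex[male]" in d.columns  # reference = 'female' (alphabetical)

    def test_missing_covariates_drop_rows(self, rng):
        n = 50
        bmi = rng.normal(20, 2, n)
        bmi[:10] = np.nan
        df = records_from_days(rng.integers(1, 366, n), rng.normal(size=n), maternal_bmi=bmi)
        d = build_design(df, k=1, covariates=["maternal_bmi"])
        assert d.X.shape[0] == 40
        assert d.n_dropped == 10

    def test_unknown_covariate(self, rng):
        df = records_from_days([1, 2, 3], [0.0, 1.0, 2.0])
        with pytest.raises(DesignError, match="shoe_size"):
            build_design(df, k=1, covariates=["shoe_size"])


class TestGaussianLm:
    def test_intercept_only(self, rng):
        y = rng.normal(2.0, 1.0, 40)
        fit = fit_gaussian_lm(y, np.ones((40, 1)), ["const"])
        assert fit.coefficients[0] == pytest.approx(y.mean(), rel=1e-12)
        assert fit.sigma2_mle == pytest.approx(np.var(y), rel=1e-12)
        expected_ll = -(40 / 2) * (np.log(2 * np.pi * fit.sigma2_mle) + 1)
        assert fit.loglik == pytest.approx(expected_ll, rel=1e-12)

    def test_exact_fit_flagged_degenerate(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = 2.0 + 3.0 * np.arange(10.0)
        fit = fit_gaussian_lm(y, X)
        assert fit.degenerate and fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations_oracle(self, rng):
        X = np.column_stack([np.ones(60), rng.normal(size=(60, 3))])
        y = rng.normal(size=60)
        fit = fit_gaussian_lm(y, X)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.coefficients, beta, atol=1e-9)

    def test_collinear_columns_named(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([np.ones(30), x, 2 * x])
        with pytest.raises(RankDeficiencyError, match="collinear"):
            fit_gaussian_lm(rng.normal(size=30), X, ["const", "x", "x2"])

    def test_needs_more_rows_than_columns(self, rng):
        with pytest.raises(DesignError):
            fit_gaussian_lm(np.zeros(3), np.eye(3))


class TestLrt:
    def test_identical_models(self, rng):
        y = rng.normal(size=30)
        X = np.ones((30, 1))
        fit = fit_gaussian_lm(y, X)
        res = likelihood_ratio_test(fit, fit)
        assert res.chi2 == 0.0 and res.p_value == 1.0

    def test_one_fourier_pair_has_two_df(self, rng):
        df = records_from_days(rng.integers(1, 366, 50), rng.normal(size=50))
        _, _, lrt = seasonal_lrt(df, k=1)
        assert lrt.df == 2

    def test_sample_mismatch_rejected(self, rng):
        y = rng.normal(size=30)
        f1 = fit_gaussian_lm(y, np.ones((30, 1)))
        f2 = fit_gaussian_lm(y[:20], np.ones((20, 1)))
        with pytest.raises(DesignError, match="identical samples"):
            likelihood_ratio_test(f1, f2)

    def test_chi2_invariant_to_affine_outcome_rescaling(self, rng):
        df = records_from_days(rng.integers(1, 366, 120), rng.normal(size=120))
        _, _, lrt1 = seasonal_lrt(df, k=1)
        df2 = df.assign(ltl_z=3.0 * df["ltl_z"] - 2.0)
        _, _, lrt2 = seasonal_lrt(df2, k=1)
        assert lrt1.chi2 == pytest.approx(lrt2.chi2, abs=1e-8)


class TestHarmonicSelection:
    def test_pure_single_harmonic_selects_one_pair(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            days = rng.integers(1, 366, 250)
            theta = 2 * np.pi * (days - 1) / 365
            y = 1.0 * np.sin(theta) + rng.normal(0, 0.5, 250)
            sel = select_harmonics(records_from_days(days, y))
            hits += sel.k == 1
        # adding a spurious pair is rejected at alpha = 0.05, so ~95% of
        # runs select k = 1; 0.90 is a 3-sigma-safe lower bound
        assert hits / reps >= 0.90

    def test_no_signal_still_reports_minimal_basis(self, rng):
        days = rng.integers(1, 366, 200)
        sel = select_harmonics(records_from_days(days, rng.normal(size=200)))
        assert sel.k == 1
        assert sel.tests[0][:2] == (0, 1)  # baseline-vs-k=1 trail recorded

    def test_two_strong_harmonics_select_two_pairs(self, rng):
        days = rng.integers(1, 366, 400)
        theta = 2 * np.pi * (days - 1) / 365
        y = np.sin(theta) + 0.8 * np.cos(2 * theta) + rng.normal(0, 0.3, 400)
        sel = select_harmonics(records_from_days(days, y))
        assert sel.k == 2


class TestSeasonalSummary:
    def test_known_sine_amplitude_and_peak(self):
        days, theta = dense_year()
        y = 0.3 * np.sin(theta)
        model = fit_seasonal_model(records_from_days(days, y), k=1)
        summ = seasonal_summary(model)
        bound = 0.6 * (1 - np.cos(np.pi / GRID_DAYS))
        assert summ.amplitude == pytest.approx(0.6, abs=bound + 1e-9)
        # sin peaks at quarter year
        assert abs(summ.peak_day - (GRID_DAYS / 4 + 1)) <= 1.0

    def test_flat_curve_for_constant_outcome(self):
        days, _ = dense_year()
        model = fit_seasonal_model(records_from_days(days, np.full(365, 1.3)), k=1)
        summ = seasonal_summary(model)
        assert summ.amplitude < 1e-10

    def test_grid_agrees_with_closed_form(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=2)
            days, theta = dense_year()
            model = fit_seasonal_model(records_from_days(days, a * np.sin(theta) + b * np.cos(theta)), k=1)
            summ = seasonal_summary(model)
            amp_cf, peak_cf = amplitude_closed_form(a, b)
            bound = amp_cf * (1 - np.cos(np.pi / GRID_DAYS))
            assert abs(summ.amplitude - amp_cf) <= bound + 1e-9
            assert abs(circular_day_difference(summ.peak_day, peak_cf)) <= 1.0

    def test_phase_equivariance_under_date_shift(self, rng):
        shift = 40
        days = rng.integers(1, 366, 200)
        theta = 2 * np.pi * (days - 1) / 365
        resid = rng.normal(0, 0.5, 200)  # fixed residuals, independent of date
        y = 0.4 * np.sin(theta) + 0.2 * np.cos(theta) + resid
        df1 = records_from_days(days, y)
        df2 = records_from_days((days - 1 + shift) % 365 + 1, y)
        m1, _, l1 = seasonal_lrt(df1, k=1)
        m2, _, l2 = seasonal_lrt(df2, k=1)
        s1, s2 = seasonal_summary(m1), seasonal_summary(m2)
        assert l1.chi2 == pytest.approx(l2.chi2, abs=1e-8)
        # rotation moves the true peak between grid points, so amplitudes
        # agree only up to twice the grid discretization bound
        bound = 2 * s1.amplitude * (1 - np.cos(np.pi / GRID_DAYS))
        assert s1.amplitude == pytest.approx(s2.amplitude, abs=bound)
        expected_shift = shift * GRID_DAYS / 365.0
        got = circular_day_difference(s2.peak_day, s1.peak_day)
        assert abs(got - expected_shift) <= 1.5

    def test_covariate_centering_changes_intercept_only(self, rng):
        n = 150
        days = rng.integers(1, 366, n)
        df = records_from_days(days, rng.normal(size=n), age=rng.normal(9, 0.3, n))
        m1 = fit_seasonal_model(df, k=1, covariates=["age"])
        m2 = fit_seasonal_model(df.assign(age=df["age"] + 10.0), k=1, covariates=["age"])
        assert np.allclose(m1.fit.coefficients[1:], m2.fit.coefficients[1:], atol=1e-8)
        assert seasonal_summary(m1).amplitude == pytest.approx(
            seasonal_summary(m2).amplitude, abs=1e-8
        )


class TestBootstrap:
    def test_same_seed_identical(self, rng):
        days = rng.integers(1, 366, 120)
        theta = 2 * np.pi * (days - 1) / 365
        y = 0.3 * np.sin(theta) + rng.normal(0, 1, 120)
        df = records_from_days(days, y)
        r1 = bootstrap_amplitude_ci(df, B=150, seed=5)
        r2 = bootstrap_amplitude_ci(df, B=150, seed=5)
        assert r1.amplitude_ci == r2.amplitude_ci
        assert r1.peak_day_ci == r2.peak_day_ci

    def test_noiseless_data_degenerate_interval(self):
        days, theta = dense_year()
        df = records_from_days(days, 0.3 * np.sin(theta) + 0.1 * np.cos(theta))
        r = bootstrap_amplitude_ci(df, B=100, seed=1)
        assert r.amplitude_ci[1] - r.amplitude_ci[0] < 1e-8
        assert r.amplitude_ci[0] == pytest.approx(r.amplitude, abs=1e-8)

    def test_minimum_replicates_enforced(self, rng):
        df = records_from_days(rng.integers(1, 366, 50), rng.normal(size=50))
        with pytest.raises(DesignError):
            bootstrap_amplitude_ci(df, B=50)


class TestCovariateEffects:
    def test_effect_recovery(self):
        from seasontl.synthetic import emphasis_like, generate_cohort

        cfg = emphasis_like(seed=42, n=3000, covariate_effects={"birthweight": 0.2})
        cohort, _ = generate_cohort(cfg)
        table = covariate_effect_models(cohort, ["birthweight"])
        row = table[table["term"] == "birthweight"].iloc[0]
        beta_per_sd = row["beta"] * cohort["birthweight"].std(ddof=1)
        assert beta_per_sd == pytest.approx(0.2, abs=0.07)
        assert row["fourier_pairs"] == 1  # birthweight is seasonally adjusted

    def test_constant_predictor_rejected(self, rng):
        df = records_from_days(
            rng.integers(1, 366, 30), rng.normal(size=30),
            age=rng.normal(9, 0.2, 30), sex=rng.choice(["male", "female"], 30),
            flat=np.ones(30),
        )
        with pytest.raises(DesignError, match="constant"):
            covariate_effect_models(df, ["flat"])

    def test_predictor_collinear_with_fourier_term(self, rng):
        n = 80
        days = rng.integers(1, 366, n)
        theta = conception_angles(records_from_days(days, np.zeros(n))["conception_date"])
        df = records_from_days(
            days, rng.normal(size=n),
            age=rng.normal(9, 0.2, n), sex=rng.choice(["male", "female"], n),
            maternal_bmi=np.sin(theta),
        )
        with pytest.raises(RankDeficiencyError):
            covariate_effect_models(df, ["maternal_bmi"])

    def test_null_predictor_p_values_are_calibrated(self, rng):
        # no true effect: Wald p for birthweight should be ~ Uniform(0,1)
        from seasontl.synthetic import emphasis_like, generate_cohort

        pvals = []
        for i in range(200):
            cfg = emphasis_like(seed=1000 + i, n=120, true_amplitude=0.0)
            cohort, _ = generate_cohort(cfg)
            t = covariate_effect_models(cohort, ["birthweight"])
            pvals.append(t[t["term"] == "birthweight"]["p_value"].iloc[0])
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert 0.01 <= rate <= 0.10  # ~5% with 200-rep Monte Carlo slack
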