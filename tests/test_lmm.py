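"""Mixed-model estimation: exact recoveries, invariances, cross-checks
against statsmodels, cAIC degeneracies, and the incidence generator."""

import math

import numpy as np
import pandas as pd
import pytest

from hipimpinge.lmm import (
    IncidenceGenerator,
    ModelSpec,
    _conditional_fit,
    _ols_fit,
    build_design,
    compare_models,
    fit_mixed,
    fit_random_intercept,
    simulate_incidence,
)


def _gen(**kw):
    return IncidenceGenerator(**kw)


class TestExactRecovery:
    def test_noiseless_data_recovers_slope_exactly(self):
        """Zero random-intercept and residual SDs: the tilt coefficient is
        recovered to numerical precision."""
        df = simulate_incidence(_gen(random_intercept_sd=0.0, residual_sd=0.0, seed=1))
        fit = fit_mixed(df)
        j = fit.terms.index("tilt_deg")
        assert abs(fit.beta[j] - (-0.8)) < 1e-8
        assert fit.var_residual < 1e-12 or fit.boundary

    def test_constant_response(self):
        df = simulate_incidence(_gen(seed=2))
        df["incidence_pct"] = 42.0
        fit = fit_mixed(df)
        assert abs(fit.beta[fit.terms.index("intercept")] - 42.0) < 1e-8
        assert np.abs(fit.beta[1:]).max() < 1e-8

    def test_deterministic_arithmetic_without_noise(self):
        """All SDs zero and a single AIIS level: responses are exactly
        intercept + slope * tilt."""
        gen = IncidenceGenerator(
            n_patients=3, random_intercept_sd=0.0, residual_sd=0.0,
            distributions={"femoral_version": (14.19, 0.0),
                           "acetabular_version": (18.63, 0.0),
                           "lcea": (30.77, 0.0)},
            aiis_probs={"II": 1.0}, seed=0,
        )
        df = simulate_incidence(gen)
        at = lambda t: df.loc[df.tilt_deg == t, "incidence_pct"].unique()
        assert at(10.0) == pytest.approx([25.5])
        assert at(-10.0) == pytest.approx([41.5])
        assert at(0.0) == pytest.approx([33.5])


class TestInvariances:
    def test_reml_shift_invariance(self):
        df = simulate_incidence(_gen(seed=5))
        f0 = fit_mixed(df)
        df2 = df.copy()
        df2["incidence_pct"] = df2["incidence_pct"] + 100.0
        f1 = fit_mixed(df2)
        assert abs(f1.beta[0] - f0.beta[0] - 100.0) < 1e-6
        assert np.abs(f1.beta[1:] - f0.beta[1:]).max() < 1e-8
        assert abs(f1.var_intercept - f0.var_intercept) < 1e-6
        assert abs(f1.var_residual - f0.var_residual) < 1e-6

    def test_singular_design_names_column(self):
        df = simulate_incidence(_gen(seed=6))
        df["lcea"] = 30.77
        with pytest.raises(ValueError, match="lcea"):
            fit_mixed(df)

    def test_too_few_groups_rejected(self):
        df = simulate_incidence(_gen(n_patients=1, seed=0))
        with pytest.raises(ValueError):
            fit_mixed(df, ModelSpec(fixed=("tilt_deg",)))


class TestStatsmodelsAgreement:
    def test_estimates_match_mixedlm(self):
        """Fixed effects, SEs and variance components agree with
        statsmodels MixedLM (REML) within 1e-4 relative."""
        import statsmodels.api as sm

        df = simulate_incidence(_gen(seed=42))
        fit = fit_mixed(df)
        d = df[df.region == "A"]
        X, _ = build_design(d, ModelSpec())
        ref = sm.MixedLM(d["incidence_pct"].to_numpy(), X,
                         groups=d["patient_id"].to_numpy()).fit(reml=True, method="lbfgs")
        assert np.abs((fit.beta - np.asarray(ref.fe_params)) / fit.beta).max() < 1e-4
        assert np.abs((fit.se - np.asarray(ref.bse_fe)) / fit.se).max() < 1e-4
        assert abs(fit.var_residual - ref.scale) / ref.scale < 1e-3
        assert abs(fit.var_intercept - float(np.asarray(ref.cov_re)[0, 0])) \
            / fit.var_intercept < 1e-3


class TestCAIC:
    def test_vanishing_intercept_variance_gives_marginal_aic(self):
        """As the random-intercept variance -> 0, rho -> rank(X) and cAIC
        converges to the fixed-effects AIC (difference < 0.01)."""
        df = simulate_incidence(_gen(n_patients=25, random_intercept_sd=0.0,
                                     residual_sd=8.0, seed=9))
        d = df[df.region == "A"]
        X, terms = build_design(d, ModelSpec(fixed=("tilt_deg", "femoral_version")))
        y = d["incidence_pct"].to_numpy(float)
        groups = d["patient_id"].to_numpy()
        codes = pd.factorize(groups)[0]
        sizes = np.bincount(codes).astype(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = float(((y - X @ beta) ** 2).sum()) / (len(y) - X.shape[1])
        theta_tiny = 1e-10 / sigma2
        rho, caic_val, _ = _conditional_fit(theta_tiny, beta, sigma2, X, y,
                                            codes, sizes, X.shape[1])
        assert abs(rho - X.shape[1]) < 1e-6
        ols = _ols_fit(X, y, terms)
        # compare penalties at the same sigma^2 convention
        n = len(y)
        cond_ll = -0.5 * (n * math.log(2 * math.pi * sigma2)
                          + float(((y - X @ beta) ** 2).sum()) / sigma2)
        assert abs(caic_val - (-2 * cond_ll + 2 * (X.shape[1] + 1))) < 0.01
        assert ols["caic"] == pytest.approx(ols["deviance"] + 2 * (X.shape[1] + 1))

    def test_pure_intercept_model_rho_approaches_group_count(self):
        """With huge intercept variance and tiny residual variance each
        patient is one effective parameter: rho -> k."""
        k, n_i = 12, 3
        rng = np.random.default_rng(0)
        y = np.repeat(rng.normal(0, 30, k), n_i) + rng.normal(0, 0.01, k * n_i)
        X = np.ones((k * n_i, 1))
        codes = np.repeat(np.arange(k), n_i)
        sizes = np.full(k, float(n_i))
        theta = 30.0**2 / 0.01**2
        rho, _, _ = _conditional_fit(theta, np.array([y.mean()]), 0.01**2, X, y,
                                     codes, sizes, 1)
        assert abs(rho - k) < 0.01

    def test_irrelevant_covariate_does_not_lower_caic(self):
        """Adding a null covariate increases cAIC in the median across
        simulations (penalty beats fit)."""
        deltas = []
        rng = np.random.default_rng(7)
        for _ in range(30):
            df = simulate_incidence(_gen(n_patients=30, beta_lcea=0.0,
                                         seed=int(rng.integers(2**31))))
            small = fit_mixed(df, ModelSpec(fixed=("tilt_deg", "femoral_version")))
            big = fit_mixed(df, ModelSpec(fixed=("tilt_deg", "femoral_version", "lcea")))
            deltas.append(big.caic - small.caic)
        assert np.median(deltas) >= 0.0


class TestModelComparison:
    def test_report_structure(self):
        df = simulate_incidence(_gen(seed=3))
        rep = compare_models(df)
        assert list(rep["model"]) == [
            "univariate mixed: AIIS type", "univariate mixed: femoral version",
            "univariate mixed: posterior pelvic tilt", "univariate mixed: LCEA",
            "multivariate regression", "multivariate mixed",
        ]
        assert rep["best_caic"].sum() == 1

    def test_sparse_truth_favors_univariate(self):
        """No intercept variance and only a tilt effect: the univariate
        tilt model usually beats the multivariate mixed model on cAIC."""
        wins = 0
        rng = np.random.default_rng(11)
        n_rep = 20
        for _ in range(n_rep):
            df = simulate_incidence(_gen(
                n_patients=40, random_intercept_sd=0.0, beta_aiis_I=0.0,
                beta_fv=0.0, beta_av=0.0, beta_lcea=0.0,
                seed=int(rng.integers(2**31))))
            rep = compare_models(df).set_index("model")
            wins += (rep.loc["univariate mixed: posterior pelvic tilt", "caic"]
                     < rep.loc["multivariate mixed", "caic"])
        assert wins > n_rep / 2


class TestGenerator:
    def test_deterministic(self):
        a = simulate_incidence(_gen(seed=13))
        b = simulate_incidence(_gen(seed=13))
        pd.testing.assert_frame_equal(a, b)

    def test_large_sample_means_match_generative_means(self):
        """Per-tilt empirical means agree with the generative expectation
        within 3 standard errors (n = 10,000 patients)."""
        gen = _gen(n_patients=10_000, seed=21)
        df = simulate_incidence(gen)
        total_sd = math.sqrt(
            gen.random_intercept_sd**2 + gen.residual_sd**2
            + (gen.beta_fv * gen.distributions["femoral_version"][1]) ** 2
            + (gen.beta_av * gen.distributions["acetabular_version"][1]) ** 2
            + (gen.beta_lcea * gen.distributions["lcea"][1]) ** 2
            + gen.beta_aiis_I**2 * 0.25,
        )
        for tilt in gen.tilts:
            emp = df.loc[df.tilt_deg == tilt, "incidence_pct"].mean()
            expected = gen.mean_at_neutral + gen.beta_tilt * tilt
            assert abs(emp - expected) < 3 * total_sd / math.sqrt(gen.n_patients)

    def test_clip_mode_logs_truncation_fraction(self):
        df = simulate_incidence(_gen(truncation="clip", seed=4))
        assert "truncation_fraction" in df.attrs
        assert 0.0 <= df.attrs["truncation_fraction"] < 0.2
        assert df["incidence_pct"].between(0.0, 100.0).all()

    def test_lattice_mode_snaps_to_grid(self):
        df = simulate_incidence(_gen(truncation="lattice", seed=4))
        steps = df["incidence_pct"] / (100.0 / 12.0)
        assert np.abs(steps - steps.round()).max() < 1e-9

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            IncidenceGenerator(residual_sd=-1.0)
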