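"""FIML engine, model zoo, fit indices and close-fit power."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from driftsem.sem import (
    FREE,
    ModelSpec,
    StructuralModel,
    build_model,
    compare_aic,
    fit_fiml,
    fit_indices,
    min_n_close_fit,
    power_close_fit,
    rmsea_from_chi2,
)
from driftsem.sem.engine import IdentificationError, independence_loglik, saturated_loglik


def one_factor_spec(cols, name="1f"):
    return ModelSpec(
        name=name, observed=list(cols), latents=["f"],
        loadings={(c, "f"): (1.0 if i == 0 else FREE) for i, c in enumerate(cols)},
        latent_cov={("f", "f"): FREE},
    )


def simulate_one_factor(n, loadings, noise_sd, seed):
    gen = np.random.default_rng(seed)
    eta = gen.standard_normal(n)
    lam = np.asarray(loadings)
    X = np.outer(eta, lam) + gen.standard_normal((n, lam.size)) * noise_sd
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(lam.size)])


class TestDfBookkeeping:
    """The ladder's degrees of freedom, derived from each spec's moment
    and free-parameter counts."""

    @pytest.mark.parametrize(
        "name, options, df",
        [
            ("three_factor", {}, 24),
            ("three_factor", {"equal_inhibition_loadings": True}, 26),
            ("three_factor_higher_order", {}, 24),
            ("three_factor_higher_order", {"zero_first_order_residuals": True}, 27),
            ("one_factor", {}, 27),
            ("one_factor_plus_criteria", {}, 115),
            ("speed_regression", {}, 53),
            ("speed_regression", {"zero_ef_residual": True}, 54),
            ("speed_regression_plus_criteria", {"zero_ef_residual": True}, 166),
        ],
    )
    def test_ladder_df(self, name, options, df):
        assert build_model(name, **options).df == df

    def test_unknown_model_and_bad_counts(self):
        with pytest.raises(ValueError):
            build_model("two_factor")
        vm = {"inhibition": ["a", "b"], "updating": ["c", "d", "e"], "shifting": ["f", "g", "h"]}
        with pytest.raises(ValueError):
            build_model("three_factor", variable_map=vm)

    def test_spec_json_roundtrip(self):
        spec = build_model("speed_regression", zero_ef_residual=True)
        back = ModelSpec.from_json(spec.to_json())
        assert back.df == spec.df
        assert back.free_parameters() == spec.free_parameters()

    def test_negative_df_rejected(self):
        cols = ["a", "b"]
        spec = ModelSpec(
            name="over", observed=cols, latents=["f", "g"],
            loadings={("a", "f"): FREE, ("b", "f"): FREE, ("a", "g"): FREE, ("b", "g"): FREE},
            latent_cov={("f", "f"): FREE, ("g", "g"): FREE, ("f", "g"): FREE},
        )
        with pytest.raises(IdentificationError):
            StructuralModel(pd.DataFrame(np.random.randn(30, 2), columns=cols), spec)


class TestFimlLikelihood:
    def test_fiml_equals_casewise_normal_loglik(self):
        # oracle: sum of scipy multivariate-normal logpdfs over rows,
        # each restricted to its observed entries
        df = simulate_one_factor(80, [1.0, 0.9, 0.8, 1.1], 0.6, seed=0)
        df.iloc[::7, 1] = np.nan
        df.iloc[3::11, 3] = np.nan
        spec = one_factor_spec(df.columns)
        model = StructuralModel(df, spec)
        theta, mu0 = model._start_values()
        sigma = model.implied_sigma(theta)
        ours = model.loglik(theta, mu0)
        brute = 0.0
        X = df.to_numpy()
        for row in X:
            obs = ~np.isnan(row)
            brute += multivariate_normal.logpdf(
                row[obs], mean=mu0[obs], cov=sigma[np.ix_(obs, obs)]
            )
        assert ours == pytest.approx(brute, rel=1e-10)

    def test_complete_data_chi2_matches_wishart_form(self):
        # with no missingness the FIML chi-square equals the classic
        # N*(log|Sigma| + tr(S Sigma^-1) - log|S| - p) discrepancy
        df = simulate_one_factor(300, [1.0, 0.9, 0.8, 1.1, 0.7], 0.6, seed=1)
        res = fit_fiml(df, one_factor_spec(df.columns))
        X = df.to_numpy()
        S = np.cov(X.T, bias=True)
        theta = res.params.to_numpy()
        sigma = res.model.implied_sigma(theta)
        p = X.shape[1]
        f_ml = (
            np.log(np.linalg.det(sigma))
            + np.trace(np.linalg.solve(sigma, S))
            - np.log(np.linalg.det(S))
            - p
        )
        assert res.chi2 == pytest.approx(X.shape[0] * f_ml, rel=1e-4)

    def test_saturated_spec_chi2_zero(self):
        df = simulate_one_factor(120, [1.0, 0.8, 0.9], 0.5, seed=2)
        cols = list(df.columns)
        sat = ModelSpec(
            name="sat", observed=cols, latents=[f"f{i}" for i in range(3)],
            loadings={(c, f"f{i}"): 1.0 for i, c in enumerate(cols)},
            latent_cov={
                (f"f{i}", f"f{j}"): FREE for i in range(3) for j in range(i, 3)
            },
            residual_cov={(c, c): 0.0 for c in cols},
        )
        res = fit_fiml(df, sat)
        assert res.df == 0
        assert res.chi2 == pytest.approx(0.0, abs=1e-4)

    def test_em_saturated_matches_complete_when_no_missing(self):
        df = simulate_one_factor(100, [1.0, 0.9], 0.5, seed=3)
        ll, mu, sigma = saturated_loglik(df.to_numpy())
        np.testing.assert_allclose(mu, df.mean().to_numpy(), rtol=1e-8)
        np.testing.assert_allclose(sigma, np.cov(df.to_numpy().T, bias=True), rtol=1e-8)

    def test_independence_loglik_factorises(self):
        df = simulate_one_factor(60, [1.0, 0.7], 0.4, seed=4)
        df.iloc[:5, 0] = np.nan
        ll, k = independence_loglik(df.to_numpy())
        brute = 0.0
        for j in range(2):
            col = df.iloc[:, j].dropna().to_numpy()
            var = col.var()
            brute += np.sum(-0.5 * (np.log(2 * np.pi * var) + (col - col.mean()) ** 2 / var))
        assert ll == pytest.approx(brute, rel=1e-10)
        assert k == 4


class TestRecoveryAndInference:
    def test_loading_recovery_with_missing_data(self):
        df = simulate_one_factor(400, [1.0, 0.9, 0.8, 1.1, 0.7, 0.85], 0.6, seed=5)
        gen = np.random.default_rng(6)
        mask = gen.random(df.shape) < 0.1
        df = df.mask(mask)
        res = fit_fiml(df, one_factor_spec(df.columns))
        truth = {"lambda:x1~f": 0.9, "lambda:x2~f": 0.8, "lambda:x3~f": 1.1,
                 "lambda:x4~f": 0.7, "lambda:x5~f": 0.85}
        for name, val in truth.items():
            assert res.params[name] == pytest.approx(val, abs=0.12)
        assert res.converged

    def test_critical_ratio_examples(self):
        df = simulate_one_factor(200, [1.0, 0.9, 0.8], 0.6, seed=7)
        res = fit_fiml(df, one_factor_spec(df.columns))
        # synthetic checks of the z formula on the result object
        res.params["lambda:x1~f"] = 0.0
        z, p = res.critical_ratio("lambda:x1~f")
        assert p == pytest.approx(1.0)
        res.params["lambda:x1~f"] = 1.959964 * res.se["lambda:x1~f"]
        z, p = res.critical_ratio("lambda:x1~f")
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_heywood_case_reported_not_crashed(self):
        # tiny sample, weak indicator: negative residual variances happen
        gen = np.random.default_rng(8)
        df = pd.DataFrame(gen.standard_normal((30, 3)), columns=["a", "b", "c"])
        df["b"] = df["a"] * 0.99 + 0.05 * gen.standard_normal(30)
        res = fit_fiml(df, one_factor_spec(["a", "b", "c"]))
        assert isinstance(res.warnings, list)  # completes with statuses

    def test_model_equivalence_one_factor_vs_zero_residual_higher_order(self):
        from driftsem.synthetic import GeneratorConfig, generate_population

        cfg = GeneratorConfig(n_participants=200, seed=17)
        truth = generate_population(cfg)
        dp = truth.drift_params
        table = dp[dp.condition.isin(["demanding", "single"])].pivot(
            index="participant", columns="task", values="v"
        )
        one = fit_fiml(table, build_model("one_factor"), compute_se=False)
        ho = fit_fiml(
            table,
            build_model("three_factor_higher_order", zero_first_order_residuals=True),
            compute_se=False,
        )
        assert one.df == ho.df == 27
        assert one.loglik == pytest.approx(ho.loglik, abs=1e-3)


class TestFitIndices:
    def test_rmsea_from_printed_chi2(self):
        assert rmsea_from_chi2(28.56, 26, 148) == pytest.approx(0.026, abs=5e-4)
        assert rmsea_from_chi2(51.86, 27, 148) == pytest.approx(0.079, abs=5e-4)

    def test_perfect_fit_boundary(self):
        df = simulate_one_factor(500, [1.0, 0.9, 0.8, 1.1], 0.6, seed=9)
        res = fit_fiml(df, one_factor_spec(df.columns))
        if res.chi2 <= res.df:
            assert res.rmsea == 0.0
            assert res.cfi == 1.0
        lo, hi = res.rmsea_ci()
        assert lo <= res.rmsea + 1e-9
        assert res.rmsea <= hi + 1e-9

    def test_indices_dict(self):
        df = simulate_one_factor(200, [1.0, 0.9, 0.8], 0.6, seed=10)
        res = fit_fiml(df, one_factor_spec(df.columns))
        idx = fit_indices(res)
        assert set(idx) >= {"chi2", "df", "cfi", "rmsea", "aic"}


class TestCompareAic:
    def _two_fits(self):
        df = simulate_one_factor(150, [1.0, 0.9, 0.8, 1.1], 0.6, seed=11)
        spec_a = one_factor_spec(df.columns, name="a")
        spec_b = one_factor_spec(df.columns, name="b")
        return fit_fiml(df, spec_a, compute_se=False), fit_fiml(df, spec_b, compute_se=False)

    def test_identical_models_delta_zero(self):
        a, b = self._two_fits()
        out = compare_aic([a, b])
        assert out["delta_aic"].iloc[1] == pytest.approx(0.0, abs=1e-5)

    def test_substantial_flag_rule(self):
        a, b = self._two_fits()
        b.loglik = a.loglik - 3.80  # delta AIC 7.60: below the threshold
        assert not compare_aic([a, b])["substantial"].iloc[1]
        b.loglik = a.loglik - 6.0  # delta AIC 12: substantial
        assert compare_aic([a, b])["substantial"].iloc[1]

    def test_different_samples_refused(self):
        a, _ = self._two_fits()
        df2 = simulate_one_factor(149, [1.0, 0.9, 0.8, 1.1], 0.6, seed=12)
        c = fit_fiml(df2, one_factor_spec(df2.columns), compute_se=False)
        with pytest.raises(ValueError):
            compare_aic([a, c])


class TestCloseFitPower:
    def test_null_equals_alternative_gives_alpha(self):
        assert power_close_fit(100, 200, 0.05, 0.05, 0.05) == pytest.approx(0.05, abs=1e-10)

    def test_realized_sample_power(self):
        assert power_close_fit(166, 148) > 0.96

    def test_minimum_sample_size(self):
        assert min_n_close_fit(166, 0.05, 0.08, 0.05, 0.80) == 95

    def test_monotone_in_n_and_df(self):
        ns = [80, 120, 200, 400]
        pw = [power_close_fit(166, n) for n in ns]
        assert all(a < b for a, b in zip(pw, pw[1:]))
        dfs = [50, 100, 200, 400]
        pw = [power_close_fit(d, 148) for d in dfs]
        assert all(a < b for a, b in zip(pw, pw[1:]))

    def test_doubling_df_reduces_minimum_n(self):
        assert min_n_close_fit(332) < min_n_close_fit(166)

    def test_barely_above_alpha_needs_tiny_n(self):
        n = min_n_close_fit(166, 0.05, 0.08, 0.05, 0.0500001)
        assert n >= 2 and n < 10

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            power_close_fit(166, 148, eps0=0.08, eps1=0.05)
        with pytest.raises(ValueError):
            min_n_close_fit(166, target_power=0.04)
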