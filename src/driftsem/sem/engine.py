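"""Confirmatory latent-variable models with full-information ML.

Model parameterisation (all matrices over observed vars p and latents m):

    Sigma = Lambda (I - B)^-1 Psi (I - B)^-T Lambda^T + Theta

with Lambda the loading matrix, B latent regression paths, Psi latent
(disturbance) covariances and Theta residual covariances.  Means are
saturated (one free mean per observed variable), so the mean structure
contributes no degrees of freedom.

Estimation maximises the casewise normal log-likelihood over missingness
patterns (FIML), which reduces to complete-data normal-theory ML when no
values are missing.  Standard errors come from the observed information
matrix (numerical Hessian).  Variances are left unconstrained so that
boundary cases surface as small negative estimates (Heywood cases) rather
than being silently clipped; such states, and non-positive-definite latent
covariances, are reported as warnings on the result object.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.stats import chi2, ncx2, norm

__all__ = [
    "ModelSpec",
    "StructuralModel",
    "SEMResults",
    "fit_fiml",
    "fit_indices",
    "critical_ratio_test",
    "compare_aic",
    "saturated_loglik",
    "independence_loglik",
]


class IdentificationError(ValueError):
    """Model not identified (rank-deficient information at start values)."""


FREE = "free"


@dataclass
class ModelSpec:
    """Declarative latent-variable model.

    observed : ordered observed-variable names.
    latents : ordered latent-variable names.
    loadings : (observed, latent) -> FREE or a fixed value.  Scale-setting
        convention: the first loading of each factor is fixed to 1 and the
        factor variance is estimated.
    latent_cov : (latent, latent) -> FREE or fixed value; diagonal entries
        are disturbance variances.  Unlisted off-diagonals are fixed at 0.
    regressions : (target_latent, source_latent) -> FREE or fixed value.
    residual_cov : (observed, observed) -> FREE or fixed value; unlisted
        diagonals default to FREE, unlisted off-diagonals to 0.
    """

    name: str
    observed: list
    latents: list
    loadings: dict = field(default_factory=dict)
    latent_cov: dict = field(default_factory=dict)
    regressions: dict = field(default_factory=dict)
    residual_cov: dict = field(default_factory=dict)

    def free_parameters(self) -> list:
        """Names of free structural parameters, in a stable order."""
        out = []
        for (o, l), v in self.loadings.items():
            if v == FREE:
                out.append(f"lambda:{o}~{l}")
        for (a, b), v in self.latent_cov.items():
            if v == FREE:
                out.append(f"psi:{a}~~{b}")
        for (t, s), v in self.regressions.items():
            if v == FREE:
                out.append(f"beta:{t}~{s}")
        for (a, b), v in self._full_residual_cov().items():
            if v == FREE:
                out.append(f"theta:{a}~~{b}")
        return out

    def _full_residual_cov(self) -> dict:
        full = {}
        for o in self.observed:
            full[(o, o)] = self.residual_cov.get((o, o), FREE)
        for (a, b), v in self.residual_cov.items():
            if a != b:
                full[(a, b)] = v
        return full

    @property
    def n_free(self) -> int:
        return len(self.free_parameters())

    @property
    def df(self) -> int:
        p = len(self.observed)
        return p * (p + 1) // 2 - self.n_free

    def to_json(self) -> str:
        def enc(d):
            return {f"{k[0]}|{k[1]}": v for k, v in d.items()}

        return json.dumps(
            dict(
                name=self.name,
                observed=list(self.observed),
                latents=list(self.latents),
                loadings=enc(self.loadings),
                latent_cov=enc(self.latent_cov),
                regressions=enc(self.regressions),
                residual_cov=enc(self.residual_cov),
            ),
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        raw = json.loads(text)

        def dec(d):
            return {tuple(k.split("|")): v for k, v in d.items()}

        return cls(
            name=raw["name"],
            observed=raw["observed"],
            latents=raw["latents"],
            loadings=dec(raw["loadings"]),
            latent_cov=dec(raw["latent_cov"]),
            regressions=dec(raw["regressions"]),
            residual_cov=dec(raw["residual_cov"]),
        )


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

_LOG2PI = float(np.log(2.0 * np.pi))


def _pattern_stats(data: np.ndarray):
    """Group rows by missingness pattern; per-pattern n, mean and scatter."""
    mask = ~np.isnan(data)
    stats = []
    patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
    for g, pat in enumerate(patterns):
        idx = np.flatnonzero(pat)
        if idx.size == 0:
            continue
        rows = data[inverse == g][:, idx]
        n_g = rows.shape[0]
        mean_g = rows.mean(axis=0)
        centered = rows - mean_g
        scatter = centered.T @ centered / n_g
        stats.append((idx, n_g, mean_g, scatter))
    return stats


def _loglik_from_stats(stats, mu: np.ndarray, sigma: np.ndarray) -> float:
    ll = 0.0
    for idx, n_g, mean_g, scatter in stats:
        sub = sigma[np.ix_(idx, idx)]
        k = idx.size
        try:
            chol = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        diff = mean_g - mu[idx]
        inv_s = np.linalg.solve(sub, scatter)
        quad = diff @ np.linalg.solve(sub, diff)
        ll += -0.5 * n_g * (k * _LOG2PI + logdet + np.trace(inv_s) + quad)
    return float(ll)


class SaturatedModelError(RuntimeError):
    """Saturated covariance not estimable (e.g. fewer persons than
    variables); chi-square-based fit indices are then unavailable."""


def saturated_loglik(data: np.ndarray, tol: float = 1e-10, max_iter: int = 2000):
    """FIML log-likelihood of the saturated model (free mean and covariance).

    Complete data: closed form from the ML covariance.  With missing data:
    EM for the multivariate-normal mean/covariance.
    """
    stats = _pattern_stats(data)
    p = data.shape[1]
    if data.shape[0] <= p:
        raise SaturatedModelError(
            f"saturated model needs more persons ({data.shape[0]}) than variables ({p})"
        )
    if len(stats) == 1 and stats[0][0].size == p:
        _, n, mean, scatter = stats[0]
        if np.linalg.matrix_rank(scatter) < p:
            raise SaturatedModelError("sample covariance singular")
        return _loglik_from_stats(stats, mean, scatter), mean, scatter
    # EM start: available-case means/variances
    mu = np.nanmean(data, axis=0)
    sigma = np.diag(np.nanvar(data, axis=0) + 1e-6)
    n = data.shape[0]
    prev = -np.inf
    for _ in range(max_iter):
        # E-step: accumulate expected sufficient statistics
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for idx, n_g, mean_g, scatter in stats:
            miss = np.setdiff1d(np.arange(p), idx)
            rows_mean = mean_g
            s_oo = sigma[np.ix_(idx, idx)]
            if miss.size:
                s_mo = sigma[np.ix_(miss, idx)]
                try:
                    reg = np.linalg.solve(s_oo, s_mo.T).T  # miss x obs
                except np.linalg.LinAlgError:
                    ridge = s_oo + 1e-8 * np.trace(s_oo) / s_oo.shape[0] * np.eye(s_oo.shape[0])
                    reg = np.linalg.solve(ridge, s_mo.T).T
                cond_cov = sigma[np.ix_(miss, miss)] - reg @ s_mo.T
            # per-pattern expected stats from (n_g, mean_g, scatter)
            e_mean = np.zeros(p)
            e_mean[idx] = rows_mean
            e_sc = np.zeros((p, p))
            e_sc[np.ix_(idx, idx)] = scatter + np.outer(rows_mean, rows_mean)
            if miss.size:
                m_cond = mu[miss] + reg @ (rows_mean - mu[idx])
                e_mean[miss] = m_cond
                # E[x_m x_o'] = (mu_m - R mu_o) mean_o' + R E[x_o x_o']
                e_xm_xo = np.outer(mu[miss] - reg @ mu[idx], rows_mean) + reg @ (
                    scatter + np.outer(rows_mean, rows_mean)
                )
                e_sc[np.ix_(miss, idx)] = e_xm_xo
                e_sc[np.ix_(idx, miss)] = e_xm_xo.T
                e_mm = (
                    cond_cov
                    + np.outer(mu[miss] - reg @ mu[idx], m_cond)
                    + e_xm_xo @ reg.T
                )
                e_sc[np.ix_(miss, miss)] = e_mm
            s1 += n_g * e_mean
            s2 += n_g * e_sc
        mu = s1 / n
        sigma = s2 / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        ll = _loglik_from_stats(stats, mu, sigma)
        if abs(ll - prev) < tol * (1.0 + abs(ll)):
            break
        prev = ll
    return ll, mu, sigma


def independence_loglik(data: np.ndarray) -> tuple[float, int]:
    """FIML log-likelihood and free-parameter count of the independence
    baseline (free means and variances, zero covariances).

    With a diagonal covariance the likelihood factorises per variable, so
    the per-variable available-case ML mean/variance is exact.
    """
    ll = 0.0
    p = data.shape[1]
    for j in range(p):
        col = data[:, j]
        col = col[~np.isnan(col)]
        n = col.size
        var = col.var()  # ML (divide by n)
        if n == 0 or var <= 0:
            continue  # degenerate column carries no baseline information
        ll += -0.5 * n * (_LOG2PI + np.log(var) + 1.0)
    return float(ll), 2 * p


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

class StructuralModel:
    """A latent-variable model bound to a person x variable score table.

    Parameters
    ----------
    data : DataFrame whose columns include every observed variable of the
        spec; NaN marks missing values (handled by FIML).
    spec : ModelSpec
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        missing_cols = [c for c in spec.observed if c not in data.columns]
        if missing_cols:
            raise KeyError(f"data lacks observed variables: {missing_cols}")
        self.spec = spec
        self.data = data[spec.observed].astype(float)
        self._X = self.data.to_numpy()
        keep = ~np.all(np.isnan(self._X), axis=1)
        self._X = self._X[keep]
        self.nobs = self._X.shape[0]
        self._stats = _pattern_stats(self._X)
        self._complete = len(self._stats) == 1 and self._stats[0][0].size == len(spec.observed)
        self._index = self._build_index()
        if self.spec.df < 0:
            raise IdentificationError(
                f"negative degrees of freedom ({self.spec.df}); model not identified"
            )

    # -- parameter bookkeeping ------------------------------------------------
    def _build_index(self):
        spec = self.spec
        obs_i = {o: i for i, o in enumerate(spec.observed)}
        lat_i = {l: i for i, l in enumerate(spec.latents)}
        free_names = spec.free_parameters()
        pos = {name: i for i, name in enumerate(free_names)}
        entries = []  # (matrix, i, j, free_pos or None, fixed_value)
        for (o, l), v in spec.loadings.items():
            entries.append(("lambda", obs_i[o], lat_i[l],
                            pos.get(f"lambda:{o}~{l}"), v))
        for (a, b), v in spec.latent_cov.items():
            entries.append(("psi", lat_i[a], lat_i[b], pos.get(f"psi:{a}~~{b}"), v))
        for (t, s), v in spec.regressions.items():
            entries.append(("beta", lat_i[t], lat_i[s], pos.get(f"beta:{t}~{s}"), v))
        for (a, b), v in spec._full_residual_cov().items():
            entries.append(("theta", obs_i[a], obs_i[b], pos.get(f"theta:{a}~~{b}"), v))
        return dict(free_names=free_names, entries=entries)

    def _matrices(self, theta: np.ndarray):
        p = len(self.spec.observed)
        m = len(self.spec.latents)
        lam = np.zeros((p, m))
        psi = np.zeros((m, m))
        beta = np.zeros((m, m))
        th = np.zeros((p, p))
        for mat, i, j, posn, v in self._index["entries"]:
            val = theta[posn] if posn is not None else float(v)
            if mat == "lambda":
                lam[i, j] = val
            elif mat == "psi":
                psi[i, j] = val
                psi[j, i] = val
            elif mat == "beta":
                beta[i, j] = val
            else:
                th[i, j] = val
                th[j, i] = val
        return lam, psi, beta, th

    def implied_sigma(self, theta: np.ndarray) -> np.ndarray:
        lam, psi, beta, th = self._matrices(theta)
        m = psi.shape[0]
        inv = np.linalg.solve(np.eye(m) - beta, np.eye(m))
        latent = inv @ psi @ inv.T
        return lam @ latent @ lam.T + th

    # -- likelihood -----------------------------------------------------------
    def loglik(self, theta: np.ndarray, mu: np.ndarray) -> float:
        sigma = self.implied_sigma(theta)
        return _loglik_from_stats(self._stats, mu, sigma)

    def _start_values(self):
        spec = self.spec
        var = np.nanvar(self._X, axis=0, ddof=1)
        obs_i = {o: i for i, o in enumerate(spec.observed)}
        # scaling indicator per latent = first observed with a fixed loading
        scale_var = {}
        for l in spec.latents:
            for (o, ll), v in spec.loadings.items():
                if ll == l and v != FREE:
                    scale_var[l] = var[obs_i[o]]
                    break
            else:
                scale_var[l] = 1.0
        theta0 = []
        for name in self._index["free_names"]:
            kind, rest = name.split(":", 1)
            if kind == "lambda":
                theta0.append(1.0)
            elif kind == "psi":
                a, b = rest.split("~~")
                if a == b:
                    theta0.append(0.5 * scale_var.get(a, 1.0))
                else:
                    theta0.append(0.1 * np.sqrt(scale_var.get(a, 1.0) * scale_var.get(b, 1.0)))
            elif kind == "beta":
                theta0.append(0.1)
            else:
                a, b = rest.split("~~")
                theta0.append(0.5 * var[obs_i[a]] if a == b else 0.0)
        mu0 = np.nanmean(self._X, axis=0)
        return np.asarray(theta0), mu0

    def fit(self, maxiter: int = 2000, gtol: float = 1e-8, compute_se: bool = True) -> "SEMResults":
        theta0, mu0 = self._start_values()
        k = theta0.size

        if self._complete:
            # mu profiles out exactly at the sample mean
            mu_hat = mu0

            def nll(th):
                val = self.loglik(th, mu_hat)
                return -val if np.isfinite(val) else 1e12

            res = minimize(nll, theta0, method="L-BFGS-B",
                           options=dict(maxiter=maxiter, gtol=gtol, maxfun=10 * maxiter))
            full = res.x
        else:
            def nll(z):
                val = self.loglik(z[:k], z[k:])
                return -val if np.isfinite(val) else 1e12

            res = minimize(nll, np.concatenate([theta0, mu0]), method="L-BFGS-B",
                           options=dict(maxiter=maxiter, gtol=gtol, maxfun=10 * maxiter))
            full = res.x[:k]
            mu_hat = res.x[k:]

        theta_hat = full
        ll_model = self.loglik(theta_hat, mu_hat)
        warnings_list = []
        try:
            ll_sat, _, _ = saturated_loglik(self._X)
        except (SaturatedModelError, np.linalg.LinAlgError) as err:
            ll_sat = np.nan
            warnings_list.append(f"saturated model unavailable: {err}")
        ll_base, base_free = independence_loglik(self._X)
        p = len(self.spec.observed)
        lam, psi, beta, th = self._matrices(theta_hat)
        if np.any(np.diag(psi) < 0) or np.any(np.diag(th) < 0):
            warnings_list.append("negative variance estimate (Heywood case)")
        try:
            m = psi.shape[0]
            inv = np.linalg.solve(np.eye(m) - beta, np.eye(m))
            latent_cov = inv @ psi @ inv.T
            if np.any(np.linalg.eigvalsh(latent_cov) < -1e-10):
                warnings_list.append("latent covariance matrix not positive definite")
        except np.linalg.LinAlgError:
            warnings_list.append("latent covariance matrix singular")
        if not res.success:
            warnings_list.append(f"optimizer: {res.message}")

        se = np.full(k, np.nan)
        if compute_se:
            se = self._standard_errors(theta_hat, mu_hat, warnings_list)

        chi2_stat = max(2.0 * (ll_sat - ll_model), 0.0) if np.isfinite(ll_sat) else np.nan
        df = self.spec.df
        chi2_base = max(2.0 * (ll_sat - ll_base), 0.0) if np.isfinite(ll_sat) else np.nan
        df_base = p * (p + 1) // 2 - p  # independence: p free variances
        n_free_total = k + p  # structural + saturated means

        return SEMResults(
            model=self,
            spec=self.spec,
            params=pd.Series(theta_hat, index=self._index["free_names"]),
            se=pd.Series(se, index=self._index["free_names"]),
            mu=pd.Series(mu_hat, index=self.spec.observed),
            loglik=ll_model,
            loglik_saturated=ll_sat,
            loglik_baseline=ll_base,
            chi2=chi2_stat,
            df=df,
            chi2_baseline=chi2_base,
            df_baseline=df_base,
            nobs=self.nobs,
            n_free=n_free_total,
            converged=bool(res.success),
            warnings=warnings_list,
        )

    def _standard_errors(self, theta, mu, warnings_list, step: float = 1e-5):
        """Observed-information SEs via central-difference Hessian."""
        k = theta.size

        def f(th):
            if self._complete:
                return self.loglik(th, mu)
            # re-profile means would be costlier; holding mu at the FIML
            # estimate gives the observed information for theta given mu
            return self.loglik(th, mu)

        h = step * (1.0 + np.abs(theta))
        hess = np.empty((k, k))
        f0 = f(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = h[i]
                ej[j] = h[j]
                fpp = f(theta + ei + ej)
                fpm = f(theta + ei - ej)
                fmp = f(theta - ei + ej)
                fmm = f(theta - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
        info = -hess
        try:
            cov = np.linalg.inv(info)
            diag = np.diag(cov)
            if np.any(diag < 0):
                warnings_list.append("information matrix not positive definite")
            se = np.sqrt(np.where(diag > 0, diag, np.nan))
        except np.linalg.LinAlgError:
            warnings_list.append("information matrix singular; SEs unavailable")
            se = np.full(k, np.nan)
        return se

    def check_identification(self) -> bool:
        """Rank check of the Jacobian of vech(Sigma) at start values."""
        theta0, _ = self._start_values()
        k = theta0.size
        p = len(self.spec.observed)
        iu = np.triu_indices(p)

        def vech_sigma(th):
            return self.implied_sigma(th)[iu]

        J = np.empty((iu[0].size, k))
        h = 1e-6
        for i in range(k):
            e = np.zeros(k)
            e[i] = h
            J[:, i] = (vech_sigma(theta0 + e) - vech_sigma(theta0 - e)) / (2 * h)
        return np.linalg.matrix_rank(J, tol=1e-8) == k


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class SEMResults:
    """Fitted latent-variable model: estimates, SEs, fit statistics."""

    model: StructuralModel
    spec: ModelSpec
    params: pd.Series
    se: pd.Series
    mu: pd.Series
    loglik: float
    loglik_saturated: float
    loglik_baseline: float
    chi2: float
    df: int
    chi2_baseline: float
    df_baseline: int
    nobs: int
    n_free: int
    converged: bool
    warnings: list

    # -- fit indices ----------------------------------------------------------
    @property
    def p_value(self) -> float:
        if self.df == 0 or not np.isfinite(self.chi2):
            return np.nan
        return float(chi2.sf(self.chi2, self.df))

    @property
    def cfi(self) -> float:
        if not np.isfinite(self.chi2):
            return np.nan
        d_model = max(self.chi2 - self.df, 0.0)
        d_base = max(self.chi2_baseline - self.df_baseline, d_model, 0.0)
        if d_base == 0.0:
            return 1.0
        return 1.0 - d_model / d_base

    @property
    def rmsea(self) -> float:
        if self.df == 0 or not np.isfinite(self.chi2):
            return np.nan
        return float(np.sqrt(max(self.chi2 - self.df, 0.0) / (self.df * (self.nobs - 1))))

    def rmsea_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval by inverting the noncentral chi-square."""
        if self.df == 0 or not np.isfinite(self.chi2):
            return (np.nan, np.nan)
        lo_q, hi_q = (1.0 + level) / 2.0, (1.0 - level) / 2.0
        scale = self.df * (self.nobs - 1)

        def bound(q):
            # find lambda with ncx2.cdf(chi2, df, lam) = q
            if ncx2.cdf(self.chi2, self.df, 0.0) < q:
                return 0.0
            hi = max(self.chi2 * 2, 10.0)
            while ncx2.cdf(self.chi2, self.df, hi) > q:
                hi *= 2.0
            lam = brentq(lambda l: ncx2.cdf(self.chi2, self.df, l) - q, 0.0, hi)
            return lam

        return (float(np.sqrt(bound(lo_q) / scale)), float(np.sqrt(bound(hi_q) / scale)))

    @property
    def aic(self) -> float:
        return float(-2.0 * self.loglik + 2.0 * self.n_free)

    # -- inference ------------------------------------------------------------
    def critical_ratio(self, parameter: str) -> tuple[float, float]:
        """Two-sided critical-ratio (Wald z) test for one free parameter."""
        if parameter not in self.params.index:
            raise KeyError(parameter)
        est = self.params[parameter]
        s = self.se[parameter]
        if not np.isfinite(s) or s <= 0:
            warnings.warn(f"{parameter}: SE unavailable; test undefined")
            return (np.nan, np.nan)
        z = est / s
        return float(z), float(2.0 * norm.sf(abs(z)))

    def summary(self) -> str:
        lines = [
            f"Model: {self.spec.name}   n = {self.nobs}   converged: {self.converged}",
            f"logLik = {self.loglik:.3f}   chi2({self.df}) = {self.chi2:.2f}"
            f"   p = {self.p_value:.3f}" if self.df else
            f"logLik = {self.loglik:.3f}   chi2(0) = 0 (saturated)",
            f"CFI = {self.cfi:.3f}   RMSEA = {self.rmsea:.3f}"
            f"   90/95% CI = [{self.rmsea_ci()[0]:.3f}, {self.rmsea_ci()[1]:.3f}]"
            if self.df else "",
            f"AIC = {self.aic:.2f}",
        ]
        tab = pd.DataFrame({"estimate": self.params, "se": self.se})
        tab["z"] = tab["estimate"] / tab["se"]
        tab["p"] = 2.0 * norm.sf(np.abs(tab["z"]))
        lines.append(tab.to_string(float_format=lambda v: f"{v: .4f}"))
        if self.warnings:
            lines.append("warnings: " + "; ".join(self.warnings))
        return "\n".join(s for s in lines if s)


# ---------------------------------------------------------------------------
# functional front ends
# ---------------------------------------------------------------------------

def rmsea_from_chi2(chi2_stat: float, df: int, n: int) -> float:
    """RMSEA from a reported chi-square: sqrt(max(chi2 - df, 0) / (df (N-1)))."""
    if df <= 0:
        raise ValueError("RMSEA undefined for df <= 0")
    return float(np.sqrt(max(chi2_stat - df, 0.0) / (df * (n - 1))))


def rmsea_ci_from_chi2(chi2_stat: float, df: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """RMSEA confidence interval from a reported chi-square by noncentrality
    inversion (symmetric two-sided at ``level``)."""
    lo_q, hi_q = (1.0 + level) / 2.0, (1.0 - level) / 2.0
    scale = df * (n - 1)

    def bound(q):
        if ncx2.cdf(chi2_stat, df, 1e-12) < q:
            return 0.0
        hi = max(chi2_stat * 2, 10.0)
        while ncx2.cdf(chi2_stat, df, hi) > q:
            hi *= 2.0
        return brentq(lambda l: ncx2.cdf(chi2_stat, df, l) - q, 1e-12, hi)

    return (float(np.sqrt(bound(lo_q) / scale)), float(np.sqrt(bound(hi_q) / scale)))


def fit_fiml(score_table: pd.DataFrame, spec: ModelSpec, **kwargs) -> SEMResults:
    """Fit ``spec`` to a person x variable table by FIML."""
    return StructuralModel(score_table, spec).fit(**kwargs)


def fit_indices(result: SEMResults) -> dict:
    """CFI, RMSEA (with 95% CI) and AIC for a fitted model."""
    lo, hi = result.rmsea_ci()
    return dict(
        chi2=result.chi2, df=result.df, p=result.p_value,
        cfi=result.cfi, rmsea=result.rmsea, rmsea_ci_low=lo, rmsea_ci_high=hi,
        aic=result.aic,
    )


def critical_ratio_test(result: SEMResults, parameter: str) -> tuple[float, float]:
    return result.critical_ratio(parameter)


def compare_aic(results: list, threshold: float = 10.0) -> pd.DataFrame:
    """Rank fitted models by AIC; flag differences >= ``threshold`` as
    substantial.  Refuses to compare fits on different samples."""
    base = results[0]
    for r in results[1:]:
        if r.nobs != base.nobs or list(r.spec.observed) != list(base.spec.observed):
            raise ValueError("AIC comparison requires the same data and observed variables")
    rows = [dict(model=r.spec.name, aic=r.aic, df=r.df) for r in results]
    out = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    out["substantial"] = out["delta_aic"] >= threshold
    return out
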