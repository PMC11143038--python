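"""Two-boundary Wiener diffusion: first-passage distributions, simulation,
and Kolmogorov–Smirnov parameter estimation.

The model describes a two-choice decision as noisy evidence accumulation
between two absorbing boundaries a distance ``a`` apart (diffusion
coefficient fixed at 1).  Accumulation starts at relative position ``zr``
(fixed at 0.5 here: unbiased), drifts at rate ``v`` toward the correct
(upper) boundary, and the observed response time adds a non-decision time
``t0`` that varies uniformly across trials over a range ``st0``.

Densities and CDFs use the standard small-time / large-time series
representations of the Wiener first-passage-time distribution with an
automatic truncation-based switching rule.  Parameter estimation minimises
the supremum distance between the empirical and model-implied CDF on the
signed-RT axis (error RTs negated), a criterion that fits RT shape and
accuracy simultaneously; drift rates may be condition-specific while
``a``, ``t0`` and ``st0`` are shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "DiffusionParams",
    "FitDiagnostics",
    "DiffusionFitResult",
    "DiffusionModel",
    "hit_probability",
    "fpt_density",
    "fpt_cdf",
    "simulate_trials",
    "sample_first_passage",
    "estimate_ks",
    "ks_statistic",
    "ez_starting_values",
    "model_check",
    "TRIAL_COLUMNS",
]

#: canonical trial-table schema used across the package
TRIAL_COLUMNS = ["participant", "task", "condition", "trial_index", "rt_s", "correct"]

_EPS = 1e-6  # absolute accuracy target of the density series


class ParameterError(ValueError):
    """Raised when diffusion parameters violate their domain."""


class EstimationError(RuntimeError):
    """Raised when KS estimation cannot proceed (degenerate data)."""


@dataclass(frozen=True)
class DiffusionParams:
    """Wiener diffusion parameters.

    v : drift rate (evidence units / s, diffusion coefficient 1)
    a : boundary separation (> 0)
    t0 : mean non-decision time (s, >= 0)
    st0 : inter-trial range of the non-decision time; the non-decision
        time is uniform on [t0 - st0/2, t0 + st0/2]
    zr : relative start point, fixed at 0.5 (unbiased) in every fit
    """

    v: float
    a: float
    t0: float = 0.0
    st0: float = 0.0
    zr: float = 0.5

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.v, self.a, self.t0, self.st0, self.zr])):
            raise ParameterError("diffusion parameters must be finite")
        if self.a <= 0:
            raise ParameterError(f"boundary separation a must be > 0, got {self.a}")
        if not 0 < self.zr < 1:
            raise ParameterError(f"relative start zr must lie in (0, 1), got {self.zr}")
        if self.st0 < 0:
            raise ParameterError(f"st0 must be >= 0, got {self.st0}")
        if self.t0 - self.st0 / 2 < -1e-12:
            raise ParameterError("non-decision window extends below zero (t0 - st0/2 < 0)")

    @property
    def t_floor(self) -> float:
        """Earliest possible response time."""
        return self.t0 - self.st0 / 2


@dataclass
class FitDiagnostics:
    """Goodness-of-fit summary for one KS fit."""

    ks_stat: float
    n_trials: int
    predicted_quantiles: np.ndarray  # RT at the 25/50/75th percentiles (s)
    predicted_accuracy: float
    converged: bool = True


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def hit_probability(params: DiffusionParams) -> float:
    """Probability of absorbing at the correct (upper) boundary.

    (1 - exp(-2 v zr a)) / (1 - exp(-2 v a)); equals 1 / (1 + exp(-a v))
    for the unbiased start zr = 0.5, and exactly zr when v = 0.
    """
    v, a, zr = params.v, params.a, params.zr
    if abs(v) < 1e-9:
        return zr
    num = -np.expm1(-2.0 * v * zr * a)
    den = -np.expm1(-2.0 * v * a)
    return float(num / den)


# ---------------------------------------------------------------------------
# first-passage density / CDF (lower boundary is the reference; the upper
# boundary follows from the reflection v -> -v, zr -> 1 - zr)
# ---------------------------------------------------------------------------

def _density_lower_raw(t: np.ndarray, v: float, a: float, zr: float) -> np.ndarray:
    """Density of absorption at the lower boundary at decision time t (> 0).

    Small-time and large-time series, each truncated to absolute accuracy
    ``_EPS``; per element the representation needing fewer terms wins.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    if not pos.any():
        return out
    tp = t[pos]
    w = tp / a**2  # normalized time

    # truncation counts (Navarro & Fuss 2009 style bounds)
    with np.errstate(divide="ignore", invalid="ignore"):
        ks = 2.0 + np.sqrt(np.maximum(-2.0 * w * np.log(2.0 * _EPS * np.sqrt(2.0 * np.pi * w)), 0.0))
        ks = np.maximum(ks, np.sqrt(w) + 1.0)
        kl = np.sqrt(np.maximum(-2.0 * np.log(np.pi * w * _EPS) / (np.pi**2 * w), 0.0))
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(w)))

    use_small = ks < kl
    f1 = np.empty_like(w)

    if use_small.any():
        ws = w[use_small]
        K = int(np.ceil(ks[use_small].max()))
        k = np.arange(-K, K + 1)
        nodes = zr + 2.0 * k  # (2K+1,)
        # sum_k (zr+2k) exp(-(zr+2k)^2 / (2w)) / sqrt(2 pi w^3)
        expo = -(nodes[None, :] ** 2) / (2.0 * ws[:, None])
        series = (nodes[None, :] * np.exp(expo)).sum(axis=1)
        f1[use_small] = series / np.sqrt(2.0 * np.pi * ws**3)

    if (~use_small).any():
        wl = w[~use_small]
        K = int(np.ceil(kl[~use_small].max()))
        k = np.arange(1, K + 1)
        expo = -(k[None, :] ** 2) * np.pi**2 * wl[:, None] / 2.0
        series = (k[None, :] * np.exp(expo) * np.sin(k[None, :] * np.pi * zr)).sum(axis=1)
        f1[~use_small] = np.pi * series

    # scale back from the normalized (a=1, v=0) problem
    scale = np.exp(-v * a * zr - v**2 * tp / 2.0) / a**2
    out[pos] = np.maximum(scale * f1, 0.0)
    return out


def _prob_lower(v: float, a: float, zr: float) -> float:
    if abs(v) < 1e-9:
        return 1.0 - zr
    num = -np.expm1(-2.0 * v * zr * a)
    den = -np.expm1(-2.0 * v * a)
    return float(1.0 - num / den)


# Gauss-Legendre nodes reused for small-time CDF quadrature
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


def _cdf_lower_raw(t: np.ndarray, v: float, a: float, zr: float) -> np.ndarray:
    """P(absorb at lower boundary and decision time <= t)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    if not pos.any():
        return out
    tp = t[pos]
    w = tp / a**2
    p_low = _prob_lower(v, a, zr)
    res = np.empty_like(tp)

    small = w < 0.05  # large-time CDF series converges slowly here
    if small.any():
        # integrate the density over [0, t] (smooth integrand, fixed GL rule)
        ts = tp[small]
        half = ts / 2.0
        nodes = half[:, None] * (_GL_NODES[None, :] + 1.0)  # (m, 64)
        dens = _density_lower_raw(nodes.ravel(), v, a, zr).reshape(nodes.shape)
        res[small] = (dens * _GL_WEIGHTS[None, :]).sum(axis=1) * half

    if (~small).any():
        tl = tp[~small]
        wl = w[~small]
        # truncation: |term_k| <= (pi/a^2) k e^{-v a zr} e^{-lam_k t} / lam_k
        # with lam_k >= k^2 pi^2 / (2 a^2); solve for the tail < _EPS crudely
        K = int(np.ceil(np.sqrt(max(
            -2.0 * np.log(_EPS * np.pi * wl.min() / 2.0), 1.0)) / (np.pi * np.sqrt(wl.min())))) + 2
        K = min(max(K, 4), 100_000)
        k = np.arange(1, K + 1)
        lam = (v**2 + (k * np.pi / a) ** 2) / 2.0  # (K,)
        coef = k * np.sin(k * np.pi * zr) / lam  # (K,)
        expo = np.exp(-lam[None, :] * tl[:, None])  # (m, K)
        series = expo @ coef
        res[~small] = p_low - (np.pi / a**2) * np.exp(-v * a * zr) * series

    out[pos] = np.clip(res, 0.0, p_low)
    return out


def _st0_nodes(params: DiffusionParams, n_nodes: int = 11):
    """Quadrature nodes/weights over the uniform non-decision window."""
    if params.st0 <= 0:
        return np.array([params.t0]), np.array([1.0])
    x, wgt = np.polynomial.legendre.leggauss(n_nodes)
    nodes = params.t0 + (params.st0 / 2.0) * x
    return nodes, wgt / 2.0  # weights sum to 1


def _boundary_vzr(params: DiffusionParams, boundary: str):
    if boundary == "upper":
        return -params.v, 1.0 - params.zr
    if boundary == "lower":
        return params.v, params.zr
    raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")


def fpt_density(params: DiffusionParams, t, boundary: str = "upper") -> np.ndarray | float:
    """First-passage density (1/s) at observed time ``t`` for one boundary.

    Zero for t below the non-decision floor; the uniform non-decision
    window is handled by quadrature over st0.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.isfinite(t_arr).all():
        raise ValueError("t must be finite")
    v, zr = _boundary_vzr(params, boundary)
    nodes, wgt = _st0_nodes(params)
    dec = t_arr[:, None] - nodes[None, :]
    dens = _density_lower_raw(dec.ravel(), v, params.a, zr).reshape(dec.shape)
    out = dens @ wgt
    return out if np.ndim(t) else float(out[0])


def fpt_cdf(params: DiffusionParams, t, boundary: str = "upper") -> np.ndarray | float:
    """P(response at ``boundary`` with RT <= t)."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.isfinite(t_arr).all():
        raise ValueError("t must be finite")
    v, zr = _boundary_vzr(params, boundary)
    nodes, wgt = _st0_nodes(params)
    dec = t_arr[:, None] - nodes[None, :]
    cdfs = _cdf_lower_raw(dec.ravel(), v, params.a, zr).reshape(dec.shape)
    out = cdfs @ wgt
    return out if np.ndim(t) else float(out[0])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_trials(
    params: DiffusionParams,
    n: int,
    seed: int | np.random.Generator,
    dt: float = 1e-4,
    max_t: float = 20.0,
    participant: str = "p1",
    task: str = "task",
    condition: str = "cond",
) -> pd.DataFrame:
    """Euler–Maruyama simulation of ``n`` trials; returns a trial table.

    Discrete-time monitoring lets paths overshoot the boundaries between
    steps, which biases absorption statistics outward by about
    0.5826*sqrt(dt) per boundary (the Broadie–Glasserman–Kou continuity
    correction); the boundaries are therefore pulled inward by that amount
    so the simulated process matches the continuous-time model.  Trials
    not absorbed by ``max_t`` (vanishingly rare for sensible parameters)
    are censored there and labelled by the sign of the final evidence
    state.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng(seed)
    sqdt = np.sqrt(dt)
    shift = 0.5826 * sqdt  # continuity correction per boundary
    upper_b = params.a - shift
    lower_b = shift
    if upper_b - lower_b <= 0:
        raise ValueError("dt too coarse for this boundary separation")
    block = 256
    max_steps = int(np.ceil(max_t / dt))

    rts = np.empty(n)
    hits = np.empty(n, dtype=np.int64)
    # chunk trials to bound memory at block * chunk floats
    chunk = max(1, int(2.5e7) // block)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        m = hi - lo
        x = np.full(m, params.zr * params.a)
        alive = np.arange(m)
        dec_t = np.full(m, max_t)
        hit = np.zeros(m, dtype=np.int64)
        step = 0
        while alive.size and step < max_steps:
            nsteps = min(block, max_steps - step)
            incr = rng.normal(params.v * dt, sqdt, size=(alive.size, nsteps))
            path = x[alive, None] + np.cumsum(incr, axis=1)
            up = path >= upper_b
            lowm = path <= lower_b
            crossed = up | lowm
            any_cross = crossed.any(axis=1)
            first = np.argmax(crossed, axis=1)
            idx = alive[any_cross]
            f = first[any_cross]
            dec_t[idx] = (step + f + 1) * dt
            hit[idx] = up[any_cross, f].astype(np.int64)
            x[alive] = path[:, -1]
            alive = alive[~any_cross]
            step += nsteps
        if alive.size:  # censored: classify by final position
            hit[alive] = (x[alive] >= params.zr * params.a).astype(np.int64)
        rts[lo:hi] = dec_t
        hits[lo:hi] = hit

    ndt = params.t0 + (rng.random(n) - 0.5) * params.st0
    return pd.DataFrame(
        {
            "participant": participant,
            "task": task,
            "condition": condition,
            "trial_index": np.arange(n),
            "rt_s": rts + ndt,
            "correct": hits,
        }
    )


def sample_first_passage(
    params: DiffusionParams,
    n: int,
    rng: np.random.Generator,
    grid_size: int = 2048,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast exact-distribution sampler via inverse-CDF on a dense grid.

    Returns (rt, correct).  Used by the synthetic-data generator, where the
    Euler path-level simulator would be needlessly slow.
    """
    from driftsem._wfpt_fast import boundary_cdf_grid

    # find a horizon covering all but ~1e-7 of the mass (decision time only)
    def total(t):
        g = np.array([float(t)])
        return float(
            boundary_cdf_grid(g, params.v, params.a, 0.0, 0.0, params.zr, False)[0]
            + boundary_cdf_grid(g, params.v, params.a, 0.0, 0.0, params.zr, True)[0]
        )

    T = 1.0
    while total(T) < 1.0 - 1e-7 and T < 200.0:
        T *= 2.0
    grid = np.linspace(0.0, T, grid_size)
    cdf_up = boundary_cdf_grid(grid, params.v, params.a, 0.0, 0.0, params.zr, False)
    cdf_lo = boundary_cdf_grid(grid, params.v, params.a, 0.0, 0.0, params.zr, True)
    p_up = hit_probability(params)

    u = rng.random(n)
    correct = (u < p_up).astype(np.int64)
    q = rng.random(n)
    rt = np.empty(n)
    for val, cdf, mass in ((1, cdf_up, p_up), (0, cdf_lo, 1.0 - p_up)):
        sel = correct == val
        if not sel.any():
            continue
        target = q[sel] * cdf[-1]
        rt[sel] = np.interp(target, cdf, grid)
    ndt = params.t0 + (rng.random(n) - 0.5) * params.st0
    return rt + ndt, correct


# ---------------------------------------------------------------------------
# KS estimation
# ---------------------------------------------------------------------------

def _signed_sorted(rt: np.ndarray, correct: np.ndarray) -> np.ndarray:
    return np.sort(np.where(correct > 0, rt, -rt))


def _model_signed_cdf(params: DiffusionParams, x: np.ndarray) -> np.ndarray:
    """Model CDF of the signed RT (errors negative, correct positive)."""
    p_low = 1.0 - hit_probability(params)
    out = np.empty_like(x)
    neg = x < 0
    if neg.any():
        out[neg] = p_low - np.asarray(fpt_cdf(params, -x[neg], "lower"))
    if (~neg).any():
        out[~neg] = p_low + np.asarray(fpt_cdf(params, x[~neg], "upper"))
    return out


def _ks_statistic_ref(params: DiffusionParams, rt: np.ndarray, correct: np.ndarray) -> float:
    """Reference (numpy series) KS statistic; kept as the oracle for the
    compiled kernel used in fitting."""
    x = _signed_sorted(np.asarray(rt, float), np.asarray(correct))
    n = x.size
    model = _model_signed_cdf(params, x)
    upper = np.arange(1, n + 1) / n
    lower = np.arange(0, n) / n
    return float(max(np.abs(model - upper).max(), np.abs(model - lower).max()))


def ks_statistic(params: DiffusionParams, rt: np.ndarray, correct: np.ndarray) -> float:
    """Supremum distance between empirical and model signed-RT CDFs."""
    from driftsem._wfpt_fast import ks_statistic_fast

    x = _signed_sorted(np.asarray(rt, float), np.asarray(correct))
    return float(ks_statistic_fast(x, params.v, params.a, params.t0, params.st0, params.zr))


def ez_starting_values(rt: np.ndarray, correct: np.ndarray) -> DiffusionParams:
    """Moment-based (EZ-style) starting values from accuracy, RT mean, RT var."""
    rt = np.asarray(rt, float)
    n = rt.size
    pc = (np.sum(correct) + 0.5) / (n + 1.0)  # edge-corrected accuracy
    pc = float(np.clip(pc, 0.02, 0.98))
    if abs(pc - 0.5) < 1e-3:
        pc = 0.51
    mrt = float(np.mean(rt))
    vrt = float(np.var(rt, ddof=1))
    if vrt <= 0:
        raise EstimationError("degenerate RT variance; cannot form starting values")
    L = np.log(pc / (1.0 - pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5) / vrt
    v = np.sign(pc - 0.5) * abs(x) ** 0.25
    v = float(np.clip(v, -9.0, 9.0))
    if abs(v) < 0.1:
        v = 0.1 if pc >= 0.5 else -0.1
    a = float(np.clip(L / v, 0.2, 4.5))
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(-v * a)) / (1.0 + np.exp(-v * a))
    t0 = max(mrt - mdt, 0.05)
    t0 = min(t0, max(rt.min() - 1e-3, 1e-3))
    return DiffusionParams(v=v, a=a, t0=t0, st0=min(0.1, t0))


_BOUNDS = {"a": (0.1, 5.0), "v": (-10.0, 10.0)}


@dataclass
class DiffusionFitResult:
    """Result of a KS diffusion fit (single- or multi-condition)."""

    params: dict[str, DiffusionParams]  # keyed by condition label
    ks_stat: float
    diagnostics: dict[str, FitDiagnostics]
    n_trials: dict[str, int]
    converged: bool
    n_restarts: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for cond, p in self.params.items():
            rows.append(
                {
                    "condition": cond,
                    "v": p.v,
                    "a": p.a,
                    "t0": p.t0,
                    "st0": p.st0,
                    "ks_stat": self.diagnostics[cond].ks_stat,
                    "n_trials": self.n_trials[cond],
                }
            )
        return pd.DataFrame(rows)


class DiffusionModel:
    """Wiener diffusion model for one participant's trials in one task.

    Fits {v, a, t0, st0} by minimising the KS statistic on the signed-RT
    distribution.  With several conditions, drift is condition-specific
    while a, t0, st0 are shared, matching the convention of estimating
    condition-wise drift with all other parameters held constant.

    Parameters
    ----------
    trials : DataFrame with columns rt_s, correct and (if multi-condition)
        condition.
    min_trials : minimum trials required per condition.
    """

    def __init__(self, trials: pd.DataFrame, min_trials: int = 40):
        if "condition" in trials.columns:
            groups = {str(c): g for c, g in trials.groupby("condition", sort=True)}
        else:
            groups = {"all": trials}
        for cond, g in groups.items():
            if len(g) < min_trials:
                raise EstimationError(
                    f"condition {cond!r} has {len(g)} trials; at least {min_trials} required"
                )
            if np.var(g["rt_s"].to_numpy(), ddof=1) <= 1e-12:
                raise EstimationError(f"condition {cond!r} has degenerate RT variance")
        self.conditions = sorted(groups)
        self._rt = {c: groups[c]["rt_s"].to_numpy(float) for c in self.conditions}
        self._correct = {c: groups[c]["correct"].to_numpy() for c in self.conditions}
        self._signed = {
            c: _signed_sorted(self._rt[c], self._correct[c]) for c in self.conditions
        }
        self._min_rt = min(r.min() for r in self._rt.values())

    # objective: trial-weighted mean of per-condition KS statistics
    def _objective(self, theta: np.ndarray) -> float:
        from driftsem._wfpt_fast import ks_statistic_fast

        k = len(self.conditions)
        vs, a, t0, st0 = theta[:k], theta[k], theta[k + 1], theta[k + 2]
        # the support floor t0 - st0/2 must stay below the smallest RT; t0
        # itself may exceed it when st0 is large
        if not (
            _BOUNDS["a"][0] <= a <= _BOUNDS["a"][1]
            and np.all(np.abs(vs) <= _BOUNDS["v"][1])
            and 1e-4 <= t0
            and 0.0 <= st0 <= 2.0 * t0
            and t0 - st0 / 2.0 <= self._min_rt
        ):
            return 2.0 + float(np.sum(np.abs(theta)))
        tot_n = 0
        acc = 0.0
        for i, c in enumerate(self.conditions):
            n = self._signed[c].size
            acc += n * ks_statistic_fast(self._signed[c], vs[i], a, t0, st0, 0.5)
            tot_n += n
        return acc / tot_n

    def fit(
        self,
        n_restarts: int = 5,
        seed: int | None = 0,
        xatol: float = 1e-4,
        maxiter: int | None = None,
        method: str = "nelder-mead",
    ) -> DiffusionFitResult:
        """Minimise the KS criterion.

        method="nelder-mead" (default): multi-start simplex from jittered
        moment-based starting values — fast, adequate for pipeline use.
        method="global": seeded differential evolution with a simplex
        polish — slower but reliably reaches the global optimum, which
        matters for parameter-recovery studies (the KS surface has a flat
        drift/boundary ridge when accuracy is near ceiling).

        ``maxiter`` caps the simplex iterations per start.  A small cap
        (tens of iterations) leaves the estimate close to the moment-based
        start and acts as variance control on the drift/boundary ridge of
        near-ceiling-accuracy data; battery-level measurement uses this
        deliberately (see fit_battery_ddm).
        """
        if method == "global":
            return self._fit_global(seed=seed)
        rng = np.random.default_rng(seed)
        k = len(self.conditions)
        if maxiter is None:
            maxiter = 400 * (k + 3)
        start = []
        for c in self.conditions:
            start.append(ez_starting_values(self._rt[c], self._correct[c]))
        theta0 = np.concatenate(
            [
                [p.v for p in start],
                [np.mean([p.a for p in start])],
                [min(np.mean([p.t0 for p in start]), self._min_rt - 1e-3)],
                [min(np.mean([p.st0 for p in start]), 0.9 * np.mean([p.t0 for p in start]))],
            ]
        )
        best = None
        for r in range(max(1, n_restarts)):
            if r == 0:
                x0 = theta0
            else:
                jitter = rng.normal(0, 1, theta0.size) * np.array([0.5] * k + [0.15, 0.02, 0.02])
                x0 = theta0 + jitter
                x0[k] = np.clip(x0[k], 0.15, 4.8)
                x0[k + 1] = np.clip(x0[k + 1], 2e-3, self._min_rt - 1e-3)
                x0[k + 2] = np.clip(x0[k + 2], 0.0, 1.8 * x0[k + 1])
            res = minimize(
                self._objective,
                x0,
                method="Nelder-Mead",
                options={"xatol": xatol, "fatol": 1e-5, "maxiter": maxiter},
            )
            if best is None or res.fun < best.fun:
                best = res
        vs, a, t0, st0 = best.x[:k], best.x[k], best.x[k + 1], best.x[k + 2]
        st0 = max(0.0, min(st0, 2.0 * t0))
        params = {
            c: DiffusionParams(v=float(vs[i]), a=float(a), t0=float(t0), st0=float(st0))
            for i, c in enumerate(self.conditions)
        }
        diagnostics = {}
        for c, p in params.items():
            kstat = ks_statistic(p, self._rt[c], self._correct[c])
            diagnostics[c] = FitDiagnostics(
                ks_stat=kstat,
                n_trials=self._rt[c].size,
                predicted_quantiles=predicted_rt_quantiles(p),
                predicted_accuracy=hit_probability(p),
                converged=bool(best.success),
            )
        return DiffusionFitResult(
            params=params,
            ks_stat=float(best.fun),
            diagnostics=diagnostics,
            n_trials={c: self._rt[c].size for c in self.conditions},
            converged=bool(best.success),
            n_restarts=max(1, n_restarts),
        )

    def _fit_global(self, seed: int | None = 0) -> DiffusionFitResult:
        from scipy.optimize import differential_evolution

        k = len(self.conditions)
        bounds = (
            [(-10.0, 10.0)] * k
            + [(_BOUNDS["a"][0], _BOUNDS["a"][1])]
            + [(1e-3, self._min_rt + 0.5)]
            + [(0.0, 1.0)]
        )
        res = differential_evolution(
            self._objective,
            bounds,
            seed=None if seed is None else int(seed),
            maxiter=150,
            tol=1e-6,
            polish=True,
            init="sobol",
        )
        vs, a, t0, st0 = res.x[:k], res.x[k], res.x[k + 1], res.x[k + 2]
        st0 = max(0.0, min(st0, 2.0 * t0))
        params = {
            c: DiffusionParams(v=float(vs[i]), a=float(a), t0=float(t0), st0=float(st0))
            for i, c in enumerate(self.conditions)
        }
        diagnostics = {}
        for c, p in params.items():
            diagnostics[c] = FitDiagnostics(
                ks_stat=ks_statistic(p, self._rt[c], self._correct[c]),
                n_trials=self._rt[c].size,
                predicted_quantiles=predicted_rt_quantiles(p),
                predicted_accuracy=hit_probability(p),
                converged=bool(res.success),
            )
        return DiffusionFitResult(
            params=params,
            ks_stat=float(res.fun),
            diagnostics=diagnostics,
            n_trials={c: self._rt[c].size for c in self.conditions},
            converged=bool(res.success),
            n_restarts=1,
        )


def estimate_ks(
    trials: pd.DataFrame,
    n_restarts: int = 5,
    seed: int | None = 0,
    min_trials: int = 40,
) -> DiffusionFitResult:
    """Functional front end to :class:`DiffusionModel`.

    Single-condition tables give one parameter set; tables with a
    ``condition`` column give condition-specific drift with shared
    a, t0, st0.
    """
    return DiffusionModel(trials, min_trials=min_trials).fit(n_restarts=n_restarts, seed=seed)


# ---------------------------------------------------------------------------
# posterior predictive model check
# ---------------------------------------------------------------------------

def predicted_rt_quantiles(
    params: DiffusionParams,
    probs: Sequence[float] = (0.25, 0.5, 0.75),
    grid_size: int = 2048,
) -> np.ndarray:
    """RT quantiles of the model-implied pooled (both-boundary) RT
    distribution, by monotone interpolation of the CDF on a dense grid."""
    from driftsem._wfpt_fast import pooled_cdf_grid

    def total_cdf(t):
        return pooled_cdf_grid(
            np.atleast_1d(np.asarray(t, float)), params.v, params.a,
            params.t0, params.st0, params.zr,
        )

    hi = params.t0 + 1.0
    while float(total_cdf(hi)[0]) < max(probs) + 1e-6 and hi < 300.0:
        hi *= 2.0
    grid = np.linspace(params.t_floor, hi, grid_size)
    cdf = total_cdf(grid)
    return np.interp(np.asarray(probs, float), cdf, grid)


def model_check(
    trials_by_participant: Mapping[str, pd.DataFrame],
    params_by_participant: Mapping[str, DiffusionParams],
    probs: Sequence[float] = (0.25, 0.5, 0.75),
) -> pd.DataFrame:
    """Observed-vs-predicted correlations across participants.

    For each participant, observed RT quantiles and accuracy are compared
    with the model-implied quantiles (CDF inversion) and hit probability;
    one Pearson correlation per statistic is returned.  Zero-variance
    series yield NaN with ``defined=False`` rather than being dropped.
    """
    ids = sorted(set(trials_by_participant) & set(params_by_participant))
    if len(ids) < 3:
        raise ValueError("model_check requires at least 3 participants")
    obs_q, pred_q, obs_acc, pred_acc = [], [], [], []
    for pid in ids:
        tr = trials_by_participant[pid]
        rt = tr["rt_s"].to_numpy(float)
        obs_q.append(np.quantile(rt, probs))
        obs_acc.append(tr["correct"].mean())
        p = params_by_participant[pid]
        pred_q.append(predicted_rt_quantiles(p, probs))
        pred_acc.append(hit_probability(p))
    obs_q = np.asarray(obs_q)
    pred_q = np.asarray(pred_q)
    rows = []
    for j, p in enumerate(probs):
        rows.append(_corr_row(f"rt_q{int(p * 100)}", obs_q[:, j], pred_q[:, j]))
    rows.append(_corr_row("accuracy", np.asarray(obs_acc), np.asarray(pred_acc)))
    return pd.DataFrame(rows)


def _corr_row(name: str, obs: np.ndarray, pred: np.ndarray) -> dict:
    s_o, s_p = np.std(obs), np.std(pred)
    if s_o < 1e-12 or s_p < 1e-12:
        return {"statistic": name, "r": np.nan, "defined": False}
    r = float(np.corrcoef(obs, pred)[0, 1])
    return {"statistic": name, "r": r, "defined": True}
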