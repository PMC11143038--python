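"""Power analysis for the RMSEA test of close fit.

The test contrasts H0: population RMSEA <= eps0 against H1: RMSEA >= eps1
using noncentral chi-square distributions with noncentrality
lambda = (N - 1) * df * eps^2 (the N-1 convention of MacCallum, Browne &
Sugawara).  Power at the alternative is the probability mass of the H1
distribution beyond the 1-alpha quantile of the H0 distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import ncx2

__all__ = ["PowerSpec", "power_close_fit", "min_n_close_fit"]


@dataclass(frozen=True)
class PowerSpec:
    df: int
    n: int
    eps0: float = 0.05
    eps1: float = 0.08
    alpha: float = 0.05

    def __post_init__(self):
        if not (0 <= self.eps0 <= self.eps1):
            raise ValueError("need 0 <= eps0 <= eps1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.df < 1 or self.n < 2:
            raise ValueError("need df >= 1 and n >= 2")


def power_close_fit(
    df: int, n: int, eps0: float = 0.05, eps1: float = 0.08, alpha: float = 0.05
) -> float:
    """Power of the close-fit test; equals alpha exactly when eps1 == eps0."""
    spec = PowerSpec(df=df, n=n, eps0=eps0, eps1=eps1, alpha=alpha)
    lam0 = (spec.n - 1) * spec.df * spec.eps0**2
    lam1 = (spec.n - 1) * spec.df * spec.eps1**2
    crit = ncx2.ppf(1.0 - spec.alpha, spec.df, lam0)
    return float(ncx2.sf(crit, spec.df, lam1))


def min_n_close_fit(
    df: int,
    eps0: float = 0.05,
    eps1: float = 0.08,
    alpha: float = 0.05,
    target_power: float = 0.80,
    n_max: int = 1_000_000,
) -> int:
    """Smallest integer N whose close-fit power reaches ``target_power``.

    Bisection over N; power is monotone increasing in N.
    """
    if not alpha < target_power < 1:
        raise ValueError("target power must lie in (alpha, 1)")
    if eps1 <= eps0:
        raise ValueError("eps1 must exceed eps0 for a nontrivial requirement")
    lo, hi = 2, 4
    while power_close_fit(df, hi, eps0, eps1, alpha) < target_power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError("target power unreachable below n_max")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_close_fit(df, mid, eps0, eps1, alpha) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi
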