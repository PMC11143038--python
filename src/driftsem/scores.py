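"""Person-level measurement scores and their reliabilities.

Two scoring families coexist in the pipeline:

* heterogeneous scores — RT difference scores (demanding - baseline),
  mean RTs of the demanding condition, and arcsine-transformed proportion
  correct, mirroring the traditional mixed RT/accuracy scoring of
  executive-function batteries;
* homogeneous scores — drift rates estimated per condition, and their
  difference scores.

Reliability comes as Spearman-Brown-corrected odd-even split-half
correlations for trial-based scores and Cronbach's alpha for item scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "ReliabilityEstimate",
    "condition_mean_rt",
    "difference_score",
    "arcsine_accuracy",
    "spearman_brown",
    "split_half_reliability",
    "cronbach_alpha",
    "composite_zscore",
    "wmc_scores",
    "pairwise_correlations",
]


@dataclass
class ReliabilityEstimate:
    variable: str
    method: str  # spearman_brown_odd_even | cronbach_alpha
    value: float  # inadmissible (< 0) values are reported as-is, never clipped
    n: int


def condition_mean_rt(trials: pd.DataFrame, correct_only: bool = True) -> pd.Series:
    """Mean RT per participant (seconds); error trials excluded by default.

    Participants with no (correct) trials get NaN.
    """
    t = trials[trials["correct"] > 0] if correct_only else trials
    out = t.groupby("participant")["rt_s"].mean()
    return out.reindex(trials["participant"].unique())


def difference_score(
    demanding: pd.Series, baseline: pd.Series, sign: str = "demanding_minus_baseline"
) -> pd.Series:
    """Per-person condition contrast; missing if either side is missing.

    For RTs the (default) convention demanding - baseline makes the cost
    positive; drift differences typically use baseline - demanding so that
    a larger value again means a larger demand effect.
    """
    idx = demanding.index.union(baseline.index)
    d = demanding.reindex(idx).astype(float)
    b = baseline.reindex(idx).astype(float)
    if sign == "demanding_minus_baseline":
        return d - b
    if sign == "baseline_minus_demanding":
        return b - d
    raise ValueError(f"unknown sign convention {sign!r}")


def arcsine_accuracy(p) -> np.ndarray | float:
    """Variance-stabilising arcsine transform asin(sqrt(p)), in radians.

    Applied at the finest block level available and then averaged per
    person; the transform is convex above p = 0.5, so block-level averages
    exceed the transform of the pooled proportion.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return out if np.ndim(p) else float(out)


def spearman_brown(r: float) -> float:
    """Project a half-test correlation to full length: 2r / (1 + r)."""
    return 2.0 * r / (1.0 + r)


def split_half_reliability(
    trials: pd.DataFrame,
    scoring_fn: Callable[[pd.DataFrame], pd.Series],
    variable: str = "score",
) -> ReliabilityEstimate:
    """Spearman-Brown-corrected odd-even split-half reliability.

    Trials are split by the parity of ``trial_index`` within each
    participant x condition; ``scoring_fn`` maps each half to a person
    score (mean RT, drift rate, arcsine accuracy, ...); the two half
    scores are correlated across persons and stepped up with 2r/(1+r).
    """
    parity = trials["trial_index"].to_numpy() % 2
    halves = []
    for p in (1, 0):  # odd, even
        half = trials.loc[parity == p]
        halves.append(scoring_fn(half))
    a, b = halves
    both = pd.concat([a.rename("odd"), b.rename("even")], axis=1).dropna()
    if len(both) < 3 or both["odd"].std() == 0 or both["even"].std() == 0:
        warnings.warn(f"{variable}: split-half correlation undefined")
        return ReliabilityEstimate(variable, "spearman_brown_odd_even", np.nan, len(both))
    r = float(both["odd"].corr(both["even"]))
    return ReliabilityEstimate(variable, "spearman_brown_odd_even", spearman_brown(r), len(both))


def cronbach_alpha(items: pd.DataFrame, variable: str = "scale") -> ReliabilityEstimate:
    """Cronbach's alpha, k/(k-1) * (1 - sum(item var) / var(total)).

    Rows with any missing item are dropped (listwise).
    """
    x = items.dropna()
    k = x.shape[1]
    if k < 2:
        raise ValueError("alpha requires at least 2 items")
    total_var = x.sum(axis=1).var(ddof=1)
    if not np.isfinite(total_var) or total_var <= 0:
        warnings.warn(f"{variable}: zero total variance")
        return ReliabilityEstimate(variable, "cronbach_alpha", np.nan, len(x))
    item_var = x.var(ddof=1).sum()
    alpha = k / (k - 1.0) * (1.0 - item_var / total_var)
    return ReliabilityEstimate(variable, "cronbach_alpha", float(alpha), len(x))


def composite_zscore(subtests: pd.DataFrame, grouping: dict[str, list[str]]) -> pd.DataFrame:
    """Aggregate column-standardised subtests into component scores.

    ``grouping`` maps component name -> list of subtest columns; each
    component is the mean of the z-scored subtests assigned to it
    (NaN-aware; a person with all subtests of a component missing gets
    NaN for that component).
    """
    z = (subtests - subtests.mean()) / subtests.std(ddof=1)
    out = {}
    for comp, cols in grouping.items():
        missing = [c for c in cols if c not in subtests.columns]
        if missing:
            raise KeyError(f"component {comp!r}: unknown subtests {missing}")
        out[comp] = z[cols].mean(axis=1)
    return pd.DataFrame(out)


def wmc_scores(responses: pd.DataFrame) -> pd.Series:
    """Working-memory task score: mean proportion correct per set size,
    then the mean across set sizes.

    ``responses`` needs columns participant, set_size, correct.  Set sizes
    missing for a person are excluded from that person's average with a
    warning.
    """
    per_size = (
        responses.groupby(["participant", "set_size"])["correct"].mean().unstack("set_size")
    )
    if per_size.isna().any().any():
        warnings.warn("some participants are missing whole set sizes; averaging the rest")
    return per_size.mean(axis=1, skipna=True)


def pairwise_correlations(score_table: pd.DataFrame, min_n: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with per-pair n.

    Cells with fewer than ``min_n`` complete pairs are set to NaN.
    """
    r = score_table.corr(method="pearson", min_periods=min_n)
    notna = score_table.notna().astype(int)
    n = notna.T @ notna
    return r, n
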