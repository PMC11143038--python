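"""Outlier handling for trial-level two-choice RT data.

The cleaning protocol is fixed and auditable, in this order:

1. discard responses faster than 150 ms (strictly faster; 150 ms is kept);
2. within each participant x condition, log-transform RTs, z-standardise
   (sample SD, n-1), and drop trials with |z| > 3 — one pass, no iteration;
3. participant-level checks per task condition: exclusion below the exact
   binomial guessing threshold, and mean-RT / empirical-logit-accuracy
   values deviating more than 3 SD from the sample average;
4. person-level derived scores beyond 3 SD are set missing (the model
   stage handles missingness), not deleted row-wise.

Every removal is logged in an :class:`ExclusionReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "ExclusionReport",
    "filter_fast_trials",
    "trim_rt_outliers_logz",
    "min_correct_threshold",
    "exclude_participants_3sd",
    "trim_scores_3sd",
    "preprocess_trials",
]

MIN_RT_S = 0.150


@dataclass
class ExclusionReport:
    """Book-keeping for every removal decision.

    trial_log : one row per (participant, task, condition) with counts of
        trials removed by the fast filter and the log-z trim.
    participant_log : one row per excluded participant x variable with a
        single reason code in {below_guessing, rt_3sd, logit_acc_3sd,
        score_3sd}.
    """

    _trial_rows: list = field(default_factory=list)
    _participant_rows: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    _TRIAL_COLS = (
        "participant", "task", "condition",
        "n_input", "n_removed_fast", "n_removed_z", "removal_fraction",
    )
    _PART_COLS = ("participant", "task", "condition", "variable", "reason")

    @property
    def trial_log(self) -> pd.DataFrame:
        return pd.DataFrame(self._trial_rows, columns=list(self._TRIAL_COLS))

    @property
    def participant_log(self) -> pd.DataFrame:
        return pd.DataFrame(self._participant_rows, columns=list(self._PART_COLS))

    def add_trials(self, keys, n_input, n_fast, n_z) -> None:
        row = dict(zip(["participant", "task", "condition"], keys))
        row.update(
            n_input=n_input,
            n_removed_fast=n_fast,
            n_removed_z=n_z,
            removal_fraction=(n_fast + n_z) / n_input if n_input else 0.0,
        )
        self._trial_rows.append(row)

    def add_participant(self, participant, task, condition, variable, reason) -> None:
        self._participant_rows.append(
            dict(participant=participant, task=task, condition=condition,
                 variable=variable, reason=reason)
        )


def filter_fast_trials(
    trials: pd.DataFrame, min_rt: float = MIN_RT_S, report: ExclusionReport | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop trials with rt strictly below ``min_rt`` (default 150 ms)."""
    report = report or ExclusionReport()
    if trials.empty:
        warnings.warn("filter_fast_trials: empty input")
        return trials.copy(), report
    keep = trials["rt_s"] >= min_rt
    out = trials.loc[keep].copy()
    if out.empty:
        report.flags.append("all_trials_below_fast_threshold")
    return out, report


def trim_rt_outliers_logz(
    trials: pd.DataFrame,
    z_limit: float = 3.0,
    group_cols: tuple = ("participant", "task", "condition"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass removal of trials with |z(log rt)| > ``z_limit``.

    The z-transform is computed once per participant x condition with the
    sample SD (n-1).  Groups with fewer than 3 trials, or zero log-RT
    variance, are left untouched.
    """
    if trials.empty:
        warnings.warn("trim_rt_outliers_logz: empty input")
        return trials.copy(), pd.DataFrame(columns=[*group_cols, "n_removed"])
    cols = [c for c in group_cols if c in trials.columns]
    kept_parts, log_rows = [], []
    for keys, g in trials.groupby(cols, sort=False):
        logs = np.log(g["rt_s"].to_numpy(float))
        if len(g) < 3:
            warnings.warn(f"group {keys}: fewer than 3 trials, no trimming")
            kept_parts.append(g)
            log_rows.append((*np.atleast_1d(keys), 0))
            continue
        sd = logs.std(ddof=1)
        if sd <= 0:
            kept_parts.append(g)
            log_rows.append((*np.atleast_1d(keys), 0))
            continue
        z = (logs - logs.mean()) / sd
        keep = np.abs(z) <= z_limit
        kept_parts.append(g.loc[keep])
        log_rows.append((*np.atleast_1d(keys), int((~keep).sum())))
    out = pd.concat(kept_parts).sort_index()
    log = pd.DataFrame(log_rows, columns=[*cols, "n_removed"])
    return out, log


def min_correct_threshold(n_trials: int, n_alternatives: int, alpha: float = 0.05) -> int:
    """Smallest correct count c with P(X >= c) <= alpha under guessing.

    X ~ Binomial(n_trials, 1/n_alternatives).  Participants whose correct
    count falls below c cannot be distinguished from guessing at level
    ``alpha`` and are excluded.
    """
    if n_trials < 1 or n_alternatives < 2:
        raise ValueError("need n_trials >= 1 and n_alternatives >= 2")
    p = 1.0 / n_alternatives
    # P(X >= c) = sf(c - 1); find smallest c in 0..n_trials+1
    cs = np.arange(0, n_trials + 2)
    tail = binom.sf(cs - 1, n_trials, p)
    ok = np.nonzero(tail <= alpha)[0]
    c = int(cs[ok[0]])
    if c > n_trials:
        warnings.warn(
            "guessing threshold exceeds the trial count; condition untestable at this alpha"
        )
    return c


def _empirical_logit(correct_count: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Logit of the smoothed proportion (x + 0.5) / (n + 1); finite at 0 and 1."""
    p = (correct_count + 0.5) / (n + 1.0)
    return np.log(p / (1.0 - p))


def exclude_participants_3sd(
    scores: pd.Series,
    transform: str = "none",
    sd_limit: float = 3.0,
    counts: pd.Series | None = None,
) -> tuple[pd.Series, pd.Index]:
    """Exclude persons whose score deviates > ``sd_limit`` SD from the mean.

    ``transform='logit'`` applies the empirical logit to accuracy
    proportions (requires ``counts``, the per-person trial counts).
    Returns the retained scores and the excluded index.  A zero-SD sample
    excludes nobody.
    """
    x = scores.astype(float)
    if transform == "logit":
        if counts is None:
            raise ValueError("logit transform requires per-person trial counts")
        x = pd.Series(
            _empirical_logit(
                (scores * counts).round().to_numpy(float), counts.to_numpy(float)
            ),
            index=scores.index,
        )
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd <= 0:
        return scores, pd.Index([])
    dev = (x - x.mean()).abs() / sd
    excluded = x.index[dev > sd_limit]
    return scores.drop(excluded), excluded


def trim_scores_3sd(scores: pd.Series, sd_limit: float = 3.0) -> pd.Series:
    """Set values beyond ``sd_limit`` sample SDs to missing (length kept).

    Single pass: the mean/SD are computed once on the input, so a second
    application may remove more — callers must not iterate.
    """
    x = scores.astype(float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd <= 0:
        return x
    out = x.copy()
    out[(x - x.mean()).abs() / sd > sd_limit] = np.nan
    return out


_PREPROCESSED_FLAG = "__driftsem_preprocessed__"


def preprocess_trials(
    trials: pd.DataFrame,
    n_alternatives: dict | int = 2,
    alpha: float = 0.05,
    min_rt: float = MIN_RT_S,
    z_limit: float = 3.0,
    sd_limit: float = 3.0,
    min_participants_for_3sd: int = 10,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Full trial-level pipeline: fast filter -> log-z trim -> participant checks.

    ``n_alternatives`` may be a single integer or a mapping from task name
    to response-alternative count (tasks with four response keys keep their
    four-alternative guessing threshold even though responses are coded
    binary).  Participant exclusions apply per task: all of an excluded
    participant's trials in that task are dropped.
    """
    if trials.attrs.get(_PREPROCESSED_FLAG):
        raise ValueError(
            "input already preprocessed; the trimming rules are single-pass "
            "and must not be applied twice"
        )
    report = ExclusionReport()
    step1, report = filter_fast_trials(trials, min_rt=min_rt, report=report)
    n_fast = (
        trials.groupby(["participant", "task", "condition"]).size()
        - step1.groupby(["participant", "task", "condition"]).size().reindex(
            trials.groupby(["participant", "task", "condition"]).size().index, fill_value=0
        )
    )
    step2, zlog = trim_rt_outliers_logz(step1, z_limit=z_limit)
    n_in = trials.groupby(["participant", "task", "condition"]).size()
    zlog = zlog.set_index(["participant", "task", "condition"])["n_removed"]
    for keys in n_in.index:
        report.add_trials(
            keys,
            int(n_in.loc[keys]),
            int(n_fast.get(keys, 0)),
            int(zlog.get(keys, 0)),
        )

    # participant-level checks per task x condition
    drop_pairs: set = set()
    for (task, cond), g in step2.groupby(["task", "condition"]):
        n_alt = n_alternatives.get(task, 2) if isinstance(n_alternatives, dict) else n_alternatives
        per = g.groupby("participant").agg(
            n=("correct", "size"), n_corr=("correct", "sum"), mean_rt=("rt_s", "mean"),
            acc=("correct", "mean"),
        )
        for pid, row in per.iterrows():
            thr = min_correct_threshold(int(row["n"]), n_alt, alpha)
            if row["n_corr"] < thr:
                drop_pairs.add((pid, task))
                report.add_participant(pid, task, cond, "accuracy", "below_guessing")
        if len(per) >= min_participants_for_3sd:
            _, exc_rt = exclude_participants_3sd(per["mean_rt"], "none", sd_limit)
            for pid in exc_rt:
                drop_pairs.add((pid, task))
                report.add_participant(pid, task, cond, "mean_rt", "rt_3sd")
            _, exc_acc = exclude_participants_3sd(
                per["acc"], "logit", sd_limit, counts=per["n"]
            )
            for pid in exc_acc:
                drop_pairs.add((pid, task))
                report.add_participant(pid, task, cond, "accuracy", "logit_acc_3sd")

    if drop_pairs:
        mask = ~step2.set_index(["participant", "task"]).index.isin(drop_pairs)
        step2 = step2.loc[mask]
    out = step2.reset_index(drop=True)
    out.attrs[_PREPROCESSED_FLAG] = True
    return out, report
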