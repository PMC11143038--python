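"""Synthetic two-choice RT batteries with a known latent structure.

The generator emulates a 12-task battery (3 inhibition, 3 updating,
3 shifting, 3 elementary-speed tasks), each task with a lower- and a
greater-demand condition (speed tasks: one condition), at the trial counts
of the study design it mirrors.  Person-level drift rates arise from a
linear-Gaussian latent structure:

    common EF  c = beta * s + zeta,          zeta ~ N(0, ef_residual_var)
    domain     f_d = c + delta_d,            delta_d ~ N(0, domain_var)
    drift      v(p,t,cond) = mu_{t,cond} + lambda_t * F_t(p) + e_{p,t} + eps_{p,t,cond}

where s is the task-general speed factor (it also drives the three
elementary tasks directly), e is stable task-specific person variance and
eps a small person x condition interaction.  Working-memory-capacity and
intelligence scores are generated from latent criteria correlated with s.

Defaults are calibrated to the descriptive statistics of the study the
package models: task-mean drifts and their person SDs, criterion
correlations (speed-intelligence 0.46, speed-WMC 0.46, WMC-intelligence
0.76) and trial counts.  With the default beta = 1 and zero EF-specific
variance, the common EF factor coincides with speed — the configuration
whose recovery the end-to-end tests probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ddm import DiffusionParams, sample_first_passage

__all__ = [
    "TaskSpec",
    "GeneratorConfig",
    "GroundTruth",
    "default_battery",
    "default_config",
    "miniature_config",
    "generate_population",
    "generate_trial_data",
    "generate_criterion_scores",
    "generate_battery",
]


@dataclass(frozen=True)
class TaskSpec:
    """One task of the battery.

    mean_v_demanding / sd_v are calibrated to the drift descriptives of
    the modelled study (greater-demand condition); reliability informs how
    much of the printed SD is treated as true person variance.
    """

    name: str
    domain: str  # inhibition | updating | shifting | speed
    n_trials_per_condition: int
    mean_v_demanding: float
    sd_v: float
    reliability: float
    n_alternatives: int = 2
    t0_mean: float = 0.45
    a_mean: float = 1.1
    two_condition: bool = True

    @property
    def true_sd_v(self) -> float:
        """Person SD of true drift: printed SD shrunk by the reliability."""
        return self.sd_v * np.sqrt(max(self.reliability, 0.0))


def default_battery() -> list[TaskSpec]:
    """The 12-task battery at the modelled study's experimental trial
    counts (split equally over the two conditions where applicable)."""
    rows = [
        # name, domain, n/cond, mean v (demanding), sd v, reliability, alts, t0
        ("stroop", "inhibition", 96, 2.60, 0.74, 0.48, 4, 0.62),
        ("flanker", "inhibition", 100, 5.05, 1.32, 0.57, 2, 0.38),
        ("neg_priming", "inhibition", 96, 3.62, 0.94, 0.47, 4, 0.45),
        ("keep_track", "updating", 96, 1.69, 0.62, 0.81, 2, 0.50),
        ("running_span", "updating", 120, 1.78, 0.58, 0.67, 2, 0.50),
        ("n_back", "updating", 96, 1.74, 0.46, 0.83, 2, 0.45),
        ("switching", "shifting", 192, 2.16, 0.85, 0.90, 2, 0.50),
        ("number_letter", "shifting", 128, 2.29, 0.92, 0.89, 2, 0.55),
        ("global_local", "shifting", 192, 1.65, 0.51, 0.79, 4, 0.50),
        ("two_choice", "speed", 100, 6.25, 1.58, 0.70, 2, 0.28),
        ("sternberg", "speed", 100, 2.35, 0.71, 0.45, 2, 0.62),
        ("posner", "speed", 120, 3.27, 0.74, 0.53, 2, 0.48),
    ]
    return [
        TaskSpec(
            name=n, domain=d, n_trials_per_condition=nt, mean_v_demanding=mv,
            sd_v=sv, reliability=rel, n_alternatives=alt, t0_mean=t0,
            two_condition=(d != "speed"),
        )
        for (n, d, nt, mv, sv, rel, alt, t0) in rows
    ]


@dataclass(frozen=True)
class GeneratorConfig:
    """Latent structure and measurement distributions of the battery."""

    n_participants: int = 148
    battery: tuple = field(default_factory=lambda: tuple(default_battery()))
    # latent structure
    beta_ef_on_speed: float = 1.0
    ef_residual_var: float = 0.0  # variance of the EF disturbance zeta
    domain_specific_var: float = 0.0  # variance of delta per EF domain
    # variance partition of true drift (fractions of true task variance)
    frac_general: float = 0.6
    frac_task_specific: float = 0.3
    frac_condition_interaction: float = 0.1
    # condition structure: baseline drift = demanding + offset
    baseline_drift_offset: float = 1.0
    # measurement parameter dispersion (log-scale SDs)
    a_log_sd: float = 0.10
    t0_log_sd: float = 0.10
    st0_range: tuple = (0.10, 0.20)
    # criterion structure
    r_speed_wmc: float = 0.46
    r_speed_gf: float = 0.46
    r_wmc_gf: float = 0.76
    criterion_loading: float = 0.80
    n_missing_binding: int = 5
    # trial contamination (uniform fast guesses)
    contamination_rate: float = 0.0
    seed: int = 0

    def latent_corr(self) -> np.ndarray:
        R = np.array(
            [
                [1.0, self.r_speed_wmc, self.r_speed_gf],
                [self.r_speed_wmc, 1.0, self.r_wmc_gf],
                [self.r_speed_gf, self.r_wmc_gf, 1.0],
            ]
        )
        if np.any(np.linalg.eigvalsh(R) < -1e-10):
            raise ValueError("criterion correlation matrix not positive semi-definite")
        return R


def default_config(**overrides) -> GeneratorConfig:
    return GeneratorConfig(**overrides)


def miniature_config(**overrides) -> GeneratorConfig:
    """Fixture-scale battery: 12 participants, 48 trials per condition."""
    mini = tuple(
        replace(t, n_trials_per_condition=48) for t in default_battery()
    )
    kw = dict(n_participants=12, battery=mini)
    kw.update(overrides)
    return GeneratorConfig(**kw)


@dataclass
class GroundTruth:
    """Everything needed to score recovery against the generator."""

    latents: pd.DataFrame  # person x {speed, common_ef, wmc, intelligence, f_<domain>}
    drift_params: pd.DataFrame  # person x task x condition true DiffusionParams fields
    config: GeneratorConfig

    def to_json(self) -> str:
        import json

        return json.dumps(
            dict(
                latents=self.latents.to_dict(orient="list"),
                drift_params=self.drift_params.to_dict(orient="list"),
                n_participants=self.config.n_participants,
                seed=self.config.seed,
            )
        )


def _participant_ids(n: int) -> list:
    width = len(str(n))
    return [f"p{str(i + 1).zfill(width)}" for i in range(n)]


def generate_population(config: GeneratorConfig, seed: int | None = None) -> GroundTruth:
    """Draw persons: latent scores and true diffusion parameters per
    task x condition."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_participants
    pids = _participant_ids(n)

    R = config.latent_corr()
    chol = np.linalg.cholesky(R)
    z = rng.standard_normal((n, 3)) @ chol.T
    speed, wmc, gf = z[:, 0], z[:, 1], z[:, 2]
    zeta = rng.standard_normal(n) * np.sqrt(config.ef_residual_var)
    common_ef = config.beta_ef_on_speed * speed + zeta

    lat = {"speed": speed, "wmc": wmc, "intelligence": gf, "common_ef": common_ef}
    for d in ("inhibition", "updating", "shifting"):
        delta = rng.standard_normal(n) * np.sqrt(config.domain_specific_var)
        lat[f"f_{d}"] = common_ef + delta
    latents = pd.DataFrame(lat, index=pids)
    latents.index.name = "participant"

    rows = []
    for task in config.battery:
        factor = latents["speed"] if task.domain == "speed" else latents[f"f_{task.domain}"]
        sd_true = task.true_sd_v
        # normalise the factor contribution so total true variance matches
        lam = np.sqrt(config.frac_general) * sd_true / max(factor.std(ddof=0), 1e-9)
        e_task = rng.standard_normal(n) * np.sqrt(config.frac_task_specific) * sd_true
        a_p = np.exp(rng.normal(np.log(task.a_mean), config.a_log_sd, n))
        t0_p = np.exp(rng.normal(np.log(task.t0_mean), config.t0_log_sd, n))
        st0_p = rng.uniform(*config.st0_range, n)
        st0_p = np.minimum(st0_p, 1.8 * t0_p)
        conditions = ["demanding", "baseline"] if task.two_condition else ["single"]
        for cond in conditions:
            mu = task.mean_v_demanding
            if cond == "baseline":
                mu += config.baseline_drift_offset
            eps = rng.standard_normal(n) * np.sqrt(config.frac_condition_interaction) * sd_true
            v = mu + lam * factor.to_numpy() + e_task + eps
            v = np.clip(v, 0.05, 9.5)
            for i, pid in enumerate(pids):
                rows.append(
                    dict(
                        participant=pid, task=task.name, condition=cond,
                        v=v[i], a=a_p[i], t0=t0_p[i], st0=st0_p[i],
                    )
                )
    drift_params = pd.DataFrame(rows)
    return GroundTruth(latents=latents, drift_params=drift_params, config=config)


def generate_trial_data(
    truth: GroundTruth, seed: int | None = None
) -> pd.DataFrame:
    """Simulate the full battery's trials from the persons' true parameters.

    An optional contamination process replaces a configured fraction of
    trials with uniform fast guesses (rt < 150 ms, chance accuracy) to
    exercise the preprocessing stage.
    """
    config = truth.config
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    n_per = {t.name: t.n_trials_per_condition for t in config.battery}
    frames = []
    for row in truth.drift_params.itertuples(index=False):
        params = DiffusionParams(v=row.v, a=row.a, t0=row.t0, st0=row.st0)
        n_tr = n_per[row.task]
        rt, correct = sample_first_passage(params, n_tr, rng)
        if config.contamination_rate > 0:
            bad = rng.random(n_tr) < config.contamination_rate
            rt[bad] = rng.uniform(0.01, 0.149, bad.sum())
            correct[bad] = rng.integers(0, 2, bad.sum())
        frames.append(
            pd.DataFrame(
                dict(
                    participant=row.participant, task=row.task, condition=row.condition,
                    trial_index=np.arange(n_tr), rt_s=rt, correct=correct,
                )
            )
        )
    return pd.concat(frames, ignore_index=True)


_WMC_SCALES = {
    # indicator: (mean percent correct, SD) per the modelled descriptives
    "memory_updating": (63.0, 20.0),
    "binding": (86.0, 11.0),
    "operation_span": (78.0, 13.0),
    "sentence_span": (84.0, 11.0),
}
_BIS_SCALES = {
    "bis_pc": (101.6, 7.12),
    "bis_ps": (101.1, 7.15),
    "bis_m": (98.6, 7.16),
    "bis_c": (98.2, 6.97),
}


def generate_criterion_scores(
    truth: GroundTruth, seed: int | None = None
) -> pd.DataFrame:
    """WMC indicators (4) and intelligence components (4) from the latent
    criteria, each with standardized loading ``criterion_loading``; a few
    persons miss the binding indicator, mirroring incomplete criterion
    data."""
    config = truth.config
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    lam = config.criterion_loading
    noise_sd = np.sqrt(1.0 - lam**2)
    out = {}
    for name, (mean, sd) in _WMC_SCALES.items():
        z = lam * truth.latents["wmc"] + noise_sd * rng.standard_normal(len(truth.latents))
        out[name] = np.clip(mean + sd * z, 0.0, 100.0)
    for name, (mean, sd) in _BIS_SCALES.items():
        z = lam * truth.latents["intelligence"] + noise_sd * rng.standard_normal(len(truth.latents))
        out[name] = mean + sd * z
    scores = pd.DataFrame(out, index=truth.latents.index)
    if config.n_missing_binding > 0:
        miss = rng.choice(
            scores.index, size=min(config.n_missing_binding, len(scores)), replace=False
        )
        scores.loc[miss, "binding"] = np.nan
    return scores


def generate_battery(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Convenience wrapper: population -> trials + criterion scores."""
    config = config or default_config()
    truth = generate_population(config, seed)
    trials = generate_trial_data(truth, seed)
    criteria = generate_criterion_scores(truth, seed)
    return trials, criteria, truth
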