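"""The ladder of latent-variable models for executive-function batteries.

Every model takes nine executive-function (EF) indicators grouped 3/3/3
into inhibition, updating and shifting; the later models add a
task-general speed factor (3 elementary-task indicators), a
working-memory-capacity factor (4 indicators) and a fluid-intelligence
factor (4 component scores).

Scale setting throughout: the first loading of each factor is fixed to 1
and the factor variance is estimated.  Options expose the constraint
patterns the ladder needs: fixing first-order residual variances to zero
(which makes the higher-order model equivalent to the one-factor model),
fixing the EF disturbance to zero in the speed-regression models, an
equality constraint on the inhibition loadings for difference-score
indicators, and a residual covariance between the two verbal complex-span
working-memory indicators in the criteria models.
"""

from __future__ import annotations

from .engine import FREE, ModelSpec

__all__ = ["build_model", "MODEL_NAMES", "default_variable_map"]

MODEL_NAMES = (
    "three_factor",
    "three_factor_higher_order",
    "one_factor",
    "one_factor_plus_criteria",
    "speed_regression",
    "speed_regression_plus_criteria",
)

EF_DOMAINS = ("inhibition", "updating", "shifting")


def default_variable_map() -> dict:
    """Task-name layout used by the synthetic battery and the pipeline."""
    return dict(
        inhibition=["stroop", "flanker", "neg_priming"],
        updating=["keep_track", "running_span", "n_back"],
        shifting=["switching", "number_letter", "global_local"],
        speed=["two_choice", "sternberg", "posner"],
        wmc=["memory_updating", "operation_span", "sentence_span", "binding"],
        intelligence=["bis_pc", "bis_ps", "bis_m", "bis_c"],
    )


def _add_factor(spec: ModelSpec, latent: str, indicators, first_fixed=1.0, all_fixed=None):
    for i, obs in enumerate(indicators):
        if all_fixed is not None:
            spec.loadings[(obs, latent)] = all_fixed
        else:
            spec.loadings[(obs, latent)] = first_fixed if i == 0 else FREE
    spec.latent_cov[(latent, latent)] = FREE


def _check(variable_map: dict, keys) -> None:
    counts = dict(inhibition=3, updating=3, shifting=3, speed=3, wmc=4, intelligence=4)
    for key in keys:
        got = variable_map.get(key)
        if got is None or len(got) != counts[key]:
            raise ValueError(
                f"variable map needs exactly {counts[key]} indicators for {key!r}"
            )


def build_model(
    name: str,
    variable_map: dict | None = None,
    equal_inhibition_loadings: bool = False,
    zero_first_order_residuals: bool = False,
    zero_ef_residual: bool = False,
    span_residual_covariance: bool = True,
) -> ModelSpec:
    """Construct one of the ladder's model specifications.

    Parameters
    ----------
    name : one of ``MODEL_NAMES``.
    variable_map : domain -> indicator columns; defaults to the synthetic
        battery layout.
    equal_inhibition_loadings : constrain the three inhibition loadings to
        equality (all fixed to the scaling value 1); used with
        difference-score indicators, which share a scale.
    zero_first_order_residuals : higher-order variant with the three
        first-order residual variances fixed to 0 (equivalent to the
        one-factor model).
    zero_ef_residual : speed-regression variants with the EF disturbance
        fixed to 0 (EF fully explained by speed).
    span_residual_covariance : criteria models free the residual
        covariance between the two verbal complex-span WMC indicators.
    """
    vm = variable_map or default_variable_map()
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")

    spec = ModelSpec(name=name, observed=[], latents=[])

    def use(domains):
        for d in domains:
            spec.observed.extend(vm[d])

    if name == "three_factor":
        _check(vm, EF_DOMAINS)
        use(EF_DOMAINS)
        spec.latents = list(EF_DOMAINS)
        for d in EF_DOMAINS:
            if d == "inhibition" and equal_inhibition_loadings:
                _add_factor(spec, d, vm[d], all_fixed=1.0)
            else:
                _add_factor(spec, d, vm[d])
        for i, a in enumerate(EF_DOMAINS):
            for b in EF_DOMAINS[i + 1:]:
                spec.latent_cov[(a, b)] = FREE

    elif name == "three_factor_higher_order":
        _check(vm, EF_DOMAINS)
        use(EF_DOMAINS)
        spec.latents = [*EF_DOMAINS, "common_ef"]
        for d in EF_DOMAINS:
            for i, obs in enumerate(vm[d]):
                spec.loadings[(obs, d)] = 1.0 if i == 0 else FREE
            spec.latent_cov[(d, d)] = 0.0 if zero_first_order_residuals else FREE
        for i, d in enumerate(EF_DOMAINS):
            spec.regressions[(d, "common_ef")] = 1.0 if i == 0 else FREE
        spec.latent_cov[("common_ef", "common_ef")] = FREE

    elif name in ("one_factor", "one_factor_plus_criteria"):
        _check(vm, EF_DOMAINS)
        use(EF_DOMAINS)
        spec.latents = ["common_ef"]
        _add_factor(spec, "common_ef", [o for d in EF_DOMAINS for o in vm[d]])
        if name == "one_factor_plus_criteria":
            _check(vm, ("wmc", "intelligence"))
            use(("wmc", "intelligence"))
            spec.latents += ["wmc", "intelligence"]
            _add_factor(spec, "wmc", vm["wmc"])
            _add_factor(spec, "intelligence", vm["intelligence"])
            for a, b in (
                ("common_ef", "wmc"),
                ("common_ef", "intelligence"),
                ("wmc", "intelligence"),
            ):
                spec.latent_cov[(a, b)] = FREE
            if span_residual_covariance:
                spec.residual_cov[("operation_span", "sentence_span")] = FREE

    elif name in ("speed_regression", "speed_regression_plus_criteria"):
        _check(vm, (*EF_DOMAINS, "speed"))
        use(EF_DOMAINS)
        use(("speed",))
        spec.latents = ["common_ef", "speed"]
        _add_factor(spec, "common_ef", [o for d in EF_DOMAINS for o in vm[d]])
        _add_factor(spec, "speed", vm["speed"])
        spec.regressions[("common_ef", "speed")] = FREE
        spec.latent_cov[("common_ef", "common_ef")] = 0.0 if zero_ef_residual else FREE
        if name == "speed_regression_plus_criteria":
            _check(vm, ("wmc", "intelligence"))
            use(("wmc", "intelligence"))
            spec.latents += ["wmc", "intelligence"]
            _add_factor(spec, "wmc", vm["wmc"])
            _add_factor(spec, "intelligence", vm["intelligence"])
            for a, b in (
                ("speed", "wmc"),
                ("speed", "intelligence"),
                ("wmc", "intelligence"),
            ):
                spec.latent_cov[(a, b)] = FREE
            if span_residual_covariance:
                spec.residual_cov[("operation_span", "sentence_span")] = FREE

    return spec
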