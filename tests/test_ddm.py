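"""Wiener first-passage numerics, simulation and KS estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from driftsem.ddm import (
    DiffusionModel,
    DiffusionParams,
    EstimationError,
    ParameterError,
    estimate_ks,
    ez_starting_values,
    fpt_cdf,
    fpt_density,
    hit_probability,
    ks_statistic,
    model_check,
    predicted_rt_quantiles,
    sample_first_passage,
    simulate_trials,
    _ks_statistic_ref,
)

from conftest import make_trials

PROBE_PARAMS = [
    DiffusionParams(v=2.0, a=1.0, t0=0.3),
    DiffusionParams(v=3.62, a=1.0, t0=0.3, st0=0.2),
    DiffusionParams(v=-1.2, a=0.6, t0=0.2, st0=0.1),
    DiffusionParams(v=0.5, a=2.2, t0=0.25),
    DiffusionParams(v=0.0, a=1.0, t0=0.1),
    DiffusionParams(v=6.0, a=1.4, t0=0.29, st0=0.25),
]


class TestHitProbability:
    def test_zero_drift_is_half(self):
        assert hit_probability(DiffusionParams(v=0.0, a=1.0)) == pytest.approx(0.5)

    def test_closed_form_logistic(self):
        # 1 / (1 + e^-2) for v=2, a=1, unbiased start
        assert hit_probability(DiffusionParams(v=2.0, a=1.0)) == pytest.approx(
            1.0 / (1.0 + np.exp(-2.0)), abs=1e-12
        )

    def test_typical_priming_drift_magnitude(self):
        # a mean negative-priming-scale drift puts accuracy in (0.97, 0.98)
        p = hit_probability(DiffusionParams(v=3.62, a=1.0))
        assert 0.97 < p < 0.98

    def test_invalid_params_raise(self):
        with pytest.raises(ParameterError):
            DiffusionParams(v=1.0, a=-1.0)
        with pytest.raises(ParameterError):
            DiffusionParams(v=1.0, a=1.0, zr=1.5)
        with pytest.raises(ParameterError):
            DiffusionParams(v=1.0, a=1.0, t0=0.1, st0=0.5)


class TestDensityAndCdf:
    def test_no_mass_before_nondecision_floor(self):
        p = DiffusionParams(v=2.0, a=1.0, t0=0.3, st0=0.2)
        assert fpt_density(p, p.t_floor - 0.01, "upper") == 0.0
        assert fpt_density(p, 0.0, "upper") == 0.0

    def test_zero_drift_symmetry(self):
        p = DiffusionParams(v=0.0, a=1.0, t0=0.2)
        t = np.array([0.25, 0.4, 1.0, 2.0])
        np.testing.assert_allclose(
            fpt_density(p, t, "upper"), fpt_density(p, t, "lower"), atol=1e-12
        )

    @pytest.mark.parametrize("params", PROBE_PARAMS, ids=lambda p: f"v{p.v}_a{p.a}")
    def test_conservation_and_boundary_mass(self, params):
        total = quad(
            lambda t: fpt_density(params, t, "upper") + fpt_density(params, t, "lower"),
            0, 30, limit=300,
        )[0]
        assert total == pytest.approx(1.0, abs=1e-5)
        upper = quad(lambda t: fpt_density(params, t, "upper"), 0, 30, limit=300)[0]
        assert upper == pytest.approx(hit_probability(params), abs=1e-4)

    def test_cdf_limits_and_example(self):
        p = DiffusionParams(v=2.0, a=1.0, t0=0.3)
        assert fpt_cdf(p, 0.0, "upper") == 0.0
        assert fpt_cdf(p, 10.0, "upper") == pytest.approx(0.8808, abs=1e-4)
        assert fpt_cdf(p, 10.0, "lower") == pytest.approx(1 - 0.8808, abs=1e-4)

    def test_cdf_matches_trapezoid_of_density(self):
        p = DiffusionParams(v=2.0, a=1.0, t0=0.3, st0=0.15)
        grid = np.linspace(0.0, 3.0, 3001)
        dens = fpt_density(p, grid, "upper")
        cum = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
        np.testing.assert_allclose(np.asarray(fpt_cdf(p, grid, "upper")), cum, atol=1e-4)

    def test_cdf_nondecreasing(self):
        p = DiffusionParams(v=-2.0, a=1.3, t0=0.25, st0=0.2)
        grid = np.linspace(0.0, 5.0, 500)
        for b in ("upper", "lower"):
            assert np.all(np.diff(np.asarray(fpt_cdf(p, grid, b))) >= -1e-12)

    def test_nonfinite_time_rejected(self):
        p = DiffusionParams(v=1.0, a=1.0, t0=0.2)
        with pytest.raises(ValueError):
            fpt_density(p, np.nan, "upper")
        with pytest.raises(ValueError):
            fpt_cdf(p, np.inf, "lower")


class TestFastKernel:
    """The compiled KS kernel must agree with the numpy reference path."""

    @pytest.mark.parametrize("params", PROBE_PARAMS, ids=lambda p: f"v{p.v}_a{p.a}")
    def test_kernel_matches_reference(self, params, reference_trials):
        _, trials = reference_trials
        rt = trials["rt_s"].to_numpy()
        correct = trials["correct"].to_numpy()
        ref = _ks_statistic_ref(params, rt, correct)
        fast = ks_statistic(params, rt, correct)
        assert fast == pytest.approx(ref, abs=5e-7)


class TestSimulation:
    def test_determinism(self):
        p = DiffusionParams(v=2.0, a=1.0, t0=0.3, st0=0.1)
        a = simulate_trials(p, 500, seed=11)
        b = simulate_trials(p, 500, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_rt_floor_respected(self):
        p = DiffusionParams(v=2.0, a=1.0, t0=0.3, st0=0.2)
        sim = simulate_trials(p, 2000, seed=3)
        assert (sim["rt_s"] >= p.t_floor).all()

    def test_accuracy_matches_closed_form(self):
        p = DiffusionParams(v=2.0, a=1.0, t0=0.3)
        n = 200_000
        sim = simulate_trials(p, n, seed=1, dt=1e-4)
        pred = hit_probability(p)
        se = np.sqrt(pred * (1 - pred) / n)
        assert abs(sim["correct"].mean() - pred) < 3 * se

    def test_zero_drift_mean_exit_time(self):
        # unbiased start, unit diffusion: mean decision time = z(a-z) = a^2/4
        p = DiffusionParams(v=0.0, a=1.0, t0=0.0)
        n = 100_000
        sim = simulate_trials(p, n, seed=2, dt=1e-4)
        se = sim["rt_s"].std() / np.sqrt(n)
        assert abs(sim["rt_s"].mean() - 0.25) < 3 * se

    def test_inverse_cdf_sampler_matches_model(self):
        p = DiffusionParams(v=3.62, a=1.0, t0=0.3, st0=0.2)
        gen = np.random.default_rng(5)
        rt, correct = sample_first_passage(p, 50_000, gen)
        # the KS distance of an exact sample at truth shrinks like 1/sqrt(n)
        assert ks_statistic(p, rt, correct) < 0.01
        pred = hit_probability(p)
        assert abs(correct.mean() - pred) < 3 * np.sqrt(pred * (1 - pred) / 50_000)

    def test_bad_arguments(self):
        p = DiffusionParams(v=1.0, a=1.0, t0=0.2)
        with pytest.raises(ValueError):
            simulate_trials(p, 0, seed=0)
        with pytest.raises(ValueError):
            simulate_trials(p, 10, seed=0, dt=-1.0)


class TestEstimation:
    def test_minimizer_beats_probe_vectors(self, reference_trials):
        true_params, trials = reference_trials
        res = estimate_ks(trials, n_restarts=5, seed=1)
        fitted = res.params["all"]
        achieved = ks_statistic(fitted, trials["rt_s"].to_numpy(), trials["correct"].to_numpy())
        probes = [
            true_params,
            ez_starting_values(trials["rt_s"].to_numpy(), trials["correct"].to_numpy()),
            DiffusionParams(v=1.0, a=1.5, t0=0.2, st0=0.1),
            DiffusionParams(v=5.0, a=0.8, t0=0.25),
        ]
        for p in probes:
            assert achieved <= ks_statistic(
                p, trials["rt_s"].to_numpy(), trials["correct"].to_numpy()
            ) + 1e-9

    def test_joint_fit_shares_nuisance_and_orders_drift(self):
        # two conditions, v_easy=4 > v_hard=2, shared a, t0, st0
        n_rep, correct_order = 20, 0
        for rep in range(n_rep):
            easy = make_trials(
                DiffusionParams(v=4.0, a=1.2, t0=0.3, st0=0.1), 96, 100 + rep, condition="easy"
            )
            hard = make_trials(
                DiffusionParams(v=2.0, a=1.2, t0=0.3, st0=0.1), 96, 200 + rep, condition="hard"
            )
            res = estimate_ks(pd.concat([easy, hard]), n_restarts=2, seed=rep)
            p_easy, p_hard = res.params["easy"], res.params["hard"]
            assert p_easy.a == p_hard.a and p_easy.t0 == p_hard.t0
            if p_easy.v > p_hard.v:
                correct_order += 1
        assert correct_order >= int(0.95 * n_rep)

    def test_too_few_trials_rejected(self):
        trials = make_trials(DiffusionParams(v=2.0, a=1.0, t0=0.3), 20, 1)
        with pytest.raises(EstimationError):
            estimate_ks(trials)

    def test_degenerate_rt_variance_rejected(self):
        trials = pd.DataFrame({"rt_s": np.full(50, 0.4), "correct": np.ones(50, dtype=int)})
        with pytest.raises(EstimationError):
            estimate_ks(trials)

    def test_all_correct_data_permitted(self):
        trials = make_trials(DiffusionParams(v=6.0, a=1.6, t0=0.3), 60, 3)
        trials["correct"] = 1
        res = estimate_ks(trials, n_restarts=1, seed=0)
        assert np.isfinite(res.ks_stat)

    def test_summary_table_shape(self, reference_trials):
        _, trials = reference_trials
        res = estimate_ks(trials, n_restarts=1, seed=0)
        tab = res.summary()
        assert set(tab.columns) == {"condition", "v", "a", "t0", "st0", "ks_stat", "n_trials"}
        q = res.diagnostics["all"].predicted_quantiles
        assert np.all(np.diff(q) >= 0)


class TestModelCheck:
    def _battery(self, v_mean, v_sd, a, n_trials, seed, n_person=12):
        gen = np.random.default_rng(seed)
        trials, params = {}, {}
        for i in range(n_person):
            v = float(np.clip(v_mean + v_sd * gen.standard_normal(), 0.3, 9.5))
            p = DiffusionParams(v=v, a=a, t0=0.3 + 0.05 * gen.standard_normal(), st0=0.1)
            pid = f"p{i}"
            rt, correct = sample_first_passage(p, n_trials, gen)
            trials[pid] = pd.DataFrame({"rt_s": rt, "correct": correct})
            params[pid] = p
        return trials, params

    def test_self_consistency_high_quantile_correlations(self):
        trials, params = self._battery(2.5, 0.8, 1.1, 500, seed=21)
        out = model_check(trials, params)
        q_rows = out[out["statistic"].str.startswith("rt_q")]
        assert (q_rows["r"] > 0.95).all()

    def test_identical_params_flagged_undefined(self):
        gen = np.random.default_rng(3)
        p = DiffusionParams(v=2.0, a=1.0, t0=0.3)
        trials = {}
        for i in range(4):
            rt, c = sample_first_passage(p, 200, gen)
            trials[f"p{i}"] = pd.DataFrame({"rt_s": rt, "correct": c})
        out = model_check(trials, {f"p{i}": p for i in range(4)})
        acc_row = out[out["statistic"] == "accuracy"].iloc[0]
        assert not acc_row["defined"]

    def test_needs_three_participants(self):
        p = DiffusionParams(v=2.0, a=1.0, t0=0.3)
        t = make_trials(p, 100, 1)
        with pytest.raises(ValueError):
            model_check({"p1": t}, {"p1": p})

    def test_ceiling_accuracy_collapses_accuracy_correlation(self):
        # speed-task regime: true accuracies all > 0.99 -> the accuracy
        # correlation collapses while RT-quantile recovery stays high
        trials, params = self._battery(7.0, 0.6, 1.4, 500, seed=22)
        assert min(hit_probability(p) for p in params.values()) > 0.99
        out = model_check(trials, params)
        q_rows = out[out["statistic"].str.startswith("rt_q")]
        acc = out[out["statistic"] == "accuracy"].iloc[0]
        assert (q_rows["r"] > 0.9).all()
        assert (not acc["defined"]) or abs(acc["r"]) < 0.5


class TestEstimatorConsistency:
    def test_error_shrinks_with_trial_count(self):
        # median |v̂ - v| over a fixed grid decreases from 100 to 1600 trials
        vs = np.linspace(2.2, 5.0, 6)
        med = {}
        for n in (100, 400, 1600):
            errs = []
            for i, v in enumerate(vs):
                p = DiffusionParams(v=v, a=1.0, t0=0.3, st0=0.2)
                trials = make_trials(p, n, 5000 + 17 * i + n)
                res = estimate_ks(trials, n_restarts=2, seed=i)
                (fitted,) = res.params.values()
                errs.append(abs(fitted.v - v))
            med[n] = float(np.median(errs))
        assert med[1600] < med[100]
        assert med[400] < med[100]
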