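import numpy as np
import pytest

from asyndyn.calibrate import (
    ObjectiveConfig,
    estimate_parameters,
    objective,
    objective_components,
    qualitative_criteria_check,
    scaled_sensitivities,
)
from asyndyn.params import InitialConditionSpec, build_initial_state
from asyndyn.quantify import CalibrationData
from asyndyn.simulate import EnsembleSummary, daily_grid, observable_series, simulate_ode

from .conftest import toy_params


def synthetic_data(compiled, params, init, days=(1, 2, 3, 4, 5, 6, 7)):
    """Noise-free observables of a forward run, rounded (the data oracle)."""
    x0 = build_initial_state(compiled.model, init, params, integer=False)
    grid = daily_grid()
    traj = simulate_ode(compiled, params, x0, grid[-1], grid)
    obs = observable_series(traj)
    days = np.asarray(days)
    return CalibrationData.from_arrays(
        days,
        np.round(obs["monomers"][days]),
        np.round(obs["dimers"][days]),
        np.round(obs["oligomers"][days]),
    )


class TestObjective:
    def test_perfect_fit_scores_near_zero(self, compiled, calibrated):
        params, init = calibrated
        data = synthetic_data(compiled, params, init)
        score = objective(compiled, params, init, data)
        assert score < 5e-3  # only rounding of the data remains

    def test_hand_computed_weighted_sse(self, compiled, calibrated):
        # brute-force oracle over the six residuals of a two-day series
        params, init = calibrated
        exact = synthetic_data(compiled, params, init, days=(1, 2))
        shifted = exact.table.copy()
        shifted.loc[0, "monomers"] += 30
        shifted.loc[1, "dimers"] += 5
        shifted.loc[1, "oligomers"] -= 10
        data = CalibrationData(shifted)
        comp = objective_components(compiled, params, init, data)

        x0 = build_initial_state(compiled.model, init, params, integer=False)
        grid = np.linspace(0.0, 2 * 600000.0 / 7.0, 9)
        traj = simulate_ode(compiled, params, x0, grid[-1], grid, rtol=1e-6, atol=1e-6)
        obs = observable_series(traj)
        expected = 0.0
        for name in ("monomers", "dimers", "oligomers"):
            w = 1.0 / np.mean(data.series(name)) ** 2
            resid = obs[name][[4, 8]] - data.series(name)
            expected += w * float(resid @ resid)
        assert comp["sse"] == pytest.approx(expected, rel=1e-9)
        assert comp["penalty"] == 0.0

    def test_cap_violation_raises_score(self, compiled, calibrated):
        params, init = calibrated
        data = synthetic_data(compiled, params, init)
        loose = objective(compiled, params, init, data, ObjectiveConfig(hmw_max=15.0))
        # drop the cap below the trajectory's actual HMW maximum
        tight = objective(compiled, params, init, data, ObjectiveConfig(hmw_max=0.5))
        assert tight > loose

    def test_row_order_invariance(self, compiled, calibrated):
        params, init = calibrated
        data = synthetic_data(compiled, params, init)
        shuffled = CalibrationData(
            data.table.sample(frac=1, random_state=0).reset_index(drop=True)
        )
        a = objective(compiled, params, init, data)
        b = objective(compiled, params, init, shuffled)
        assert a == pytest.approx(b, rel=1e-12)

    def test_moving_toward_observation_improves(self, compiled, calibrated):
        params, init = calibrated
        exact = synthetic_data(compiled, params, init)
        far = exact.table.copy()
        far.loc[3, "oligomers"] += 40
        near = exact.table.copy()
        near.loc[3, "oligomers"] += 10
        worse = objective(compiled, params, init, CalibrationData(far))
        better = objective(compiled, params, init, CalibrationData(near))
        assert better < worse


class TestScaledSensitivities:
    def test_linear_growth_has_unit_sensitivity(self, compiled, zero_init):
        # monomers(t) = k_syn_asyn * t  =>  S = 1 at every day
        params = toy_params(k_syn_asyn=0.01)
        table = scaled_sensitivities(compiled, params, zero_init, targets=("monomers",))
        i = table.parameters.index("k_syn_asyn")
        assert np.allclose(table.matrix[i], 1.0, atol=1e-5)

    def test_da_steady_state_degradation_sensitivity(self, compiled):
        # DA* = k_syn/k_deg  =>  S(DA*, k_deg_da) = -1
        params = toy_params(k_syn_da=1.0, k_deg_da=1e-3)
        init = InitialConditionSpec(
            monomer_total=0, dimer_total=0, oligomer_total=0, lamp2a=0, proteasome=0
        )
        table = scaled_sensitivities(compiled, params, init, targets=("DA",))
        i = table.parameters.index("k_deg_da")
        assert table.matrix[i, 0, -1] == pytest.approx(-1.0, abs=1e-4)

    def test_unreachable_parameter_has_zero_sensitivity(self, compiled, calibrated):
        # lysosome-internal degradation cannot influence cytosolic observables
        params, init = calibrated
        table = scaled_sensitivities(compiled, params, init, rel_delta=1e-2)
        i = table.parameters.index("k_lys_deg")
        assert np.max(np.abs(table.matrix[i])) < 1e-6

    def test_zero_baseline_flagged_not_infinite(self, compiled, zero_init):
        # DA stays identically zero (no production), so S(DA, k_deg_da) is
        # undefined at the baseline and must be flagged rather than infinite
        params = toy_params(k_syn_da=0.0, k_deg_da=0.01)
        table = scaled_sensitivities(compiled, params, zero_init, targets=("DA",))
        assert np.all(np.isfinite(table.matrix))
        i = table.parameters.index("k_deg_da")
        assert table.undefined[i].all()

    def test_deterministic_and_stable_to_delta_halving(self, compiled, calibrated):
        params, init = calibrated
        t1 = scaled_sensitivities(compiled, params, init, rel_delta=1e-3)
        t2 = scaled_sensitivities(compiled, params, init, rel_delta=1e-3)
        assert np.array_equal(t1.matrix, t2.matrix)
        t3 = scaled_sensitivities(compiled, params, init, rel_delta=5e-4)
        assert t1.ranked()[:5] == t3.ranked()[:5]


class TestEstimateParameters:
    def test_empty_free_set_rejected(self, compiled, calibrated):
        params, init = calibrated
        data = synthetic_data(compiled, params, init)
        with pytest.raises(ValueError):
            estimate_parameters(compiled, data, params, init, free_params=[])

    def test_unknown_algorithm_rejected(self, compiled, calibrated):
        params, init = calibrated
        data = synthetic_data(compiled, params, init)
        with pytest.raises(ValueError):
            estimate_parameters(
                compiled, data, params, init, algorithm="sgd", free_params=["k_mod"]
            )

    def test_single_parameter_recovery(self, compiled, calibrated):
        # truth known by construction: perturb one constant and re-fit it
        truth, init = calibrated
        data = synthetic_data(compiled, truth, init)
        start = truth.copy()
        start["k_syn_asyn"] = truth["k_syn_asyn"] * 3.0
        fit = estimate_parameters(
            compiled,
            data,
            start,
            init,
            free_params=["k_syn_asyn"],
            bounds={"k_syn_asyn": (truth["k_syn_asyn"] / 30, truth["k_syn_asyn"] * 30)},
            seed=2,
            n_particles=12,
            n_iter=60,
            start_from_current=False,
        )
        assert fit.parameters["k_syn_asyn"] == pytest.approx(truth["k_syn_asyn"], rel=0.05)

    def test_seed_determinism(self, compiled, calibrated):
        params, init = calibrated
        data = synthetic_data(compiled, params, init)
        kwargs = dict(
            free_params=["k_mod", "k_syn_asyn"], seed=5, n_particles=6, n_iter=4
        )
        a = estimate_parameters(compiled, data, params, init, **kwargs)
        b = estimate_parameters(compiled, data, params, init, **kwargs)
        assert a.parameters.values == b.parameters.values
        assert a.objective == b.objective

    def test_truth_start_has_noise_floor_objective(self, compiled, calibrated):
        params, init = calibrated
        data = synthetic_data(compiled, params, init)
        fit = estimate_parameters(
            compiled, data, params, init, free_params=["k_mod"], seed=1,
            n_particles=4, n_iter=2, start_from_current=True,
        )
        assert fit.objective < 5e-3  # noise-free data: floor ~ rounding only

    @pytest.mark.parametrize("algorithm", ["ga", "gasr", "sres"])
    def test_comparator_algorithms_run(self, compiled, calibrated, algorithm):
        params, init = calibrated
        data = synthetic_data(compiled, params, init)
        fit = estimate_parameters(
            compiled, data, params, init, algorithm=algorithm,
            free_params=["k_syn_asyn"], seed=3, n_particles=6, n_iter=3,
        )
        assert np.isfinite(fit.objective)
        assert fit.algorithm == algorithm


def make_summary(compiled, **series):
    """Build a daily-grid EnsembleSummary with the given species columns."""
    times = daily_grid()
    mean = np.zeros((8, len(compiled.species)))
    for sid, values in series.items():
        mean[:, compiled.species.index(sid)] = values
    return EnsembleSummary(times=times, mean=mean, sd=np.zeros_like(mean),
                           species=compiled.species, n_runs=10)


class TestQualitativeCriteria:
    def test_wrong_grid_rejected(self, compiled):
        summary = make_summary(compiled)
        summary.times = np.linspace(0, 1000, 8)
        with pytest.raises(ValueError):
            qualitative_criteria_check(summary)

    def test_flat_trajectories_fail_c(self, compiled):
        summary = make_summary(
            compiled,
            WT1=np.full(8, 100.0),
            WT2=np.full(8, 10.0),
            WT3=np.full(8, 50.0),
            Lamp2a=np.zeros(8),
        )
        out = qualitative_criteria_check(summary, lamp2a_initial=200)
        assert out["c"] is False

    def test_decreasing_lamp2a_to_zero_passes_e(self, compiled):
        summary = make_summary(compiled, Lamp2a=np.array([200, 150, 110, 75, 45, 25, 10, 0.0]))
        out = qualitative_criteria_check(summary, lamp2a_initial=200)
        assert out["e"] is True

    def test_rising_lamp2a_fails_e(self, compiled):
        summary = make_summary(compiled, Lamp2a=np.array([200, 150, 190, 75, 45, 25, 10, 0.0]))
        assert qualitative_criteria_check(summary, lamp2a_initial=200)["e"] is False

    def test_hmw_cap_criterion(self, compiled):
        ok = make_summary(compiled, HMW=np.full(8, 3.0))
        bad = make_summary(compiled, HMW=np.full(8, 30.0))
        assert qualitative_criteria_check(ok)["d"] is True
        assert qualitative_criteria_check(bad)["d"] is False

    def test_textbook_shapes_pass_all(self, compiled):
        summary = make_summary(
            compiled,
            WT1=np.array([3000, 2605, 2106, 1697, 1277, 1030, 1318, 1205.0]),
            WT2=np.array([25, 22, 20, 22, 33, 37, 54, 86.0]),
            WT3=np.array([90, 108, 139, 154, 154, 155, 156, 197.0]),
            Lamp2a=np.array([200, 150, 110, 75, 45, 25, 8, 2.0]),
            HMW=np.array([0, 1, 2, 3, 3, 3, 4, 5.0]),
        )
        out = qualitative_criteria_check(summary, lamp2a_initial=200)
        assert all(out.values()), out
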