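import numpy as np
import pytest
from scipy import stats

from asyndyn.params import InitialConditionSpec, build_initial_state
from asyndyn.simulate import (
    daily_grid,
    ensemble,
    propensity,
    simulate_ode,
    simulate_ssa,
)

from .conftest import toy_params


def state_of(model, **counts):
    idx = model.species_index()
    x = np.zeros(len(model.species))
    x[idx["Source"]] = 1
    for sid, c in counts.items():
        x[idx[sid]] = c
    return x


class TestPropensity:
    def test_unimolecular(self, model):
        r = next(r for r in model.reactions if r.id == "deg_da")
        assert propensity(r, {"DA": 50}, toy_params(k_deg_da=0.1)) == pytest.approx(5.0)

    def test_heterobimolecular(self, model):
        r = next(r for r in model.reactions if r.id == "mod_wt1")
        state = {"WT1": 100, "DA": 200}
        assert propensity(r, state, toy_params(k_mod=0.001)) == pytest.approx(20.0)

    def test_homodimerization(self, model):
        r = next(r for r in model.reactions if r.id == "dim_f_WT")
        assert propensity(r, {"WT1": 10}, toy_params(k_dim_f=0.01)) == pytest.approx(0.45)

    def test_negative_count_rejected(self, model):
        r = next(r for r in model.reactions if r.id == "deg_da")
        with pytest.raises(ValueError):
            propensity(r, {"DA": -1}, toy_params(k_deg_da=0.1))


class TestOde:
    def test_da_steady_state(self, compiled):
        # closed form: DA* = k_syn_da / k_deg_da = 100
        params = toy_params(k_syn_da=1.0, k_deg_da=0.01)
        x0 = state_of(compiled.model)
        traj = simulate_ode(compiled, params, x0, 5000.0, np.linspace(0, 5000, 11))
        assert traj["DA"][-1] == pytest.approx(100.0, rel=1e-6)

    def test_zero_state_stays_zero(self, compiled):
        params = toy_params(k_deg_da=0.01, k_mod=1e-4)
        x0 = np.zeros(len(compiled.species))
        traj = simulate_ode(compiled, params, x0, 1000.0, np.linspace(0, 1000, 5))
        assert np.all(traj.states == 0.0)

    def test_lamp2a_conserved(self, compiled, calibrated):
        params, init = calibrated
        x0 = build_initial_state(compiled.model, init, params)
        traj = simulate_ode(compiled, params, x0, 600000.0, daily_grid())
        lamp_species = [
            s.id for s in compiled.model.species if s.form in ("Lamp2a", "Lamp2aComplex")
        ]
        total = traj.group_total(lamp_species)
        assert np.allclose(total, total[0], rtol=1e-6)

    def test_t_end_must_be_positive(self, compiled):
        with pytest.raises(ValueError):
            simulate_ode(compiled, toy_params(), np.zeros(90), -1.0)

    def test_source_never_changes(self, compiled, calibrated):
        params, init = calibrated
        x0 = build_initial_state(compiled.model, init, params)
        traj = simulate_ode(compiled, params, x0, 600000.0, daily_grid())
        assert np.all(traj["Source"] == 1.0)


class TestSsa:
    def test_integer_initial_counts_required(self, compiled):
        x0 = np.zeros(len(compiled.species))
        x0[compiled.species.index("DA")] = 1.5
        with pytest.raises(ValueError):
            simulate_ssa(compiled, toy_params(k_deg_da=0.1), x0, 10.0)

    def test_seed_determinism(self, compiled, calibrated):
        params, init = calibrated
        x0 = build_initial_state(compiled.model, init, params)
        a = simulate_ssa(compiled, params, x0, 60000.0, seed=7)
        b = simulate_ssa(compiled, params, x0, 60000.0, seed=7)
        c = simulate_ssa(compiled, params, x0, 60000.0, seed=8)
        assert np.array_equal(a.states, b.states)
        assert not np.array_equal(a.states, c.states)

    def test_exponential_mean_firing_time(self, compiled):
        # single-molecule decay DA -> 0 at k = 0.01/s; E[T] = 1/k = 100 s.
        # T is read off a 0.5 s grid (ceiling bias +0.25 s << tolerance).
        params = toy_params(k_deg_da=0.01)
        x0 = state_of(compiled.model, DA=1)
        grid = np.arange(0.0, 1500.0, 0.5)
        n = 10_000
        times = np.empty(n)
        alive_at_end = 0
        for i in range(n):
            traj = simulate_ssa(compiled, params, x0, 1500.0, grid, seed=i)
            da = traj["DA"]
            dead = np.nonzero(da == 0)[0]
            if len(dead):
                times[i] = grid[dead[0]]
            else:  # censored beyond 15 mean lifetimes; negligible mass
                times[i] = 1500.0
                alive_at_end += 1
        assert alive_at_end < 5
        se = times.std(ddof=1) / np.sqrt(n)
        assert abs(times.mean() - 100.0) < 3 * se + 0.25

    def test_linear_birth_death_matches_ode(self, compiled):
        # Source -> Source + DA, DA -> 0: first-order network, so the SSA
        # ensemble mean must track the ODE solution.
        params = toy_params(k_syn_da=0.05, k_deg_da=0.001)
        x0 = state_of(compiled.model)
        grid = np.linspace(0.0, 2000.0, 6)
        ode = simulate_ode(compiled, params, x0, 2000.0, grid)["DA"]
        n = 1000
        samples = np.empty((n, len(grid)))
        for i in range(n):
            samples[i] = simulate_ssa(compiled, params, x0, 2000.0, grid, seed=i)["DA"]
        mean = samples.mean(axis=0)
        se = samples.std(axis=0, ddof=1) / np.sqrt(n)
        assert np.all(np.abs(mean[1:] - ode[1:]) < 3 * se[1:] + 1e-9)

    def test_lamp2a_conserved_exactly(self, compiled, calibrated):
        params, init = calibrated
        x0 = build_initial_state(compiled.model, init, params)
        traj = simulate_ssa(compiled, params, x0, 600000.0, np.linspace(0, 600000, 200), seed=3)
        for forms in (("Lamp2a", "Lamp2aComplex"), ("Proteasome", "ProteasomeComplex")):
            ids = [s.id for s in compiled.model.species if s.form in forms]
            total = traj.group_total(ids)
            assert np.all(total == total[0])

    def test_nonnegative_counts(self, compiled, calibrated):
        params, init = calibrated
        x0 = build_initial_state(compiled.model, init, params)
        traj = simulate_ssa(compiled, params, x0, 600000.0, seed=11)
        assert np.all(traj.states >= 0)

    def test_direct_method_statistically_equivalent(self, compiled):
        # KS test on per-run event counts, NRM vs direct method.
        params = toy_params(k_syn_da=0.05, k_deg_da=0.002)
        x0 = state_of(compiled.model, DA=10)
        ev_nrm = np.array(
            [simulate_ssa(compiled, params, x0, 2000.0, seed=i).meta["events"] for i in range(1000)]
        )
        ev_dir = np.array(
            [
                simulate_ssa(compiled, params, x0, 2000.0, seed=10_000 + i, method="direct").meta["events"]
                for i in range(1000)
            ]
        )
        assert stats.ks_2samp(ev_nrm, ev_dir).pvalue > 0.01

    def test_homodimerization_large_count_limit(self, compiled):
        # 2 WT1 -> WT2 with large WT1: SSA mean of WT2 tracks the ODE.
        params = toy_params(k_dim_f=1e-7)
        x0 = state_of(compiled.model, WT1=2000)
        grid = np.linspace(0.0, 1000.0, 3)
        ode = simulate_ode(compiled, params, x0, 1000.0, grid)["WT2"]
        n = 400
        samples = np.empty((n, len(grid)))
        for i in range(n):
            samples[i] = simulate_ssa(compiled, params, x0, 1000.0, grid, seed=i)["WT2"]
        se = samples.std(axis=0, ddof=1) / np.sqrt(n)
        assert abs(samples.mean(axis=0)[-1] - ode[-1]) < 3 * se[-1] + 0.5


class TestEnsemble:
    def test_requires_two_runs(self, compiled):
        with pytest.raises(ValueError):
            ensemble(compiled, toy_params(), np.zeros(90), 100.0, n_runs=1)

    def test_no_reactions_gives_zero_sd(self, compiled):
        params = toy_params()  # all rates negligible -> no events
        x0 = state_of(compiled.model, WT1=50, Lamp2a=200)
        summary = ensemble(compiled, params, x0, 1000.0, n_runs=3, base_seed=0)
        assert np.all(summary.sd == 0.0)
        assert np.allclose(summary.mean[-1], x0)

    def test_mean_within_run_envelope(self, compiled, calibrated):
        params, init = calibrated
        x0 = build_initial_state(compiled.model, init, params)
        summary = ensemble(compiled, params, x0, 600000.0, n_runs=4, base_seed=5, keep_runs=True)
        runs = summary.meta["runs"]
        assert np.all(summary.mean <= runs.max(axis=0) + 1e-12)
        assert np.all(summary.mean >= runs.min(axis=0) - 1e-12)
        assert np.all(summary.sd >= 0)

    def test_daily_grid_shape(self, compiled, calibrated):
        params, init = calibrated
        x0 = build_initial_state(compiled.model, init, params)
        summary = ensemble(compiled, params, x0, 600000.0, n_runs=2, base_seed=1)
        assert summary.mean.shape == (8, 90)
        assert summary.times[1] == pytest.approx(600000.0 / 7.0)


class TestTrajectory:
    def test_times_must_increase(self):
        from asyndyn.simulate import Trajectory

        with pytest.raises(ValueError):
            Trajectory(times=[0.0, 0.0], states=np.zeros((2, 1)), species=["A"])

    def test_first_time_zero(self):
        from asyndyn.simulate import Trajectory

        with pytest.raises(ValueError):
            Trajectory(times=[1.0, 2.0], states=np.zeros((2, 1)), species=["A"])

    def test_csv_round_trip(self, compiled, calibrated, tmp_path):
        import pandas as pd

        params, init = calibrated
        x0 = build_initial_state(compiled.model, init, params)
        traj = simulate_ode(compiled, params, x0, 600000.0, daily_grid())
        tidy = tmp_path / "tidy.csv"
        traj.to_csv(tidy)
        df = pd.read_csv(tidy)
        assert set(df.columns) == {"time", "species", "value"}
        assert len(df) == 8 * 90
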