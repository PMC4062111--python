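"""Deterministic (ODE) and exact stochastic simulation of the network.

Mass-action kinetics on particle numbers.  The deterministic rate of a
homodimerization ``A + A -> B`` is ``(k/2) x_A**2``; the stochastic
propensity is ``k x_A (x_A - 1) / 2`` so that the two limits agree at
large counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import ssa_core
from .network import ModelSpec, ReactionDef
from .params import ParameterSet

__all__ = [
    "SECONDS_PER_WEEK",
    "daily_grid",
    "Trajectory",
    "EnsembleSummary",
    "CompiledModel",
    "propensity",
    "simulate_ode",
    "simulate_ssa",
    "ensemble",
    "observable_series",
    "OBSERVABLE_SPECIES",
]

#: The 7-day "lab time" horizon in seconds.
SECONDS_PER_WEEK = 600_000.0
#: One "day" on the simulation clock.
DAY = SECONDS_PER_WEEK / 7.0


def daily_grid(t_end: float = SECONDS_PER_WEEK, n_days: int = 7) -> np.ndarray:
    """Observation grid t = k * t_end / n_days for k = 0..n_days."""
    return np.linspace(0.0, t_end, n_days + 1)


#: Free cytosolic species entering each blot observable (both forms summed).
OBSERVABLE_SPECIES: dict[str, tuple[str, ...]] = {
    "monomers": ("WT1", "DM1"),
    "dimers": ("WT2", "DM2"),
    "oligomers": tuple(f"{f}{n}" for n in range(3, 10) for f in ("WT", "DM")),
}


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    species: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (len(self.times), len(self.species)):
            raise ValueError("states shape does not match times x species")
        if len(self.times) and self.times[0] != 0.0:
            raise ValueError("first output time must be 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __getitem__(self, species_id: str) -> np.ndarray:
        return self.states[:, self.species.index(species_id)]

    def group_total(self, species_ids) -> np.ndarray:
        idx = [self.species.index(s) for s in species_ids]
        return self.states[:, idx].sum(axis=1)

    def to_frame(self, tidy: bool = True) -> pd.DataFrame:
        wide = pd.DataFrame(self.states, columns=self.species)
        wide.insert(0, "time", self.times)
        if not tidy:
            return wide
        return wide.melt(id_vars="time", var_name="species", value_name="value")

    def to_csv(self, path, tidy: bool = True) -> None:
        self.to_frame(tidy=tidy).to_csv(path, index=False)


@dataclass
class EnsembleSummary:
    times: np.ndarray
    mean: np.ndarray  # (n_times, n_species)
    sd: np.ndarray
    species: list[str]
    n_runs: int
    meta: dict = field(default_factory=dict)

    def species_mean(self, species_id: str) -> np.ndarray:
        return self.mean[:, self.species.index(species_id)]

    def group_mean(self, species_ids) -> np.ndarray:
        idx = [self.species.index(s) for s in species_ids]
        return self.mean[:, idx].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.times):
            for j, s in enumerate(self.species):
                rows.append((t, s, self.mean[i, j], self.sd[i, j]))
        return pd.DataFrame(rows, columns=["time", "species", "mean", "sd"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def observable_series(traj: Trajectory | EnsembleSummary) -> dict[str, np.ndarray]:
    """The three blot observables (free cytosolic, both forms summed)."""
    if isinstance(traj, EnsembleSummary):
        return {k: traj.group_mean(v) for k, v in OBSERVABLE_SPECIES.items()}
    return {k: traj.group_total(v) for k, v in OBSERVABLE_SPECIES.items()}


# --------------------------------------------------------------------------
# compilation to arrays
# --------------------------------------------------------------------------


class CompiledModel:
    """Array form of a :class:`ModelSpec` for fast simulation.

    The parameter *values* are passed separately to every simulation call,
    so one compiled model serves many parameter sets.
    """

    def __init__(self, model: ModelSpec):
        self.model = model
        self.species = model.species_ids()
        idx = model.species_index()
        n_r = len(model.reactions)
        n_s = len(model.species)

        self.order = np.zeros(n_r, dtype=np.int64)
        self.r1 = np.zeros(n_r, dtype=np.int64)
        self.r2 = np.full(n_r, -1, dtype=np.int64)
        self.homo = np.zeros(n_r, dtype=np.int64)
        self.param_of = []  # grouped-constant name per reaction
        self.delta = np.zeros((n_r, n_s), dtype=np.float64)

        constant = {s.id for s in model.species if s.constant}
        for j, r in enumerate(model.reactions):
            self.param_of.append(r.rate_parameter)
            if len(r.reactants) == 1:
                sid, st = r.reactants[0]
                if st == 1:
                    self.order[j] = 1
                    self.r1[j] = idx[sid]
                else:  # A + A
                    self.order[j] = 2
                    self.r1[j] = idx[sid]
                    self.r2[j] = idx[sid]
                    self.homo[j] = 1
            else:
                (s1, _), (s2, _) = r.reactants
                self.order[j] = 2
                self.r1[j] = idx[s1]
                self.r2[j] = idx[s2]
            for sid, net in r.net_stoichiometry().items():
                if sid not in constant:
                    self.delta[j, idx[sid]] = net

        # reaction dependency graph: j -> reactions reading species j changes
        readers: list[set[int]] = [set() for _ in range(n_s)]
        for j in range(n_r):
            readers[self.r1[j]].add(j)
            if self.r2[j] >= 0:
                readers[self.r2[j]].add(j)
        dep: list[np.ndarray] = []
        for j in range(n_r):
            affected = {j}
            for s in np.nonzero(self.delta[j])[0]:
                affected |= readers[s]
            dep.append(np.array(sorted(affected), dtype=np.int64))
        self.dep_ptr = np.zeros(n_r + 1, dtype=np.int64)
        self.dep_ptr[1:] = np.cumsum([len(d) for d in dep])
        self.dep_idx = np.concatenate(dep) if dep else np.zeros(0, dtype=np.int64)

        # stoichiometry matrix for the ODE right-hand side
        self.N = self.delta.T.copy()  # (n_s, n_r)
        self._bi = self.r2 >= 0
        self._uni = ~self._bi
        self._homo_mask = self.homo == 1

    def k_vector(self, parameters) -> np.ndarray:
        """Rate-constant values per reaction; accepts ParameterSet or mapping."""
        return np.array([parameters[name] for name in self.param_of], dtype=float)

    def rates_deterministic(self, x: np.ndarray, k: np.ndarray) -> np.ndarray:
        r = np.empty(len(self.order))
        r[self._uni] = k[self._uni] * x[self.r1[self._uni]]
        bi = self._bi
        r[bi] = k[bi] * x[self.r1[bi]] * x[self.r2[bi]]
        hm = self._homo_mask
        r[hm] *= 0.5
        return r

    def rhs(self, t: float, x: np.ndarray, k: np.ndarray) -> np.ndarray:
        return self.N @ self.rates_deterministic(x, k)


def propensity(reaction: ReactionDef, state, parameters: ParameterSet) -> float:
    """Stochastic propensity of one reaction in a given state.

    ``state`` maps species id to count (mapping or pandas Series).
    """
    k = parameters[reaction.rate_parameter]
    for sid, _st in reaction.reactants:
        if state[sid] < 0:
            raise ValueError("negative species count")
    if len(reaction.reactants) == 1:
        sid, st = reaction.reactants[0]
        xa = state[sid]
        if st == 1:
            return k * xa
        return k * xa * (xa - 1.0) / 2.0
    (s1, _), (s2, _) = reaction.reactants
    return k * state[s1] * state[s2]


# --------------------------------------------------------------------------
# simulation front ends
# --------------------------------------------------------------------------


def _as_compiled(model) -> CompiledModel:
    return model if isinstance(model, CompiledModel) else CompiledModel(model)


def _param_hash(parameters) -> str:
    if hasattr(parameters, "content_hash"):
        return parameters.content_hash()
    return ""


def simulate_ode(
    model: ModelSpec | CompiledModel,
    parameters: ParameterSet,
    initial: np.ndarray,
    t_end: float,
    grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> Trajectory:
    """Integrate the mass-action ODE system with LSODA.

    Raises
    ------
    RuntimeError
        On integration failure, reporting the time reached.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    cm = _as_compiled(model)
    if grid is None:
        grid = np.linspace(0.0, t_end, 201)
    grid = np.asarray(grid, dtype=float)
    x0 = np.asarray(initial, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("negative initial count")
    k = cm.k_vector(parameters)
    sol = solve_ivp(
        cm.rhs,
        (0.0, float(t_end)),
        x0,
        t_eval=grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        args=(k,),
    )
    if not sol.success:
        t_fail = sol.t[-1] if len(sol.t) else 0.0
        raise RuntimeError(f"ODE integration failed at t={t_fail:.1f}: {sol.message}")
    states = np.clip(sol.y.T, 0.0, None)  # clip integrator undershoot only
    return Trajectory(
        times=grid,
        states=states,
        species=cm.species,
        meta={
            "algorithm": "ode-lsoda",
            "rtol": rtol,
            "param_hash": _param_hash(parameters),
        },
    )


def simulate_ssa(
    model: ModelSpec | CompiledModel,
    parameters: ParameterSet,
    initial: np.ndarray,
    t_end: float,
    grid: np.ndarray | None = None,
    seed: int = 0,
    method: str = "nrm",
) -> Trajectory:
    """Exact SSA sample path recorded on a time grid.

    ``method`` is ``"nrm"`` (Gibson-Bruck next-reaction, the default) or
    ``"direct"`` (Gillespie direct method, statistically equivalent).
    Identical arguments and seed give bitwise-identical trajectories.
    """
    cm = _as_compiled(model)
    x0 = np.asarray(initial, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("negative initial count")
    if np.any(x0 != np.round(x0)):
        raise ValueError("SSA requires integer initial counts")
    if grid is None:
        grid = daily_grid(t_end)
    grid = np.asarray(grid, dtype=float)
    kernel = {"nrm": ssa_core.ssa_next_reaction, "direct": ssa_core.ssa_direct}[method]
    states, events = kernel(
        cm.order,
        cm.r1,
        cm.r2,
        cm.homo,
        cm.k_vector(parameters),
        cm.delta,
        cm.dep_ptr,
        cm.dep_idx,
        x0.astype(np.int64),
        float(t_end),
        grid,
        int(seed) & 0x7FFFFFFF,
    )
    return Trajectory(
        times=grid,
        states=states,
        species=cm.species,
        meta={
            "algorithm": f"ssa-{method}",
            "seed": int(seed),
            "events": int(events),
            "param_hash": _param_hash(parameters),
        },
    )


def ensemble(
    model: ModelSpec | CompiledModel,
    parameters: ParameterSet,
    initial: np.ndarray,
    t_end: float = SECONDS_PER_WEEK,
    n_runs: int = 10,
    base_seed: int = 0,
    grid: np.ndarray | None = None,
    method: str = "nrm",
    keep_runs: bool = False,
) -> EnsembleSummary:
    """Mean and SD over ``n_runs`` independent SSA runs (seeds base_seed+i)."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    cm = _as_compiled(model)
    if grid is None:
        grid = daily_grid(t_end)
    grid = np.asarray(grid, dtype=float)
    runs = np.empty((n_runs, len(grid), len(cm.species)))
    for i in range(n_runs):
        traj = simulate_ssa(cm, parameters, initial, t_end, grid, seed=base_seed + i, method=method)
        runs[i] = traj.states
    summary = EnsembleSummary(
        times=grid,
        mean=runs.mean(axis=0),
        sd=runs.std(axis=0, ddof=0),
        species=cm.species,
        n_runs=n_runs,
        meta={"base_seed": int(base_seed), "method": method},
    )
    if keep_runs:
        summary.meta["runs"] = runs
    return summary
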