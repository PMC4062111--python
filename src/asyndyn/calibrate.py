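"""Model calibration: objective, sensitivity screening, global optimization.

The objective is a weighted SSE between simulated and observed daily
observables (weights ``1/mean(observed)**2`` per series) plus hinge
penalties for the three empirical caps: HMW <= 15 particles, proteasome-
bound complexes <= 20, and ASYN mass on the proteasome <= 0.5% of all
ASYN in the system.  Particle-swarm optimization is the normative search
algorithm; GA/GASR/SRES are lightweight comparators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import ModelSpec
from .params import PARAMETER_NAMES, InitialConditionSpec, ParameterSet, build_initial_state
from .quantify import CalibrationData
from .simulate import (
    SECONDS_PER_WEEK,
    CompiledModel,
    EnsembleSummary,
    Trajectory,
    daily_grid,
    observable_series,
    simulate_ode,
)

__all__ = [
    "ObjectiveConfig",
    "SensitivityTable",
    "FitResult",
    "objective",
    "objective_components",
    "scaled_sensitivities",
    "estimate_parameters",
    "qualitative_criteria_check",
    "proteasome_mass_fraction",
    "proteasome_bound_complexes",
]

OBSERVABLE_NAMES = ("monomers", "dimers", "oligomers")

#: Proteasome-bound ASYN complex species (orders 3-9, both forms).
PROTEASOME_COMPLEXES = tuple(f"P_{f}{n}" for f in ("WT", "DM") for n in range(3, 10))


@dataclass
class ObjectiveConfig:
    """Weights and constraint caps of the calibration objective."""

    hmw_max: float = 15.0
    proteasome_bound_max: float = 20.0
    proteasome_mass_fraction_max: float = 0.5  # percent
    penalty_weight: float = 10.0
    rtol: float = 1e-6
    fit_monomers: bool = True

    def weights(self, data: CalibrationData) -> dict[str, float]:
        w = {}
        for name in OBSERVABLE_NAMES:
            mean = float(np.mean(data.series(name)))
            w[name] = 1.0 / mean**2
        if not self.fit_monomers:
            w["monomers"] = 0.0
        return w


def proteasome_bound_complexes(traj) -> np.ndarray:
    """Summed proteasome-bound oligomer complex counts over time."""
    if isinstance(traj, EnsembleSummary):
        return traj.group_mean(PROTEASOME_COMPLEXES)
    return traj.group_total(PROTEASOME_COMPLEXES)


def proteasome_mass_fraction(model: ModelSpec, traj) -> np.ndarray:
    """Percent of ASYN monomer units bound to the proteasome, over time.

    Numerator counts units in P_* complexes (including P_HMW at nominal
    size 10); denominator counts units in every ASYN-carrying species.
    """
    sizes = np.array([s.size for s in model.species], dtype=float)
    prot = np.array(
        [s.form == "ProteasomeComplex" for s in model.species], dtype=bool
    )
    asyn = sizes > 0
    states = traj.mean if isinstance(traj, EnsembleSummary) else traj.states
    num = states[:, prot] @ sizes[prot]
    den = states[:, asyn] @ sizes[asyn]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(den > 0, num / den, 0.0)
    return 100.0 * frac


def _cap_penalties(model: ModelSpec, traj, config: ObjectiveConfig) -> float:
    """Quadratic hinge penalties, each normalized by its cap."""
    hmw = traj.group_mean(["HMW"]) if isinstance(traj, EnsembleSummary) else traj["HMW"]
    bound = proteasome_bound_complexes(traj)
    frac = proteasome_mass_fraction(model, traj)
    pen = 0.0
    pen += max(0.0, float(hmw.max()) - config.hmw_max) ** 2 / config.hmw_max**2
    pen += (
        max(0.0, float(bound.max()) - config.proteasome_bound_max) ** 2
        / config.proteasome_bound_max**2
    )
    pen += (
        max(0.0, float(frac.max()) - config.proteasome_mass_fraction_max) ** 2
        / config.proteasome_mass_fraction_max**2
    )
    return pen


def _fit_grid(data: CalibrationData) -> np.ndarray:
    """Daily grid refined 4x so trajectory maxima are caught between days."""
    n_days = int(data.days.max())
    return np.linspace(0.0, n_days * SECONDS_PER_WEEK / 7.0, 4 * n_days + 1)


def objective_components(
    model: ModelSpec | CompiledModel,
    parameters: ParameterSet,
    init: InitialConditionSpec,
    data: CalibrationData,
    config: ObjectiveConfig | None = None,
) -> dict:
    """Weighted SSE, penalties and per-series RMSE for one candidate."""
    config = config or ObjectiveConfig()
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    x0 = build_initial_state(cm.model, init, parameters, integer=False)
    grid = _fit_grid(data)
    try:
        traj = simulate_ode(cm, parameters, x0, grid[-1], grid, rtol=config.rtol, atol=1e-6)
    except RuntimeError as err:
        return {"sse": np.inf, "penalty": np.inf, "score": np.inf, "error": str(err)}
    obs = observable_series(traj)
    weights = config.weights(data)
    day_idx = (4 * data.days).astype(int)  # grid refined 4x
    sse = 0.0
    rmse = {}
    for name in OBSERVABLE_NAMES:
        sim = obs[name][day_idx]
        resid = sim - data.series(name)
        sse += weights[name] * float(resid @ resid)
        rmse[name] = float(np.sqrt(np.mean(resid**2)))
    penalty = _cap_penalties(cm.model, traj, config)
    return {
        "sse": sse,
        "penalty": penalty,
        "score": sse + config.penalty_weight * penalty,
        "rmse": rmse,
        "trajectory": traj,
    }


def objective(
    model: ModelSpec | CompiledModel,
    parameters: ParameterSet,
    init: InitialConditionSpec,
    data: CalibrationData,
    config: ObjectiveConfig | None = None,
) -> float:
    """Scalar calibration score (weighted SSE + cap penalties)."""
    return objective_components(model, parameters, init, data, config)["score"]


# --------------------------------------------------------------------------
# sensitivity analysis
# --------------------------------------------------------------------------


@dataclass
class SensitivityTable:
    """Scaled sensitivities S = (p/y) dy/dp per observable and day."""

    parameters: list[str]
    observables: list[str]
    days: np.ndarray
    matrix: np.ndarray  # (n_params, n_obs, n_days)
    undefined: np.ndarray  # bool mask where y == 0 at the baseline

    def max_abs(self) -> pd.Series:
        vals = np.nanmax(np.abs(np.where(self.undefined, np.nan, self.matrix)), axis=(1, 2))
        return pd.Series(vals, index=self.parameters)

    def ranked(self) -> list[str]:
        return list(self.max_abs().sort_values(ascending=False).index)

    def select(self, threshold: float) -> list[str]:
        s = self.max_abs()
        return [p for p in self.parameters if s[p] >= threshold]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.parameters):
            for j, o in enumerate(self.observables):
                for k, d in enumerate(self.days):
                    rows.append((p, o, int(d), self.matrix[i, j, k], bool(self.undefined[i, j, k])))
        return pd.DataFrame(rows, columns=["parameter", "observable", "day", "sensitivity", "undefined"])


def scaled_sensitivities(
    model: ModelSpec | CompiledModel,
    parameters: ParameterSet,
    init: InitialConditionSpec,
    targets: tuple[str, ...] = OBSERVABLE_NAMES,
    rel_delta: float = 1e-3,
    days: np.ndarray | None = None,
    rtol: float = 1e-8,
) -> SensitivityTable:
    """Central finite-difference scaled sensitivities of daily observables.

    Each parameter p is perturbed to p*(1 +/- rel_delta); the scaled
    sensitivity is ((y+ - y-) / (2 rel_delta)) / y0.  Grid points where the
    baseline observable is zero are flagged undefined rather than infinite.
    """
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    if days is None:
        days = np.arange(1, 8)
    days = np.asarray(days, dtype=int)
    grid = daily_grid()
    t_end = grid[-1]

    def run(pset: ParameterSet) -> np.ndarray:
        x0 = build_initial_state(cm.model, init, pset, integer=False)
        traj = simulate_ode(cm, pset, x0, t_end, grid, rtol=rtol, atol=1e-8)
        obs = observable_series(traj)
        rows = []
        for name in targets:  # observable name or bare species id
            rows.append(obs[name][days] if name in obs else traj[name][days])
        return np.stack(rows)  # (n_obs, n_days)

    y0 = run(parameters)
    names = list(PARAMETER_NAMES)
    mat = np.zeros((len(names), len(targets), len(days)))
    undef = np.zeros_like(mat, dtype=bool)
    for i, name in enumerate(names):
        p = parameters[name]
        if p == 0.0:
            undef[i] = True
            continue
        hi = parameters.copy()
        hi[name] = p * (1.0 + rel_delta)
        lo = parameters.copy()
        lo[name] = p * (1.0 - rel_delta)
        dy = (run(hi) - run(lo)) / (2.0 * rel_delta)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(y0 != 0.0, dy / y0, 0.0)
        undef[i] = y0 == 0.0
        mat[i] = s
    return SensitivityTable(names, list(targets), days, mat, undef)


# --------------------------------------------------------------------------
# free-variable encoding for the optimizers
# --------------------------------------------------------------------------

INIT_FIELDS = ("monomer_total", "dimer_total", "oligomer_total", "f_mono", "f_di")


@dataclass
class _FreeVars:
    """Maps a flat search vector onto (ParameterSet, InitialConditionSpec).

    Rate constants and day-0 totals are searched in log10 space; the
    unmodified fractions are searched linearly in [0, 1].
    """

    param_names: list[str]
    init_fields: list[str]
    lower: np.ndarray
    upper: np.ndarray
    log_mask: np.ndarray

    @classmethod
    def build(
        cls,
        parameters: ParameterSet,
        init: InitialConditionSpec,
        free_params: list[str],
        free_init: list[str],
        bounds: dict[str, tuple[float, float]] | None = None,
    ) -> "_FreeVars":
        bounds = bounds or {}
        lower, upper, log_mask = [], [], []
        for name in free_params:
            lo, hi = bounds.get(name, parameters.bounds(name))
            if not (0 < lo < hi and np.isfinite(hi)):
                raise ValueError(f"bounds for {name} must be finite and positive")
            lower.append(np.log10(lo))
            upper.append(np.log10(hi))
            log_mask.append(True)
        for name in free_init:
            if name in ("f_mono", "f_di"):
                lo, hi = bounds.get(name, (0.0, 1.0))
                lower.append(lo)
                upper.append(hi)
                log_mask.append(False)
            else:
                default = max(getattr(init, name), 1.0)
                lo, hi = bounds.get(name, (max(default / 10.0, 1.0), 2.0 * default))
                lower.append(np.log10(lo))
                upper.append(np.log10(hi))
                log_mask.append(True)
        return cls(
            list(free_params),
            list(free_init),
            np.array(lower),
            np.array(upper),
            np.array(log_mask, dtype=bool),
        )

    @property
    def n(self) -> int:
        return len(self.lower)

    def decode(
        self, z: np.ndarray, parameters: ParameterSet, init: InitialConditionSpec
    ) -> tuple[ParameterSet, InitialConditionSpec]:
        vals = np.where(self.log_mask, 10.0**z, z)
        pset = parameters.copy()
        for i, name in enumerate(self.param_names):
            pset[name] = vals[i]
        kwargs = {}
        for j, name in enumerate(self.init_fields):
            kwargs[name] = float(np.clip(vals[len(self.param_names) + j], 0.0, None))
        new_init = replace(init, **kwargs) if kwargs else init.copy()
        return pset, new_init

    def encode(self, parameters: ParameterSet, init: InitialConditionSpec) -> np.ndarray:
        raw = [parameters[n] for n in self.param_names] + [
            getattr(init, n) for n in self.init_fields
        ]
        raw = np.array(raw, dtype=float)
        z = np.where(self.log_mask, np.log10(np.clip(raw, 1e-300, None)), raw)
        return np.clip(z, self.lower, self.upper)


# --------------------------------------------------------------------------
# optimizers
# --------------------------------------------------------------------------


def _reflect(z: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    z = np.where(z < lo, lo + (lo - z), z)
    z = np.where(z > hi, hi - (z - hi), z)
    return np.clip(z, lo, hi)


def _pso(fun, fv: _FreeVars, seed: int, n_particles: int, n_iter: int, x_init=None):
    """Global-best PSO with the standard constriction-style coefficients."""
    rng = np.random.default_rng(seed)
    w, c1, c2 = 0.7298, 1.4962, 1.4962
    lo, hi = fv.lower, fv.upper
    span = hi - lo
    pos = lo + rng.random((n_particles, fv.n)) * span
    if x_init is not None:
        pos[0] = np.clip(x_init, lo, hi)
    vel = (rng.random((n_particles, fv.n)) - 0.5) * span * 0.2
    pbest = pos.copy()
    pbest_f = np.array([fun(p) for p in pos])
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), pbest_f[g]
    history = [gbest_f]
    n_eval = n_particles
    for _ in range(n_iter):
        r1 = rng.random((n_particles, fv.n))
        r2 = rng.random((n_particles, fv.n))
        vel = w * vel + c1 * r1 * (pbest - pos) + c2 * r2 * (gbest - pos)
        vmax = 0.5 * span
        vel = np.clip(vel, -vmax, vmax)
        pos = _reflect(pos + vel, lo, hi)
        for i in range(n_particles):
            f = fun(pos[i])
            n_eval += 1
            if f < pbest_f[i]:
                pbest_f[i] = f
                pbest[i] = pos[i]
                if f < gbest_f:
                    gbest_f = f
                    gbest = pos[i].copy()
        history.append(gbest_f)
    return gbest, gbest_f, history, n_eval


def _ga(fun, fv: _FreeVars, seed: int, pop_size: int, n_gen: int, x_init=None, stochastic_ranking=False):
    """Real-coded GA (tournament selection, blend crossover, gaussian mutation)."""
    rng = np.random.default_rng(seed)
    lo, hi = fv.lower, fv.upper
    span = hi - lo
    pop = lo + rng.random((pop_size, fv.n)) * span
    if x_init is not None:
        pop[0] = np.clip(x_init, lo, hi)
    fit = np.array([fun(p) for p in pop])
    n_eval = pop_size
    best_i = int(np.argmin(fit))
    gbest, gbest_f = pop[best_i].copy(), fit[best_i]
    history = [gbest_f]
    for _ in range(n_gen):
        order = np.argsort(fit)
        if stochastic_ranking:  # noisy bubble-sort style rank perturbation
            order = order.copy()
            for i in range(len(order) - 1):
                if rng.random() < 0.45:
                    order[i], order[i + 1] = order[i + 1], order[i]
        elite = pop[order[: max(2, pop_size // 5)]]
        children = np.empty_like(pop)
        for i in range(pop_size):
            a, b = elite[rng.integers(len(elite))], elite[rng.integers(len(elite))]
            alpha = rng.random(fv.n)
            child = alpha * a + (1 - alpha) * b
            child += rng.normal(0.0, 0.1, fv.n) * span * (rng.random(fv.n) < 0.3)
            children[i] = _reflect(child, lo, hi)
        children[0] = gbest  # elitism
        pop = children
        fit = np.array([fun(p) for p in pop])
        n_eval += pop_size
        best_i = int(np.argmin(fit))
        if fit[best_i] < gbest_f:
            gbest_f = fit[best_i]
            gbest = pop[best_i].copy()
        history.append(gbest_f)
    return gbest, gbest_f, history, n_eval


def _sres(fun, fv: _FreeVars, seed: int, lam: int, n_gen: int, x_init=None):
    """Simple (mu, lambda) evolution strategy with self-adaptive step size."""
    rng = np.random.default_rng(seed)
    lo, hi = fv.lower, fv.upper
    span = hi - lo
    mu = max(2, lam // 4)
    pop = lo + rng.random((lam, fv.n)) * span
    if x_init is not None:
        pop[0] = np.clip(x_init, lo, hi)
    sig = np.full((lam, fv.n), 0.2) * span
    fit = np.array([fun(p) for p in pop])
    n_eval = lam
    order = np.argsort(fit)
    gbest, gbest_f = pop[order[0]].copy(), fit[order[0]]
    history = [gbest_f]
    tau = 1.0 / np.sqrt(2.0 * fv.n)
    for _ in range(n_gen):
        parents = pop[order[:mu]]
        psig = sig[order[:mu]]
        idx = rng.integers(mu, size=lam)
        sig = psig[idx] * np.exp(tau * rng.normal(size=(lam, fv.n)))
        pop = _reflect(parents[idx] + sig * rng.normal(size=(lam, fv.n)), lo, hi)
        fit = np.array([fun(p) for p in pop])
        n_eval += lam
        order = np.argsort(fit)
        if fit[order[0]] < gbest_f:
            gbest_f = fit[order[0]]
            gbest = pop[order[0]].copy()
        history.append(gbest_f)
    return gbest, gbest_f, history, n_eval


_ALGORITHMS = {"ps", "ga", "gasr", "sres"}


@dataclass
class FitResult:
    parameters: ParameterSet
    init: InitialConditionSpec
    objective: float
    sse: float
    penalty: float
    rmse: dict[str, float]
    caps_satisfied: dict[str, bool]
    history: list[float] = field(default_factory=list)
    n_evaluations: int = 0
    algorithm: str = "ps"
    seed: int = 0

    def report(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "seed": self.seed,
            "objective": self.objective,
            "sse": self.sse,
            "penalty": self.penalty,
            "rmse": self.rmse,
            "caps_satisfied": self.caps_satisfied,
            "n_evaluations": self.n_evaluations,
            "parameters": {n: self.parameters[n] for n in PARAMETER_NAMES},
            "initial_conditions": self.init.to_dict(),
        }


def estimate_parameters(
    model: ModelSpec | CompiledModel,
    data: CalibrationData,
    parameters: ParameterSet,
    init: InitialConditionSpec,
    config: ObjectiveConfig | None = None,
    algorithm: str = "ps",
    free_params: list[str] | None = None,
    free_init: list[str] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_particles: int = 50,
    n_iter: int = 2000,
    start_from_current: bool = True,
) -> FitResult:
    """Fit the free rate constants and initial-condition unknowns.

    ``algorithm`` is one of ``ps`` (normative), ``ga``, ``gasr``, ``sres``.
    Given the same seed and budget the result is deterministic.
    """
    if algorithm not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; pick from {sorted(_ALGORITHMS)}")
    config = config or ObjectiveConfig()
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    if free_params is None:
        free_params = parameters.free_names()
    if free_init is None:
        free_init = []
    for name in free_params:
        if name not in PARAMETER_NAMES:
            raise ValueError(f"unknown free parameter {name!r}")
    for name in free_init:
        if name not in INIT_FIELDS:
            raise ValueError(f"unknown free initial-condition field {name!r}")
    if not free_params and not free_init:
        raise ValueError("empty free-parameter set")

    fv = _FreeVars.build(parameters, init, free_params, free_init, bounds)

    def fun(z: np.ndarray) -> float:
        pset, ics = fv.decode(z, parameters, init)
        return objective(cm, pset, ics, data, config)

    x_init = fv.encode(parameters, init) if start_from_current else None
    if algorithm == "ps":
        best, best_f, history, n_eval = _pso(fun, fv, seed, n_particles, n_iter, x_init)
    elif algorithm == "ga":
        best, best_f, history, n_eval = _ga(fun, fv, seed, n_particles, n_iter, x_init)
    elif algorithm == "gasr":
        best, best_f, history, n_eval = _ga(
            fun, fv, seed, n_particles, n_iter, x_init, stochastic_ranking=True
        )
    else:
        best, best_f, history, n_eval = _sres(fun, fv, seed, n_particles, n_iter, x_init)

    if not np.isfinite(best_f):
        raise RuntimeError("optimizer never found a finite objective; check bounds and model")

    pset, ics = fv.decode(best, parameters, init)
    comp = objective_components(cm, pset, ics, data, config)
    traj = comp["trajectory"]
    caps = {
        "hmw": bool(traj["HMW"].max() <= config.hmw_max),
        "proteasome_bound": bool(
            proteasome_bound_complexes(traj).max() <= config.proteasome_bound_max
        ),
        "proteasome_mass_fraction": bool(
            proteasome_mass_fraction(cm.model, traj).max()
            <= config.proteasome_mass_fraction_max
        ),
    }
    return FitResult(
        parameters=pset,
        init=ics,
        objective=comp["score"],
        sse=comp["sse"],
        penalty=comp["penalty"],
        rmse=comp["rmse"],
        caps_satisfied=caps,
        history=[float(h) for h in history],
        n_evaluations=n_eval,
        algorithm=algorithm,
        seed=seed,
    )


# --------------------------------------------------------------------------
# qualitative criteria
# --------------------------------------------------------------------------


def qualitative_criteria_check(
    summary: EnsembleSummary,
    hmw_max: float = 15.0,
    lamp2a_initial: float | None = None,
) -> dict[str, bool]:
    """The five empirical tuning criteria on a daily-grid ensemble.

    (a) monomers drop after day 1 and start recovering by day 6/7;
    (b) dimers roughly constant (±20%) over days 1-3, then non-decreasing;
    (c) oligomers rise >20% from day 1 to 2, non-decreasing to day 6,
        then a further increase on day 7;
    (d) the HMW pool mean never exceeds ``hmw_max``;
    (e) free Lamp2a decreases (5%-of-initial tolerance) to <= 5% of its
        initial level on day 7.
    """
    expected = daily_grid()
    if len(summary.times) != len(expected) or not np.allclose(summary.times, expected):
        raise ValueError("criteria require the 8-point daily grid over 600,000 s")
    obs = observable_series(summary)
    mono, di, olig = obs["monomers"], obs["dimers"], obs["oligomers"]
    lamp = summary.species_mean("Lamp2a")
    hmw = summary.species_mean("HMW")
    l0 = lamp2a_initial if lamp2a_initial is not None else lamp[0]

    a = bool(min(mono[2:6]) < mono[1] and (mono[6] > mono[5] or mono[7] > mono[5]))
    b = bool(
        np.all(np.abs(di[1:4] - di[1]) <= 0.2 * di[1])
        and np.all(np.diff(di[3:8]) >= 0)
    )
    c = bool(
        olig[2] > 1.2 * olig[1]
        and np.all(np.diff(olig[2:7]) >= 0)
        and olig[7] > olig[6]
    )
    d = bool(hmw.max() <= hmw_max)
    tol = 0.05 * l0
    e = bool(np.all(np.diff(lamp) <= tol) and lamp[7] <= 0.05 * l0)
    return {"a": a, "b": b, "c": c, "d": d, "e": e}
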