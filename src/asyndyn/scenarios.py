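"""In-silico intervention scenarios on the calibrated model.

Three named interventions are built in: halving the ASYN production rate,
tripling the initial Lamp2a receptor count (200 -> 600), and shutting off
DA production while keeping the initial DA pool.  Custom scenarios can
override any rate constant (multiplier or absolute value) or any
initial-condition field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import ModelSpec
from .params import PARAMETER_NAMES, InitialConditionSpec, ParameterSet, build_initial_state
from .simulate import (
    SECONDS_PER_WEEK,
    CompiledModel,
    EnsembleSummary,
    daily_grid,
    ensemble,
    observable_series,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioOutcome",
    "BUILTIN_SCENARIOS",
    "get_scenario",
    "apply_scenario",
    "run_scenario",
    "compare_scenarios",
]

_INIT_FIELDS = {
    "monomer_total",
    "dimer_total",
    "oligomer_total",
    "f_mono",
    "f_di",
    "lamp2a",
    "proteasome",
    "da",
    "hmw",
}


@dataclass(frozen=True)
class ScenarioSpec:
    """A named perturbation of parameters and/or initial conditions."""

    id: str
    param_multipliers: dict = field(default_factory=dict)
    param_values: dict = field(default_factory=dict)
    init_overrides: dict = field(default_factory=dict)
    freeze_da_initial: bool = False  # pin DA(0) at the *base* steady state


BUILTIN_SCENARIOS: dict[str, ScenarioSpec] = {
    "baseline": ScenarioSpec("baseline"),
    "s1_half_production": ScenarioSpec(
        "s1_half_production", param_multipliers={"k_syn_asyn": 0.5}
    ),
    "s2_triple_lamp2a": ScenarioSpec(
        "s2_triple_lamp2a", init_overrides={"lamp2a": 600.0}
    ),
    "s3_da_off": ScenarioSpec(
        "s3_da_off", param_values={"k_syn_da": 0.0}, freeze_da_initial=True
    ),
}


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return BUILTIN_SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; built-ins: {sorted(BUILTIN_SCENARIOS)}"
        ) from None


def apply_scenario(
    base_parameters: ParameterSet,
    base_init: InitialConditionSpec,
    spec: ScenarioSpec,
) -> tuple[ParameterSet, InitialConditionSpec]:
    """Return perturbed copies of the calibrated set; inputs are untouched."""
    for name in list(spec.param_multipliers) + list(spec.param_values):
        if name not in PARAMETER_NAMES:
            raise KeyError(f"scenario {spec.id}: unknown parameter {name!r}")
    for name in spec.init_overrides:
        if name not in _INIT_FIELDS:
            raise KeyError(f"scenario {spec.id}: unknown initial-condition field {name!r}")

    params = base_parameters.copy()
    init = base_init.copy()
    if spec.freeze_da_initial and init.da is None:
        # keep DA(0) at the unperturbed production/turnover steady state
        init = replace(init, da=base_parameters["k_syn_da"] / base_parameters["k_deg_da"])
    for name, mult in spec.param_multipliers.items():
        params[name] = params[name] * mult
    for name, value in spec.param_values.items():
        params[name] = value
    if spec.init_overrides:
        init = replace(init, **{k: float(v) for k, v in spec.init_overrides.items()})
    return params, init


@dataclass
class ScenarioOutcome:
    """Summary metrics of one scenario ensemble (pure function of it)."""

    scenario: str
    lamp2a_initial: float
    lamp2a_day7: float
    dimers_day0: float
    dimers_day7: float
    oligomers_day0: float
    oligomers_day7: float
    monomer_slope_day5_to_7: float
    hmw_max: float

    @property
    def dimer_ratio(self) -> float:
        return self.dimers_day7 / self.dimers_day0 if self.dimers_day0 else np.inf

    @property
    def oligomer_ratio(self) -> float:
        return self.oligomers_day7 / self.oligomers_day0 if self.oligomers_day0 else np.inf

    @classmethod
    def from_summary(cls, scenario: str, summary: EnsembleSummary, lamp2a_initial: float) -> "ScenarioOutcome":
        obs = observable_series(summary)
        mono = obs["monomers"]
        return cls(
            scenario=scenario,
            lamp2a_initial=float(lamp2a_initial),
            lamp2a_day7=float(summary.species_mean("Lamp2a")[7]),
            dimers_day0=float(obs["dimers"][0]),
            dimers_day7=float(obs["dimers"][7]),
            oligomers_day0=float(obs["oligomers"][0]),
            oligomers_day7=float(obs["oligomers"][7]),
            monomer_slope_day5_to_7=float((mono[7] - mono[5]) / 2.0),
            hmw_max=float(summary.species_mean("HMW").max()),
        )


def run_scenario(
    model: ModelSpec | CompiledModel,
    base_parameters: ParameterSet,
    base_init: InitialConditionSpec,
    spec: ScenarioSpec,
    n_runs: int = 10,
    seed: int = 0,
    t_end: float = SECONDS_PER_WEEK,
) -> tuple[ScenarioOutcome, EnsembleSummary]:
    """Ensemble-simulate one scenario and summarize its outcome metrics."""
    cm = model if isinstance(model, CompiledModel) else CompiledModel(model)
    params, init = apply_scenario(base_parameters, base_init, spec)
    x0 = build_initial_state(cm.model, init, params)
    summary = ensemble(cm, params, x0, t_end=t_end, n_runs=n_runs, base_seed=seed)
    outcome = ScenarioOutcome.from_summary(spec.id, summary, init.lamp2a)
    return outcome, summary


def compare_scenarios(
    outcomes: list[ScenarioOutcome], baseline_id: str = "baseline"
) -> pd.DataFrame:
    """Per-scenario metric table with baseline-relative flags.

    ``lamp2a_preserved``: day-7 free Lamp2a above 10% of its initial level.
    ``oligomer_reduction``: day-7 oligomers below the baseline day-7 value.
    """
    if len(outcomes) < 2:
        raise ValueError("need at least two scenario outcomes to compare")
    by_id = {o.scenario: o for o in outcomes}
    if baseline_id not in by_id:
        raise ValueError(f"no outcome named {baseline_id!r} to compare against")
    base = by_id[baseline_id]
    rows = []
    for o in outcomes:
        rows.append(
            {
                "scenario": o.scenario,
                "lamp2a_day7": o.lamp2a_day7,
                "lamp2a_day7_frac_initial": o.lamp2a_day7 / o.lamp2a_initial,
                "dimer_ratio_day7_day0": o.dimer_ratio,
                "oligomer_ratio_day7_day0": o.oligomer_ratio,
                "monomer_slope_day5_to_7": o.monomer_slope_day5_to_7,
                "hmw_max": o.hmw_max,
                "lamp2a_preserved": bool(o.lamp2a_day7 > 0.1 * o.lamp2a_initial),
                "oligomer_reduction": bool(
                    o.scenario != baseline_id and o.oligomers_day7 < base.oligomers_day7
                ),
                "hmw_elevated_vs_baseline": bool(
                    o.scenario != baseline_id and o.hmw_max > base.hmw_max
                ),
            }
        )
    return pd.DataFrame(rows).set_index("scenario")
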