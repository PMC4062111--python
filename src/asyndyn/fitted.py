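"""Shipped parameter sets: the calibrated fit and the starting guess.

``data/initial_guess.yaml`` is the order-of-magnitude starting table used
to seed calibration (literature-anchored reconstruction; the DA-modified
Lamp2a binding constant starts at 1.2x the unmodified one).
``data/calibrated.yaml`` is the accepted particle-swarm fit produced by
``scripts`` / the calibration pipeline with fixed seeds.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .params import InitialConditionSpec, ParameterSet

__all__ = ["load_calibrated", "load_initial_guess", "save_fit"]


def _load(name: str) -> tuple[ParameterSet, InitialConditionSpec]:
    with resources.files("asyndyn.data").joinpath(name).open() as fh:
        doc = yaml.safe_load(fh)
    params = ParameterSet.from_yaml(yaml.safe_dump({"parameters": doc["parameters"]}))
    init = InitialConditionSpec.from_dict(doc["initial_conditions"])
    return params, init


def load_calibrated() -> tuple[ParameterSet, InitialConditionSpec]:
    """The accepted calibrated parameter set and initial conditions."""
    return _load("calibrated.yaml")


def load_initial_guess() -> tuple[ParameterSet, InitialConditionSpec]:
    """The pre-calibration starting values and search bounds."""
    return _load("initial_guess.yaml")


def save_fit(path, parameters: ParameterSet, init: InitialConditionSpec, meta: dict | None = None) -> None:
    """Write a fit file in the same YAML layout as the shipped sets."""
    doc = yaml.safe_load(parameters.to_yaml())
    doc["initial_conditions"] = init.to_dict()
    if meta:
        doc["meta"] = meta
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_fit(path) -> tuple[ParameterSet, InitialConditionSpec]:
    """Read a fit file written by :func:`save_fit`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    params = ParameterSet.from_yaml(yaml.safe_dump({"parameters": doc["parameters"]}))
    init = InitialConditionSpec.from_dict(doc["initial_conditions"])
    return params, init
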