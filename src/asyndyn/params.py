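"""Grouped rate constants and initial-condition specification.

The 136 reactions share exactly 20 grouped rate constants.  Initial
conditions are specified through day-0 observable totals plus split rules
(unmodified fractions for monomers and dimers; uniform split of the
oligomer total over orders 3-9 and over the two forms).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .network import ModelSpec

__all__ = [
    "PARAMETER_NAMES",
    "ParameterSet",
    "InitialConditionSpec",
    "build_initial_state",
]

#: The 20 grouped kinetic rate constants, in canonical order.
PARAMETER_NAMES: tuple[str, ...] = (
    "k_syn_asyn",
    "k_syn_da",
    "k_deg_da",
    "k_mod",
    "k_dim_f",
    "k_olig_f",
    "k_dim_d",
    "k_olig_d",
    "k_hmw",
    "k_l2a_on_12",
    "k_l2a_on_olig",
    "k_l2a_off",
    "k_l2a_intern",
    "k_lys_deg",
    "k_l2a_on_dm",
    "k_auto_in",
    "k_auto_deg",
    "k_prot_on",
    "k_prot_deg",
    "k_prot_hmw",
)

#: Relative affinity increase of DA-modified monomer for Lamp2a used when
#: initializing k_l2a_on_dm from k_l2a_on_12.
DM_AFFINITY_FACTOR = 1.2


@dataclass
class ParameterSet:
    """Values, search bounds and free/fixed flags for the 20 constants."""

    values: dict[str, float]
    lower: dict[str, float] = field(default_factory=dict)
    upper: dict[str, float] = field(default_factory=dict)
    free: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        missing = set(PARAMETER_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing parameter values: {sorted(missing)}")
        for name, val in self.values.items():
            if val < 0 or (val == 0 and name != "k_syn_da"):
                raise ValueError(f"parameter {name} must be positive (got {val})")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __setitem__(self, name: str, value: float) -> None:
        if name not in PARAMETER_NAMES:
            raise KeyError(name)
        self.values[name] = float(value)

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            dict(self.values), dict(self.lower), dict(self.upper), dict(self.free)
        )

    def as_array(self, names: tuple[str, ...] = PARAMETER_NAMES) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)

    def free_names(self) -> list[str]:
        return [n for n in PARAMETER_NAMES if self.free.get(n, False)]

    def bounds(self, name: str) -> tuple[float, float]:
        lo = self.lower.get(name, self.values[name] / 100.0)
        hi = self.upper.get(name, self.values[name] * 100.0)
        return lo, hi

    def content_hash(self) -> str:
        payload = ";".join(f"{n}={self.values[n]:.17g}" for n in PARAMETER_NAMES)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # ------------------------------------------------------------------ io
    def to_yaml(self, path=None) -> str:
        doc = {
            "parameters": {
                n: {
                    "value": float(self.values[n]),
                    "lower": float(self.lower.get(n, self.values[n] / 100.0 if self.values[n] else 0.0)),
                    "upper": float(self.upper.get(n, self.values[n] * 100.0 if self.values[n] else 1.0)),
                    "free": bool(self.free.get(n, False)),
                }
                for n in PARAMETER_NAMES
            }
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "ParameterSet":
        if hasattr(path_or_text, "read"):
            doc = yaml.safe_load(path_or_text)
        elif isinstance(path_or_text, str) and "\n" in path_or_text:
            doc = yaml.safe_load(path_or_text)
        else:
            with open(path_or_text) as fh:
                doc = yaml.safe_load(fh)
        entries = doc["parameters"]
        return cls(
            values={n: float(entries[n]["value"]) for n in entries},
            lower={n: float(entries[n].get("lower", entries[n]["value"] / 100.0)) for n in entries},
            upper={n: float(entries[n].get("upper", entries[n]["value"] * 100.0)) for n in entries},
            free={n: bool(entries[n].get("free", False)) for n in entries},
        )

    @classmethod
    def with_defaults(cls, values: dict[str, float]) -> "ParameterSet":
        """Build a set from bare values; k_l2a_on_dm defaults to 1.2x k_l2a_on_12."""
        vals = dict(values)
        if "k_l2a_on_dm" not in vals and "k_l2a_on_12" in vals:
            vals["k_l2a_on_dm"] = DM_AFFINITY_FACTOR * vals["k_l2a_on_12"]
        return cls(values=vals)


@dataclass
class InitialConditionSpec:
    """Day-0 state expressed through observable totals and split rules.

    The oligomer total is spread uniformly over orders 3-9 and over the
    unmodified/modified forms (14 buckets); integer remainders go to the
    lowest orders, unmodified form first.
    """

    monomer_total: float = 2605.0
    dimer_total: float = 22.0
    oligomer_total: float = 108.0
    f_mono: float = 1.0  # unmodified fraction of monomers
    f_di: float = 1.0  # unmodified fraction of dimers
    lamp2a: float = 200.0
    proteasome: float = 200.0
    da: float | None = None  # None -> k_syn_da / k_deg_da
    hmw: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_mono <= 1.0 or not 0.0 <= self.f_di <= 1.0:
            raise ValueError("unmodified fractions must lie in [0, 1]")
        for name in ("monomer_total", "dimer_total", "oligomer_total", "lamp2a", "proteasome", "hmw"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def copy(self) -> "InitialConditionSpec":
        return replace(self)

    def oligomer_split(self) -> dict[str, int]:
        """Integer counts for WT3..WT9 and DM3..DM9 under the uniform rule."""
        total = int(round(self.oligomer_total))
        # buckets ordered by oligomer order, unmodified before modified
        buckets = [f"{form}{n}" for n in range(3, 10) for form in ("WT", "DM")]
        base, rem = divmod(total, len(buckets))
        out = {b: base for b in buckets}
        for b in buckets[:rem]:
            out[b] += 1
        return out

    def to_dict(self) -> dict:
        return {
            "monomer_total": self.monomer_total,
            "dimer_total": self.dimer_total,
            "oligomer_total": self.oligomer_total,
            "f_mono": self.f_mono,
            "f_di": self.f_di,
            "lamp2a": self.lamp2a,
            "proteasome": self.proteasome,
            "da": self.da,
            "hmw": self.hmw,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InitialConditionSpec":
        return cls(**d)


def build_initial_state(
    model: ModelSpec,
    init: InitialConditionSpec,
    parameters: ParameterSet | None = None,
    integer: bool = True,
) -> np.ndarray:
    """Expand an :class:`InitialConditionSpec` into a full state vector.

    Complexes, lysosome-internal, autophagosomal and sink species start at
    zero.  ``Source`` is set to 1 (a catalyst with constant level).  When
    ``init.da`` is None the DA pool starts at its production/turnover
    steady state ``k_syn_da / k_deg_da``.
    """
    idx = model.species_index()
    x = np.zeros(len(model.species), dtype=float)
    x[idx["Source"]] = 1.0

    mono_wt = init.f_mono * init.monomer_total
    di_wt = init.f_di * init.dimer_total
    x[idx["WT1"]] = mono_wt
    x[idx["DM1"]] = init.monomer_total - mono_wt
    x[idx["WT2"]] = di_wt
    x[idx["DM2"]] = init.dimer_total - di_wt
    for sid, count in init.oligomer_split().items():
        x[idx[sid]] = count
    x[idx["HMW"]] = init.hmw
    x[idx["Lamp2a"]] = init.lamp2a
    x[idx["Prot"]] = init.proteasome

    if init.da is not None:
        x[idx["DA"]] = init.da
    else:
        if parameters is None:
            raise ValueError("parameters required to derive steady-state DA(0)")
        x[idx["DA"]] = parameters["k_syn_da"] / parameters["k_deg_da"]

    if integer:
        x = np.round(x)
    if np.any(x < 0):
        raise ValueError("negative initial count")
    return x
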