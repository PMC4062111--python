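"""Western-blot densitometry to scaled particle numbers.

Converts band intensities (monomer band, dimer band, oligomer smear) into
per-cell particle numbers using three co-measured recombinant standards
(3.5, 7 and 14 ng loads), then scales counts down by 1000 for stochastic
simulation.  Monomer mass is the three-standard average of half-load
ratios; dimers use the monomer band as intensity reference with a 2x
molecular-weight divisor; the oligomer smear is converted through its
standard-normalized ratio to the dimer band.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "QuantConstants",
    "IntensityRecord",
    "CalibrationData",
    "monomer_mass_ng",
    "monomer_particles",
    "dimer_particles",
    "oligomer_particles",
    "quantify_record",
    "quantify_table",
    "load_table1",
]


@dataclass(frozen=True)
class QuantConstants:
    """Fixed constants of the quantification pipeline (read-only)."""

    rasyn_ng: tuple[float, float, float] = (3.5, 7.0, 14.0)
    cell_count: float = 3e5
    monomer_mw_kda: float = 14.4
    dalton_to_kg: float = 1.660538921e-27
    scale_factor: float = 1000.0

    @property
    def monomer_mw_ng(self) -> float:
        # kDa -> Da -> kg -> ng   (1 kg = 1e12 ng)
        return self.monomer_mw_kda * 1e3 * self.dalton_to_kg * 1e12


DEFAULT_CONSTANTS = QuantConstants()


@dataclass(frozen=True)
class IntensityRecord:
    """Band intensities for one day of culture (arbitrary units)."""

    day: int
    I_m: float
    I_d: float
    I_smear: float
    I_r1: float
    I_r2: float
    I_r3: float

    def __post_init__(self) -> None:
        for name in ("I_r1", "I_r2", "I_r3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"standard intensity {name} must be positive")
        for name in ("I_m", "I_d", "I_smear"):
            if getattr(self, name) < 0:
                raise ValueError(f"intensity {name} must be nonnegative")


@dataclass
class CalibrationData:
    """Day-indexed scaled particle numbers of the three observables."""

    table: pd.DataFrame  # columns: day, monomers, dimers, oligomers

    def __post_init__(self) -> None:
        required = ["day", "monomers", "dimers", "oligomers"]
        if list(self.table.columns[:4]) != required:
            raise ValueError(f"expected columns {required}")
        if (self.table[["monomers", "dimers", "oligomers"]] < 0).any().any():
            raise ValueError("particle numbers must be nonnegative")

    @property
    def days(self) -> np.ndarray:
        return self.table["day"].to_numpy()

    def series(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationData":
        return cls(pd.read_csv(path))

    @classmethod
    def from_arrays(cls, days, monomers, dimers, oligomers) -> "CalibrationData":
        return cls(
            pd.DataFrame(
                {
                    "day": np.asarray(days, dtype=int),
                    "monomers": np.asarray(monomers),
                    "dimers": np.asarray(dimers),
                    "oligomers": np.asarray(oligomers),
                }
            )
        )


def load_table1() -> CalibrationData:
    """The packaged daily particle-number fixture (days 1-7)."""
    with resources.files("asyndyn.data").joinpath("table1.csv").open() as fh:
        return CalibrationData(pd.read_csv(fh))


# --------------------------------------------------------------------------
# the quantification equations
# --------------------------------------------------------------------------


def monomer_mass_ng(record: IntensityRecord, constants: QuantConstants = DEFAULT_CONSTANTS) -> float:
    """Total monomer mass (ng): three-standard average of half-load ratios."""
    m1, m2, m3 = constants.rasyn_ng
    return (
        (m1 / 2.0) * record.I_m / record.I_r1
        + (m2 / 2.0) * record.I_m / record.I_r2
        + (m3 / 2.0) * record.I_m / record.I_r3
    ) / 3.0


def monomer_particles(
    mass_ng: float, constants: QuantConstants = DEFAULT_CONSTANTS, round_result: bool = True
) -> float:
    """Scaled per-cell particle count from total monomer mass."""
    if mass_ng < 0:
        raise ValueError("mass must be nonnegative")
    per_cell = mass_ng / constants.cell_count
    particles = per_cell / constants.monomer_mw_ng / constants.scale_factor
    return int(round(particles)) if round_result else particles


def dimer_particles(
    record: IntensityRecord,
    monomer_mass: float,
    constants: QuantConstants = DEFAULT_CONSTANTS,
    round_result: bool = True,
) -> float:
    """Scaled dimer count; monomer band is the intensity reference."""
    if record.I_m <= 0:
        raise ValueError("monomer intensity must be positive for the dimer ratio")
    dimer_mass = monomer_mass * record.I_d / record.I_m
    per_cell = dimer_mass / constants.cell_count
    particles = per_cell / (2.0 * constants.monomer_mw_ng) / constants.scale_factor
    return int(round(particles)) if round_result else particles


def oligomer_particles(
    record: IntensityRecord,
    dimer_count: float,
    constants: QuantConstants = DEFAULT_CONSTANTS,
    normalizer: str = "mean",
    round_result: bool = True,
) -> float:
    """Scaled oligomer-sum count via the standard-normalized smear/dimer ratio.

    ``normalizer`` selects how band intensities are normalized against the
    recombinant standards before forming the ratio: ``"mean"`` divides each
    band by the mean standard intensity; ``"per-standard"`` averages the
    three per-standard ratios.  Both cancel in the final ratio and are kept
    only to document the choice.
    """
    if record.I_d <= 0:
        raise ValueError("dimer intensity must be positive for the smear ratio")
    standards = np.array([record.I_r1, record.I_r2, record.I_r3], dtype=float)
    if normalizer == "mean":
        norm_smear = record.I_smear / standards.mean()
        norm_dimer = record.I_d / standards.mean()
    elif normalizer == "per-standard":
        norm_smear = float(np.mean(record.I_smear / standards))
        norm_dimer = float(np.mean(record.I_d / standards))
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    ratio = norm_smear / norm_dimer
    particles = dimer_count * ratio
    return int(round(particles)) if round_result else particles


def quantify_record(
    record: IntensityRecord, constants: QuantConstants = DEFAULT_CONSTANTS
) -> tuple[int, int, int]:
    """Full pipeline for one day: (monomers, dimers, oligomers), scaled.

    Rounding to integer counts happens once per observable, at the end.
    """
    if record.I_m == 0:  # blank lane: nothing to reference ratios against
        return 0, 0, 0
    mass = monomer_mass_ng(record, constants)
    mono = monomer_particles(mass, constants)
    di_exact = dimer_particles(record, mass, constants, round_result=False)
    di = int(round(di_exact))
    olig = oligomer_particles(record, di_exact, constants) if record.I_d > 0 else 0
    return mono, di, olig


def quantify_table(
    records: pd.DataFrame, constants: QuantConstants = DEFAULT_CONSTANTS
) -> CalibrationData:
    """Quantify a CSV-shaped table of IntensityRecords."""
    rows = []
    for _, row in records.iterrows():
        rec = IntensityRecord(
            day=int(row["day"]),
            I_m=float(row["I_m"]),
            I_d=float(row["I_d"]),
            I_smear=float(row["I_smear"]),
            I_r1=float(row["I_r1"]),
            I_r2=float(row["I_r2"]),
            I_r3=float(row["I_r3"]),
        )
        mono, di, olig = quantify_record(rec, constants)
        rows.append((rec.day, mono, di, olig))
    rows.sort(key=lambda r: r[0])
    return CalibrationData.from_arrays(*zip(*rows))
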