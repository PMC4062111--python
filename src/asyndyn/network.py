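"""Canonical alpha-synuclein (ASYN) reaction network.

The model tracks wild-type (WT) and dopamine-modified (DM) ASYN oligomers
(monomer through nonamer), a single high-molecular-weight (HMW) aggregate
pool, dopamine (DA), and the three proteolytic routes: chaperone-mediated
autophagy through the Lamp2a receptor, macroautophagy through an
autophagosome compartment, and the proteasome.

The canonical network has 90 species, 136 irreversible mass-action
reactions, and 3 compartments (lysosome and autophagosome nested in the
cytosol).  All reactions are elementary (at most two reactant species) and
every reaction is bound to one of 20 grouped rate constants (see
:mod:`asyndyn.params`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "CompartmentDef",
    "ModelSpec",
    "ValidationReport",
    "build_canonical_model",
    "validate_model",
    "hmw_units_absorbed",
]

CYTOSOL = "cytosol"
LYSOSOME = "lysosome"
AUTOPHAGOSOME = "autophagosome"

#: Forms a species may take; Source is the constant production entity.
FORMS = frozenset(
    {
        "WT",
        "DM",
        "DA",
        "HMW",
        "Lamp2a",
        "Lamp2aComplex",
        "Proteasome",
        "ProteasomeComplex",
        "Source",
        "Sink",
        "LysosomeInternal",
    }
)

#: Nominal monomer-unit content of the HMW pool for mass bookkeeping.
HMW_NOMINAL_SIZE = 10


@dataclass(frozen=True)
class SpeciesDef:
    """One biochemical species.

    ``size`` is the number of ASYN monomer units the species carries
    (0 for non-ASYN species such as DA, Lamp2a, the proteasome and the
    inert degradation sinks; 10 nominal for the HMW pool).
    """

    id: str
    compartment: str
    form: str
    size: int = 0
    constant: bool = False

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r} for species {self.id!r}")
        if not 0 <= self.size <= HMW_NOMINAL_SIZE:
            raise ValueError(f"species {self.id!r} has size {self.size} outside 0..10")


@dataclass(frozen=True)
class ReactionDef:
    """One irreversible elementary mass-action reaction.

    ``reactants`` and ``products`` are tuples of ``(species_id, stoichiometry)``.
    Reverse steps are separate reactions; ``rate_parameter`` names the
    grouped rate constant governing the step.
    """

    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_parameter: str

    def __post_init__(self) -> None:
        if len(self.reactants) == 0:
            raise ValueError(f"reaction {self.id!r} has no reactants")
        if len(self.reactants) > 2:
            raise ValueError(f"reaction {self.id!r} is not elementary")
        total_order = sum(s for _, s in self.reactants)
        if total_order > 2:
            raise ValueError(f"reaction {self.id!r} has kinetic order > 2")

    @property
    def reversible(self) -> bool:
        return False

    def net_stoichiometry(self) -> dict[str, int]:
        net: dict[str, int] = {}
        for sid, st in self.reactants:
            net[sid] = net.get(sid, 0) - st
        for sid, st in self.products:
            net[sid] = net.get(sid, 0) + st
        return {k: v for k, v in net.items() if v != 0}


@dataclass(frozen=True)
class CompartmentDef:
    id: str
    parent: str | None = None


@dataclass
class ModelSpec:
    """The full network: species, reactions, compartments."""

    species: list[SpeciesDef]
    reactions: list[ReactionDef]
    compartments: list[CompartmentDef]

    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def get_species(self, sid: str) -> SpeciesDef:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def parameter_names(self) -> list[str]:
        seen: list[str] = []
        for r in self.reactions:
            if r.rate_parameter not in seen:
                seen.append(r.rate_parameter)
        return seen

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return {
            "compartments": [
                {"id": c.id, "parent": c.parent} for c in self.compartments
            ],
            "species": [
                {
                    "id": s.id,
                    "compartment": s.compartment,
                    "form": s.form,
                    "size": s.size,
                    "constant": s.constant,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "id": r.id,
                    "reactants": [list(t) for t in r.reactants],
                    "products": [list(t) for t in r.products],
                    "rate_parameter": r.rate_parameter,
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            species=[SpeciesDef(**s) for s in d["species"]],
            reactions=[
                ReactionDef(
                    id=r["id"],
                    reactants=tuple((sid, st) for sid, st in r["reactants"]),
                    products=tuple((sid, st) for sid, st in r["products"]),
                    rate_parameter=r["rate_parameter"],
                )
                for r in d["reactions"]
            ],
            compartments=[CompartmentDef(**c) for c in d["compartments"]],
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path_or_text) -> "ModelSpec":
        import os

        if isinstance(path_or_text, str) and not path_or_text.lstrip().startswith("{"):
            with open(path_or_text) as fh:
                return cls.from_dict(json.load(fh))
        if hasattr(path_or_text, "read"):
            return cls.from_dict(json.load(path_or_text))
        if isinstance(path_or_text, (str, bytes, os.PathLike)) and not isinstance(
            path_or_text, str
        ):
            with open(path_or_text) as fh:
                return cls.from_dict(json.load(fh))
        return cls.from_dict(json.loads(path_or_text))

    def to_reaction_list(self) -> str:
        """One reaction per line: ``A + B -> C ; k_name``."""
        lines = []
        for r in self.reactions:
            lhs = " + ".join(
                (f"{st} {sid}" if st > 1 else sid) for sid, st in r.reactants
            )
            rhs = " + ".join(
                (f"{st} {sid}" if st > 1 else sid) for sid, st in r.products
            )
            lines.append(f"{lhs} -> {rhs if rhs else '0'} ; {r.rate_parameter}")
        return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# canonical enumeration
# --------------------------------------------------------------------------


def _species_list() -> list[SpeciesDef]:
    sp: list[SpeciesDef] = []
    add = sp.append
    # cytosol (37)
    add(SpeciesDef("Source", CYTOSOL, "Source", 0, constant=True))
    add(SpeciesDef("DA", CYTOSOL, "DA", 0))
    for n in range(1, 10):
        add(SpeciesDef(f"WT{n}", CYTOSOL, "WT", n))
    for n in range(1, 10):
        add(SpeciesDef(f"DM{n}", CYTOSOL, "DM", n))
    add(SpeciesDef("HMW", CYTOSOL, "HMW", HMW_NOMINAL_SIZE))
    add(SpeciesDef("Prot", CYTOSOL, "Proteasome", 0))
    for n in range(3, 10):
        add(SpeciesDef(f"P_WT{n}", CYTOSOL, "ProteasomeComplex", n))
    for n in range(3, 10):
        add(SpeciesDef(f"P_DM{n}", CYTOSOL, "ProteasomeComplex", n))
    add(SpeciesDef("P_HMW", CYTOSOL, "ProteasomeComplex", HMW_NOMINAL_SIZE))
    # lysosome (21)
    add(SpeciesDef("Lamp2a", LYSOSOME, "Lamp2a", 0))
    for n in range(1, 10):
        add(SpeciesDef(f"L_WT{n}", LYSOSOME, "Lamp2aComplex", n))
    for n in range(1, 10):
        add(SpeciesDef(f"L_DM{n}", LYSOSOME, "Lamp2aComplex", n))
    add(SpeciesDef("WT1_lys", LYSOSOME, "LysosomeInternal", 1))
    add(SpeciesDef("WT2_lys", LYSOSOME, "LysosomeInternal", 2))
    # autophagosome (32)
    for n in range(1, 9):
        add(SpeciesDef(f"aWT{n}", AUTOPHAGOSOME, "WT", n))
    for n in range(1, 9):
        add(SpeciesDef(f"aDM{n}", AUTOPHAGOSOME, "DM", n))
    for n in range(1, 9):
        add(SpeciesDef(f"sink_aWT{n}", AUTOPHAGOSOME, "Sink", 0))
    for n in range(1, 9):
        add(SpeciesDef(f"sink_aDM{n}", AUTOPHAGOSOME, "Sink", 0))
    return sp


def _reaction_list() -> list[ReactionDef]:
    rx: list[ReactionDef] = []

    def add(rid, reactants, products, k):
        rx.append(ReactionDef(rid, tuple(reactants), tuple(products), k))

    # production / modification (4)
    add("syn_asyn", [("Source", 1)], [("Source", 1), ("WT1", 1)], "k_syn_asyn")
    add("syn_da", [("Source", 1)], [("Source", 1), ("DA", 1)], "k_syn_da")
    add("deg_da", [("DA", 1)], [], "k_deg_da")
    add("mod_wt1", [("WT1", 1), ("DA", 1)], [("DM1", 1)], "k_mod")

    # cytosolic oligomerization (34)
    add("dim_f_WT", [("WT1", 2)], [("WT2", 1)], "k_dim_f")
    for n in range(2, 9):
        add(f"olig_f_WT{n}", [(f"WT{n}", 1), ("WT1", 1)], [(f"WT{n + 1}", 1)], "k_olig_f")
    add("dim_d_WT", [("WT2", 1)], [("WT1", 2)], "k_dim_d")
    for n in range(2, 9):
        add(f"olig_d_WT{n + 1}", [(f"WT{n + 1}", 1)], [(f"WT{n}", 1), ("WT1", 1)], "k_olig_d")
    add("hmw_form", [("WT9", 1), ("WT1", 1)], [("HMW", 1)], "k_hmw")
    add("hmw_grow", [("HMW", 1), ("WT1", 1)], [("HMW", 1)], "k_hmw")
    add("dim_f_DM", [("DM1", 2)], [("DM2", 1)], "k_dim_f")
    for n in range(2, 9):
        add(f"olig_f_DM{n}", [(f"DM{n}", 1), ("DM1", 1)], [(f"DM{n + 1}", 1)], "k_olig_f")
    add("dim_d_DM", [("DM2", 1)], [("DM1", 2)], "k_dim_d")
    for n in range(2, 9):
        add(f"olig_d_DM{n + 1}", [(f"DM{n + 1}", 1)], [(f"DM{n}", 1), ("DM1", 1)], "k_olig_d")

    # CMA / Lamp2a (37)
    for n in (1, 2):
        add(f"l2a_on_WT{n}", [("Lamp2a", 1), (f"WT{n}", 1)], [(f"L_WT{n}", 1)], "k_l2a_on_12")
    for n in range(3, 10):
        add(f"l2a_on_WT{n}", [("Lamp2a", 1), (f"WT{n}", 1)], [(f"L_WT{n}", 1)], "k_l2a_on_olig")
    for n in range(3, 10):
        add(f"l2a_off_WT{n}", [(f"L_WT{n}", 1)], [("Lamp2a", 1), (f"WT{n}", 1)], "k_l2a_off")
    for n in (1, 2):
        add(
            f"l2a_intern_WT{n}",
            [(f"L_WT{n}", 1)],
            [("Lamp2a", 1), (f"WT{n}_lys", 1)],
            "k_l2a_intern",
        )
    for n in (1, 2):
        add(f"lys_deg_WT{n}", [(f"WT{n}_lys", 1)], [], "k_lys_deg")
    # on-receptor oligomer growth consumes free cytosolic monomers
    add("l2a_grow_WT1", [("L_WT1", 1), ("WT1", 1)], [("L_WT2", 1)], "k_dim_f")
    for n in range(2, 9):
        add(f"l2a_grow_WT{n}", [(f"L_WT{n}", 1), ("WT1", 1)], [(f"L_WT{n + 1}", 1)], "k_olig_f")
    add("l2a_on_DM1", [("Lamp2a", 1), ("DM1", 1)], [("L_DM1", 1)], "k_l2a_on_dm")
    add("l2a_grow_DM1", [("L_DM1", 1), ("DM1", 1)], [("L_DM2", 1)], "k_dim_f")
    for n in range(2, 9):
        add(f"l2a_grow_DM{n}", [(f"L_DM{n}", 1), ("DM1", 1)], [(f"L_DM{n + 1}", 1)], "k_olig_f")

    # macroautophagy (32)
    for n in range(1, 9):
        add(f"auto_in_WT{n}", [(f"WT{n}", 1)], [(f"aWT{n}", 1)], "k_auto_in")
    for n in range(1, 9):
        add(f"auto_in_DM{n}", [(f"DM{n}", 1)], [(f"aDM{n}", 1)], "k_auto_in")
    for n in range(1, 9):
        add(f"auto_deg_WT{n}", [(f"aWT{n}", 1)], [(f"sink_aWT{n}", 1)], "k_auto_deg")
    for n in range(1, 9):
        add(f"auto_deg_DM{n}", [(f"aDM{n}", 1)], [(f"sink_aDM{n}", 1)], "k_auto_deg")

    # proteasome (29)
    for n in range(3, 10):
        add(f"prot_on_WT{n}", [("Prot", 1), (f"WT{n}", 1)], [(f"P_WT{n}", 1)], "k_prot_on")
    for n in range(3, 10):
        add(f"prot_on_DM{n}", [("Prot", 1), (f"DM{n}", 1)], [(f"P_DM{n}", 1)], "k_prot_on")
    for n in range(3, 10):
        add(f"prot_deg_WT{n}", [(f"P_WT{n}", 1)], [("Prot", 1)], "k_prot_deg")
    for n in range(3, 10):
        add(f"prot_deg_DM{n}", [(f"P_DM{n}", 1)], [("Prot", 1)], "k_prot_deg")
    add("prot_on_HMW", [("Prot", 1), ("HMW", 1)], [("P_HMW", 1)], "k_prot_hmw")

    return rx


def build_canonical_model() -> ModelSpec:
    """Build the canonical 90-species / 136-reaction / 3-compartment model.

    Raises
    ------
    ValueError
        If the internal enumeration is inconsistent (duplicate ids,
        dangling species references, unbound parameters).
    """
    model = ModelSpec(
        species=_species_list(),
        reactions=_reaction_list(),
        compartments=[
            CompartmentDef(CYTOSOL, None),
            CompartmentDef(LYSOSOME, CYTOSOL),
            CompartmentDef(AUTOPHAGOSOME, CYTOSOL),
        ],
    )
    report = validate_model(model)
    if report.violations:
        raise ValueError("canonical model failed validation:\n" + str(report))
    return model


def hmw_units_absorbed(reaction: ReactionDef) -> int:
    """Monomer units absorbed into the HMW pool by one firing of *reaction*.

    The HMW pool is unsized; its growth is tracked only through this
    diagnostic (10 units on formation from a nonamer + monomer, 1 unit per
    growth step).
    """
    if reaction.id == "hmw_form":
        return HMW_NOMINAL_SIZE
    if reaction.id == "hmw_grow":
        return 1
    return 0


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

EXPECTED_SPECIES = 90
EXPECTED_REACTIONS = 136
EXPECTED_COMPARTMENTS = 3
EXPECTED_PARAMETERS = 20


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        return "\n".join(self.violations) if self.violations else "OK"


def _conserved_total(model: ModelSpec, forms: Iterable[str]) -> dict[str, int]:
    forms = set(forms)
    return {s.id: 1 for s in model.species if s.form in forms}


def validate_model(model: ModelSpec, parameters: Iterable[str] | None = None) -> ValidationReport:
    """Check the structural invariants; violations are reported, not raised.

    If *parameters* is given, every reaction's rate parameter must resolve
    to one of those names.
    """
    rep = ValidationReport()
    v = rep.violations.append

    ids = model.species_ids()
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        v(f"duplicate species ids: {dup}")
    rids = [r.id for r in model.reactions]
    if len(set(rids)) != len(rids):
        v("duplicate reaction ids")

    if len(model.species) != EXPECTED_SPECIES:
        v(f"species count {len(model.species)} != {EXPECTED_SPECIES}")
    if len(model.reactions) != EXPECTED_REACTIONS:
        v(f"reaction count {len(model.reactions)} != {EXPECTED_REACTIONS}")
    if len(model.compartments) != EXPECTED_COMPARTMENTS:
        v(f"compartment count {len(model.compartments)} != {EXPECTED_COMPARTMENTS}")

    known = set(ids)
    for r in model.reactions:
        for sid, _ in list(r.reactants) + list(r.products):
            if sid not in known:
                v(f"reaction {r.id}: unknown species {sid}")

    n_const = sum(1 for s in model.species if s.constant)
    if n_const != 1:
        v(f"expected exactly one constant species (Source), found {n_const}")

    if parameters is not None:
        pset = set(parameters)
        for r in model.reactions:
            if r.rate_parameter not in pset:
                v(f"reaction {r.id}: unbound parameter {r.rate_parameter}")

    # Lamp2a and proteasome moiety conservation per-reaction
    for label, forms in (
        ("Lamp2a", ("Lamp2a", "Lamp2aComplex")),
        ("Proteasome", ("Proteasome", "ProteasomeComplex")),
    ):
        members = _conserved_total(model, forms)
        for r in model.reactions:
            net = sum(st for sid, st in r.net_stoichiometry().items() if sid in members)
            if net != 0:
                v(f"reaction {r.id}: {label} moiety not conserved (net {net:+d})")

    return rep
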