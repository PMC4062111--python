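"""SBML Level 3 Version 1 export/import.

The writer emits plain SBML: three compartments, substance-only species,
global parameters for the 20 grouped constants, and one reaction element
per network reaction with an explicit mass-action MathML product as its
kinetic law (``0.5 * k * A * A`` for homodimerizations, matching the
deterministic rate convention).  The reader recovers counts, ids,
parameter values and initial amounts from documents written here (or any
plain SBML core document with the same structure).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

import numpy as np

from .network import CompartmentDef, ModelSpec, ReactionDef, SpeciesDef
from .params import PARAMETER_NAMES, ParameterSet

__all__ = ["export_sbml", "import_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _math_product(parent: ET.Element, factors: list[tuple[str, str]]) -> None:
    math = ET.SubElement(parent, f"{{{MATHML_NS}}}math")
    apply_ = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
    ET.SubElement(apply_, f"{{{MATHML_NS}}}times")
    for kind, value in factors:
        el = ET.SubElement(apply_, f"{{{MATHML_NS}}}{kind}")
        el.text = value


def export_sbml(
    model: ModelSpec,
    parameters: ParameterSet | dict,
    initial_state: np.ndarray | dict | None = None,
    model_id: str = "asyn_dynamics",
) -> str:
    """Serialize the model to an SBML L3V1 document (returns XML text).

    Raises
    ------
    ValueError
        If a reaction references a rate constant with no value.
    """
    values = parameters.values if isinstance(parameters, ParameterSet) else dict(parameters)
    for r in model.reactions:
        if r.rate_parameter not in values or values[r.rate_parameter] is None:
            raise ValueError(f"reaction {r.id}: parameter {r.rate_parameter} has no value")
        if not np.isfinite(values[r.rate_parameter]):
            raise ValueError(f"parameter {r.rate_parameter} is not finite")

    if initial_state is None:
        amounts = {s.id: 0.0 for s in model.species}
    elif isinstance(initial_state, dict):
        amounts = {s.id: float(initial_state.get(s.id, 0.0)) for s in model.species}
    else:
        ids = model.species_ids()
        amounts = {sid: float(initial_state[i]) for i, sid in enumerate(ids)}

    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "1"})
    mdl = ET.SubElement(root, f"{{{SBML_NS}}}model", {"id": model_id})

    locomp = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    for c in model.compartments:
        ET.SubElement(
            locomp,
            f"{{{SBML_NS}}}compartment",
            {"id": c.id, "constant": "true", "size": "1", "spatialDimensions": "3"},
        )

    losp = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for s in model.species:
        ET.SubElement(
            losp,
            f"{{{SBML_NS}}}species",
            {
                "id": s.id,
                "compartment": s.compartment,
                "initialAmount": repr(amounts[s.id]),
                "hasOnlySubstanceUnits": "true",
                "boundaryCondition": "true" if s.constant else "false",
                "constant": "true" if s.constant else "false",
            },
        )

    lop = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
    for name in PARAMETER_NAMES:
        if name in values:
            ET.SubElement(
                lop,
                f"{{{SBML_NS}}}parameter",
                {"id": name, "value": repr(float(values[name])), "constant": "true"},
            )

    lor = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for r in model.reactions:
        rx = ET.SubElement(
            lor,
            f"{{{SBML_NS}}}reaction",
            {"id": r.id, "reversible": "false", "fast": "false"},
        )
        if r.reactants:
            lorct = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for sid, st in r.reactants:
                ET.SubElement(
                    lorct,
                    f"{{{SBML_NS}}}speciesReference",
                    {"species": sid, "stoichiometry": str(st), "constant": "true"},
                )
        if r.products:
            loprd = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for sid, st in r.products:
                ET.SubElement(
                    loprd,
                    f"{{{SBML_NS}}}speciesReference",
                    {"species": sid, "stoichiometry": str(st), "constant": "true"},
                )
        kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        factors: list[tuple[str, str]] = []
        if len(r.reactants) == 1 and r.reactants[0][1] == 2:  # A + A
            factors.append(("cn", "0.5"))
            factors.append(("ci", r.rate_parameter))
            factors.append(("ci", r.reactants[0][0]))
            factors.append(("ci", r.reactants[0][0]))
        else:
            factors.append(("ci", r.rate_parameter))
            for sid, st in r.reactants:
                for _ in range(st):
                    factors.append(("ci", sid))
        _math_product(kl, factors)

    ET.indent(root)
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        root, encoding="unicode"
    )


def import_sbml(text: str) -> tuple[ModelSpec, dict[str, float], dict[str, float]]:
    """Parse an SBML document written by :func:`export_sbml`.

    Returns ``(model, parameter_values, initial_amounts)``.  Species sizes
    and forms are not encoded in SBML core; imported species carry form
    ``Sink``/size 0 placeholders except where ids match the canonical
    naming, so structural counts and ids round-trip exactly.
    """
    root = ET.fromstring(text)
    ns = {"s": SBML_NS}
    mdl = root.find("s:model", ns)
    if mdl is None:
        raise ValueError("no <model> element")

    compartments = []
    for c in mdl.findall("s:listOfCompartments/s:compartment", ns):
        compartments.append(CompartmentDef(c.attrib["id"]))

    species = []
    amounts: dict[str, float] = {}
    for s in mdl.findall("s:listOfSpecies/s:species", ns):
        sid = s.attrib["id"]
        species.append(
            SpeciesDef(
                id=sid,
                compartment=s.attrib["compartment"],
                form="Source" if s.attrib.get("constant") == "true" else "Sink",
                size=0,
                constant=s.attrib.get("constant") == "true",
            )
        )
        amounts[sid] = float(s.attrib.get("initialAmount", 0.0))

    params = {
        p.attrib["id"]: float(p.attrib["value"])
        for p in mdl.findall("s:listOfParameters/s:parameter", ns)
    }

    reactions = []
    for rx in mdl.findall("s:listOfReactions/s:reaction", ns):
        reactants = tuple(
            (ref.attrib["species"], int(float(ref.attrib.get("stoichiometry", 1))))
            for ref in rx.findall("s:listOfReactants/s:speciesReference", ns)
        )
        products = tuple(
            (ref.attrib["species"], int(float(ref.attrib.get("stoichiometry", 1))))
            for ref in rx.findall("s:listOfProducts/s:speciesReference", ns)
        )
        cis = rx.findall(
            "s:kineticLaw/{%s}math/{%s}apply/{%s}ci" % (MATHML_NS, MATHML_NS, MATHML_NS),
            ns,
        )
        rate_parameter = cis[0].text.strip() if cis else ""
        reactions.append(
            ReactionDef(rx.attrib["id"], reactants, products, rate_parameter)
        )

    return ModelSpec(species, reactions, compartments), params, amounts
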