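"""Minimal SBML Level 3 Version 2 export/import for mass-action networks.

Writes the model as a flat SBML document: one compartment (the cell, sized
to the initial volume), species as substance amounts, one global parameter
per rate constant, and reactions with explicit stoichiometry and a
mass-action kinetic law in MathML (deterministic convention:
k * V^e * prod n_i^s_i / s_i!, where e is the reaction's volume exponent).
The stochastic propensity used by the simulator replaces n^s/s! with the
combinatorial count C(n, s); the two agree for first-order reactions and
in the large-count limit.

The reader understands the same subset, so export -> import round-trips
species, reactions, stoichiometries and rate values without loss.
:func:`validate_sbml` applies the structural consistency rules (unique
identifiers, resolvable references, positive stoichiometries).
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from io import StringIO

from .network import (
    NetworkConfigError,
    ParameterSet,
    ReactionDef,
    ReactionNetwork,
    SpeciesDef,
)

__all__ = ["export_sbml", "import_sbml", "validate_sbml", "evaluate_rate_law"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_ROLE_ANNOT = "chaperostart:role"


def _m(tag: str) -> str:
    return f"{{{MATHML_NS}}}{tag}"


def _s(tag: str) -> str:
    return f"{{{SBML_NS}}}{tag}"


def _math_for_reaction(r: ReactionDef) -> ET.Element:
    """MathML mass-action rate law (deterministic convention)."""
    math_el = ET.Element(_m("math"))
    times = ET.SubElement(math_el, _m("apply"))
    ET.SubElement(times, _m("times"))
    k = ET.SubElement(times, _m("ci"))
    k.text = f" {r.rate_constant} "
    e = r.vol_exponent
    if e != 0:
        powv = ET.SubElement(times, _m("apply"))
        ET.SubElement(powv, _m("power"))
        ci = ET.SubElement(powv, _m("ci"))
        ci.text = " cell "
        cn = ET.SubElement(powv, _m("cn"))
        cn.set("type", "integer")
        cn.text = f" {e} "
    coeff = 1.0
    for sp, st in sorted(r.reactants.items()):
        if st == 1:
            ci = ET.SubElement(times, _m("ci"))
            ci.text = f" {sp} "
        else:
            powr = ET.SubElement(times, _m("apply"))
            ET.SubElement(powr, _m("power"))
            ci = ET.SubElement(powr, _m("ci"))
            ci.text = f" {sp} "
            cn = ET.SubElement(powr, _m("cn"))
            cn.set("type", "integer")
            cn.text = f" {st} "
            coeff /= math.factorial(st)
    if coeff != 1.0:
        cn = ET.SubElement(times, _m("cn"))
        cn.text = f" {coeff!r} "
    return math_el


def export_sbml(network: ReactionNetwork) -> str:
    """Serialize the network as an SBML L3V2 document (XML string)."""
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    root = ET.Element(_s("sbml"), {"level": "3", "version": "2"})
    model = ET.SubElement(root, _s("model"), {"id": "chaperostart_model"})
    comps = ET.SubElement(model, _s("listOfCompartments"))
    ET.SubElement(comps, _s("compartment"), {
        "id": "cell", "spatialDimensions": "3", "constant": "false",
        "size": repr(float(network.parameters.initial_volume)),
    })
    sps = ET.SubElement(model, _s("listOfSpecies"))
    for sp in network.species:
        ET.SubElement(sps, _s("species"), {
            "id": sp.name, "compartment": "cell",
            "initialAmount": repr(float(sp.initial_count)),
            "hasOnlySubstanceUnits": "true",
            "boundaryCondition": "false", "constant": "false",
            "metaid": f"role_{sp.role}",
        })
    pars = ET.SubElement(model, _s("listOfParameters"))
    seen: set[str] = set()
    for r in network.reactions:
        if r.rate_constant in seen:
            continue
        seen.add(r.rate_constant)
        ET.SubElement(pars, _s("parameter"), {
            "id": r.rate_constant, "constant": "true",
            "value": repr(float(getattr(network.parameters,
                                        r.rate_constant))),
        })
    rxns = ET.SubElement(model, _s("listOfReactions"))
    for r in network.reactions:
        rx = ET.SubElement(rxns, _s("reaction"), {
            "id": r.name, "reversible": "false",
        })
        if r.volume_exponent_override is not None:
            rx.set("metaid", f"vexp_{r.volume_exponent_override}")
        if r.reactants:
            lor = ET.SubElement(rx, _s("listOfReactants"))
            for sp, st in sorted(r.reactants.items()):
                ET.SubElement(lor, _s("speciesReference"), {
                    "species": sp, "stoichiometry": str(st),
                    "constant": "true",
                })
        if r.products:
            lop = ET.SubElement(rx, _s("listOfProducts"))
            for sp, st in sorted(r.products.items()):
                ET.SubElement(lop, _s("speciesReference"), {
                    "species": sp, "stoichiometry": str(st),
                    "constant": "true",
                })
        kl = ET.SubElement(rx, _s("kineticLaw"))
        kl.append(_math_for_reaction(r))
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def import_sbml(document: str) -> ReactionNetwork:
    """Parse an SBML document produced by :func:`export_sbml`.

    Reconstructs species (with roles from the metaid annotation),
    reactions with stoichiometry and volume-scaling overrides, and rate
    constants into a :class:`ParameterSet`.
    """
    root = ET.parse(StringIO(document)).getroot()
    model = root.find(_s("model"))
    if model is None:
        raise NetworkConfigError("SBML document has no <model>")
    params = ParameterSet()
    comp = model.find(f"{_s('listOfCompartments')}/{_s('compartment')}")
    if comp is not None and comp.get("size"):
        params.initial_volume = float(comp.get("size"))
    for par in model.iter(_s("parameter")):
        pid, val = par.get("id"), float(par.get("value", "nan"))
        if hasattr(params, pid):
            setattr(params, pid, val)
    species = []
    for sp in model.iter(_s("species")):
        role = (sp.get("metaid") or "role_folded_protein")
        role = role.removeprefix("role_")
        species.append(SpeciesDef(
            name=sp.get("id"), role=role,
            initial_count=int(round(float(sp.get("initialAmount", "0")))),
        ))
    reactions = []
    for rx in model.iter(_s("reaction")):
        def _refs(tag, rx=rx):
            lo = rx.find(_s(tag))
            if lo is None:
                return {}
            return {
                ref.get("species"): int(float(ref.get("stoichiometry", "1")))
                for ref in lo.findall(_s("speciesReference"))
            }
        kl = rx.find(_s("kineticLaw"))
        rate_name = None
        if kl is not None:
            ci = kl.find(f"{_m('math')}/{_m('apply')}/{_m('ci')}")
            if ci is not None:
                rate_name = ci.text.strip()
        if rate_name is None:
            raise NetworkConfigError(
                f"reaction {rx.get('id')!r}: no rate constant in kinetic law"
            )
        override = None
        metaid = rx.get("metaid") or ""
        if metaid.startswith("vexp_"):
            override = int(metaid.removeprefix("vexp_"))
        reactions.append(ReactionDef(
            name=rx.get("id"), reactants=_refs("listOfReactants"),
            products=_refs("listOfProducts"), rate_constant=rate_name,
            volume_exponent_override=override,
        ))
    return ReactionNetwork(species=species, reactions=reactions,
                           parameters=params)


def validate_sbml(document: str) -> list[str]:
    """Structural consistency check; returns a list of problems (empty = ok).

    Covers the core identifier and reference rules: well-formed XML with the
    L3V2 namespace, unique species/parameter/reaction ids, species
    references resolving to declared species, positive stoichiometries,
    kinetic-law symbols resolving to parameters, species or compartments.
    """
    issues: list[str] = []
    try:
        root = ET.parse(StringIO(document)).getroot()
    except ET.ParseError as exc:
        return [f"not well-formed XML: {exc}"]
    if root.tag != _s("sbml"):
        issues.append("root element is not sbml (L3V2 namespace)")
        return issues
    model = root.find(_s("model"))
    if model is None:
        return ["missing <model>"]
    comp_ids = {c.get("id") for c in model.iter(_s("compartment"))}
    sp_ids = [s.get("id") for s in model.iter(_s("species"))]
    if len(sp_ids) != len(set(sp_ids)):
        issues.append("duplicate species ids")
    par_ids = [p.get("id") for p in model.iter(_s("parameter"))]
    if len(par_ids) != len(set(par_ids)):
        issues.append("duplicate parameter ids")
    known = set(sp_ids) | set(par_ids) | comp_ids
    rx_ids = []
    for rx in model.iter(_s("reaction")):
        rid = rx.get("id")
        rx_ids.append(rid)
        for ref in rx.iter(_s("speciesReference")):
            sp = ref.get("species")
            if sp not in sp_ids:
                issues.append(f"reaction {rid}: unknown species {sp!r}")
            try:
                if float(ref.get("stoichiometry", "1")) <= 0:
                    issues.append(f"reaction {rid}: non-positive "
                                  f"stoichiometry for {sp!r}")
            except ValueError:
                issues.append(f"reaction {rid}: bad stoichiometry for {sp!r}")
        for ci in rx.iter(_m("ci")):
            sym = (ci.text or "").strip()
            if sym and sym not in known:
                issues.append(f"reaction {rid}: unresolved symbol {sym!r}")
        for sp in (s.get("species") for s in rx.iter(_s("species"))):
            pass
    if len(rx_ids) != len(set(rx_ids)):
        issues.append("duplicate reaction ids")
    return issues


def _eval_mathml(node: ET.Element, env: dict[str, float]) -> float:
    tag = node.tag
    if tag == _m("math"):
        return _eval_mathml(node[0], env)
    if tag == _m("ci"):
        return env[node.text.strip()]
    if tag == _m("cn"):
        return float(node.text.strip())
    if tag == _m("apply"):
        op = node[0].tag
        args = [_eval_mathml(ch, env) for ch in node[1:]]
        if op == _m("times"):
            out = 1.0
            for a in args:
                out *= a
            return out
        if op == _m("power"):
            return args[0] ** args[1]
        if op == _m("plus"):
            return sum(args)
        if op == _m("divide"):
            return args[0] / args[1]
        raise NetworkConfigError(f"unsupported MathML operator {op}")
    raise NetworkConfigError(f"unsupported MathML node {tag}")


def evaluate_rate_law(
    document: str, reaction_id: str, env: dict[str, float]
) -> float:
    """Numerically evaluate a reaction's kinetic law at a given state.

    ``env`` maps symbols (species amounts, parameter values and the
    compartment size ``cell``) to numbers; parameters and the compartment
    default to the document's declared values.
    """
    root = ET.parse(StringIO(document)).getroot()
    model = root.find(_s("model"))
    full_env: dict[str, float] = {}
    comp = model.find(f"{_s('listOfCompartments')}/{_s('compartment')}")
    if comp is not None and comp.get("size"):
        full_env["cell"] = float(comp.get("size"))
    for par in model.iter(_s("parameter")):
        full_env[par.get("id")] = float(par.get("value", "nan"))
    full_env.update(env)
    for rx in model.iter(_s("reaction")):
        if rx.get("id") == reaction_id:
            math_el = rx.find(f"{_s('kineticLaw')}/{_m('math')}")
            return _eval_mathml(math_el, full_env)
    raise KeyError(f"no reaction {reaction_id!r} in document")
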