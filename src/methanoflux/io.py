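"""Model serialization: a native JSON dialect and an SBML-L3-FBC-v2 subset.

The JSON schema is the package's canonical format::

    {
      "id": "model id",
      "objective": "reaction id",
      "genes": ["g1", ...],
      "metabolites": [
        {"id": "...", "name": "...", "formula": {"C": 1, ...},
         "compartment": "c"|"e"},
        ...
      ],
      "reactions": [
        {"id": "...", "name": "...", "stoichiometry": {"met id": coeff, ...},
         "lower_bound": lb, "upper_bound": ub,
         "gene_rule": "gA and (gB or gC)" | "",
         "pathway": "...", "is_exchange": true|false},
        ...
      ]
    }

The SBML reader/writer covers species, compartments, reactions, fbc flux
bounds, fbc gene-product associations and one maximization objective.
Documents carrying constructs outside this subset (rules, events,
constraints) are rejected loudly rather than silently mis-read.
"""

from __future__ import annotations

import json
from pathlib import Path

from .model import GeneRule, MetabolicModel, Metabolite, ModelValidationError, Reaction

__all__ = ["read_model", "write_model", "ModelParseError"]


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed in the declared dialect."""


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from ``path`` in ``format`` ("json" or "sbml").

    With ``format=None`` the format is inferred from the file suffix
    (".json" vs ".xml"/".sbml").  The returned model satisfies all
    structural invariants; bounds and the objective are preserved exactly.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "json":
        model = _read_json(path)
    elif fmt in ("sbml", "sbml_fbc_subset"):
        model = _read_sbml(path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    model.validate()
    return model


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write ``model`` to ``path``; round-trips through :func:`read_model`."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "json":
        _write_json(model, path)
    elif fmt in ("sbml", "sbml_fbc_subset"):
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ValueError(f"cannot infer model format from suffix {suffix!r}")


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------


def _read_json(path: Path) -> MetabolicModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path}: invalid JSON: {exc}") from exc
    for key in ("objective", "metabolites", "reactions"):
        if key not in doc:
            raise ModelParseError(f"{path}: missing required element {key!r}")
    model = MetabolicModel(
        model_id=doc.get("id", path.stem),
        genes=doc.get("genes", []),
        objective_reaction_id=doc["objective"],
    )
    for entry in doc["metabolites"]:
        try:
            model.add_metabolite(
                Metabolite(
                    id=entry["id"],
                    name=entry.get("name", ""),
                    formula={k: int(v) for k, v in entry.get("formula", {}).items()},
                    compartment=entry.get("compartment", "c"),
                )
            )
        except (KeyError, ModelValidationError) as exc:
            raise ModelParseError(f"{path}: bad metabolite entry: {exc}") from exc
    for entry in doc["reactions"]:
        try:
            model.add_reaction(
                Reaction(
                    id=entry["id"],
                    name=entry.get("name", ""),
                    stoichiometry={k: float(v) for k, v in entry["stoichiometry"].items()},
                    lower_bound=float(entry["lower_bound"]),
                    upper_bound=float(entry["upper_bound"]),
                    gene_rule=GeneRule.from_string(entry.get("gene_rule", "")),
                    pathway=entry.get("pathway", ""),
                    is_exchange=bool(entry.get("is_exchange", False)),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ModelParseError(f"{path}: bad reaction entry: {exc}") from exc
    return model


def _write_json(model: MetabolicModel, path: Path) -> None:
    doc = {
        "id": model.id,
        "objective": model.objective_reaction_id,
        "genes": list(model.genes),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula,
                "compartment": m.compartment,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_rule": r.gene_rule.to_string(),
                "pathway": r.pathway,
                "is_exchange": r.is_exchange,
            }
            for r in model.reactions.values()
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# SBML-L3-FBC-v2 subset
# ---------------------------------------------------------------------------

_SBML_UNSUPPORTED = ("Rule", "Event", "Constraint", "InitialAssignment")

# SBML SIds must match [A-Za-z_][A-Za-z0-9_]*; ids are namespaced with the
# conventional M_/R_/G_ prefixes on write and stripped on read.


def _sid(prefix: str, raw: str) -> str:
    import re as _re

    return prefix + _re.sub(r"[^A-Za-z0-9_]", "__", raw)


def _strip(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ModelParseError(
                    f"{path}: SBML error at line {err.getLine()}: {err.getMessage()}"
                )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: document contains no <model> element")
    for kind, count in (
        ("Rule", sbml_model.getNumRules()),
        ("Event", sbml_model.getNumEvents()),
        ("Constraint", sbml_model.getNumConstraints()),
        ("InitialAssignment", sbml_model.getNumInitialAssignments()),
    ):
        if count:
            raise ModelParseError(
                f"{path}: unsupported SBML construct <{kind.lower()}> "
                f"(this reader covers the FBC subset only)"
            )
    fbc = sbml_model.getPlugin("fbc")
    if fbc is None:
        raise ModelParseError(f"{path}: missing fbc package (not a FBC model)")

    genes = [
        _strip("G_", fbc.getGeneProduct(i).getIdAttribute())
        for i in range(fbc.getNumGeneProducts())
    ]
    model = MetabolicModel(model_id=sbml_model.getIdAttribute() or path.stem, genes=genes)

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sp_fbc = sp.getPlugin("fbc")
        formula = {}
        if sp_fbc is not None and sp_fbc.isSetChemicalFormula():
            formula = Metabolite.parse_formula(sp_fbc.getChemicalFormula())
        model.add_metabolite(
            Metabolite(
                id=_strip("M_", sp.getIdAttribute()),
                name=sp.getName() or "",
                formula=formula,
                compartment=sp.getCompartment(),
            )
        )

    parameters = {
        sbml_model.getParameter(i).getIdAttribute(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rx_fbc = rx.getPlugin("fbc")
        if rx_fbc is None or not (rx_fbc.isSetLowerFluxBound() and rx_fbc.isSetUpperFluxBound()):
            raise ModelParseError(
                f"{path}: reaction {rx.getIdAttribute()!r} lacks fbc flux bounds"
            )
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            mid = _strip("M_", ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            mid = _strip("M_", ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        gpa = rx_fbc.getGeneProductAssociation()
        rule = GeneRule(_gpa_to_tree(gpa.getAssociation())) if gpa is not None else GeneRule()
        rxn_id = _strip("R_", rx.getIdAttribute())
        model.add_reaction(
            Reaction(
                id=rxn_id,
                name=rx.getName() or "",
                stoichiometry=stoich,
                lower_bound=parameters[rx_fbc.getLowerFluxBound()],
                upper_bound=parameters[rx_fbc.getUpperFluxBound()],
                gene_rule=rule,
                pathway=(rx.getNotesString() and _pathway_from_notes(rx.getNotesString())) or "",
                is_exchange=(
                    rx.getSBOTermID() == "SBO:0000627"
                    or (not rx.isSetSBOTerm() and rxn_id.startswith("EX_"))
                ),
            )
        )

    objective = fbc.getActiveObjective()
    if objective is None or objective.getNumFluxObjectives() != 1:
        raise ModelParseError(f"{path}: expected exactly one active flux objective")
    model.objective_reaction_id = _strip("R_", objective.getFluxObjective(0).getReaction())
    return model


def _gpa_to_tree(assoc):
    import libsbml

    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        return _strip("G_", assoc.getGeneProduct())
    children = [_gpa_to_tree(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
    if isinstance(assoc, libsbml.FbcAnd):
        return ("and", children)
    if isinstance(assoc, libsbml.FbcOr):
        return ("or", children)
    raise ModelParseError(f"unsupported gene association node {type(assoc).__name__}")


def _pathway_from_notes(notes: str) -> str:
    # pathway tags round-trip through a minimal <p>PATHWAY: ...</p> note
    marker = "PATHWAY:"
    if marker in notes:
        tail = notes.split(marker, 1)[1]
        return tail.split("<")[0].strip()
    return ""


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    fbc = sbml_model.getPlugin("fbc")
    fbc.setStrict(True)

    for comp_id in sorted({m.compartment for m in model.metabolites.values()}):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId(_sid("M_", met.id))
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if met.formula:
            sp.getPlugin("fbc").setChemicalFormula(met.formula_string)

    for gene in model.genes:
        gp = fbc.createGeneProduct()
        gp.setId(_sid("G_", gene))
        gp.setLabel(gene)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        rx = sbml_model.createReaction()
        rx.setId(_sid("R_", rxn.id))
        rx.setName(rxn.name)
        rx.setReversible(rxn.lower_bound < 0)
        rx.setFast(False)
        # SBO 627 marks exchange pseudo-reactions; 176 ordinary conversions
        rx.setSBOTerm("SBO:0000627" if rxn.is_exchange else "SBO:0000176")
        if rxn.pathway:
            rx.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">'
                f"<p>PATHWAY: {rxn.pathway}</p></body>"
            )
        for mid, coef in rxn.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(_sid("M_", mid))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rx_fbc = rx.getPlugin("fbc")
        rx_fbc.setLowerFluxBound(bound_param(rxn.lower_bound))
        rx_fbc.setUpperFluxBound(bound_param(rxn.upper_bound))
        if not rxn.gene_rule.is_empty:
            from .model import GeneRule

            def prefix_tree(node):
                if isinstance(node, str):
                    return _sid("G_", node)
                return (node[0], [prefix_tree(c) for c in node[1]])

            prefixed = GeneRule(prefix_tree(rxn.gene_rule.tree))
            gpa = rx_fbc.createGeneProductAssociation()
            gpa.setAssociation(prefixed.to_string(), True, False)

    objective = fbc.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    flux_obj = objective.createFluxObjective()
    flux_obj.setReaction(_sid("R_", model.objective_reaction_id))
    flux_obj.setCoefficient(1.0)
    fbc.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")
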