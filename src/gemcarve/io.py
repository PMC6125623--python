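"""Model serialization: SBML (FBC v2 and legacy COBRA dialect) and JSON.

The native JSON dialect exists because hand-writing SBML in tests is
error-prone; it is a direct transcription of the in-memory model. SBML is
written through libSBML. Reaction kind, subsystem and free-form annotation
key-value pairs are carried in SBML notes so both dialects round-trip them.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import libsbml

from .core import (
    DEFAULT_MAX_FLUX,
    GPRExpression,
    Medium,
    Metabolite,
    Model,
    Reaction,
    ReactionKind,
    formula_to_string,
    parse_formula,
    parse_gpr,
)

__all__ = ["read_model", "write_model", "ModelFormatError", "DIALECTS"]

DIALECTS = ("sbml-fbc2", "sbml-cobra", "native-json")

# keys used internally in SBML notes; everything else round-trips as
# opaque annotation
_RESERVED_NOTE_KEYS = {
    "KIND",
    "SUBSYSTEM",
    "GENE_ASSOCIATION",
    "FORMULA",
    "CHARGE",
    "EXTRACELLULAR",
}


class ModelFormatError(ValueError):
    """Unreadable or invalid model file; message carries line context."""


# ---------------------------------------------------------------------------
# notes helpers
# ---------------------------------------------------------------------------


def _notes_string(pairs: dict[str, str]) -> str:
    body = "".join(f"<p>{k}: {v}</p>" for k, v in pairs.items())
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'


_NOTE_LINE = re.compile(r"<p>\s*([^<:]+?)\s*:\s*(.*?)\s*</p>", re.S)


def _parse_notes(node: "libsbml.SBase") -> dict[str, str]:
    if not node.isSetNotes():
        return {}
    return {
        key: value for key, value in _NOTE_LINE.findall(node.getNotesString())
    }


def _set_notes(node: "libsbml.SBase", pairs: dict[str, str]) -> None:
    if pairs:
        node.setNotes(_notes_string(pairs))


def _split_annotation(notes: dict[str, str]) -> dict[str, str]:
    return {k: v for k, v in notes.items() if k not in _RESERVED_NOTE_KEYS}


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------


def _model_to_dict(model: Model) -> dict:
    return {
        "id": model.id,
        "compartments": model.compartments,
        "extracellular": model.extracellular,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": formula_to_string(m.formula) if m.formula is not None else None,
                "charge": m.charge,
                "annotation": m.annotation,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lb": r.lb,
                "ub": r.ub,
                "gpr": r.gpr.to_string(),
                "kind": r.kind.value,
                "subsystem": r.subsystem,
                "annotation": r.annotation,
            }
            for r in model.reactions.values()
        ],
        "objective": model.objective,
        "annotation": model.annotation,
    }


def _model_from_dict(data: dict) -> Model:
    model = Model(
        data["id"],
        compartments=data.get("compartments", {}),
        extracellular=data.get("extracellular", "e"),
        annotation=data.get("annotation", {}),
    )
    for entry in data.get("metabolites", []):
        formula = entry.get("formula")
        model.add_metabolite(
            Metabolite(
                id=entry["id"],
                name=entry.get("name", ""),
                compartment=entry.get("compartment", "c"),
                formula=parse_formula(formula) if formula is not None else None,
                charge=int(entry.get("charge", 0)),
                annotation=dict(entry.get("annotation", {})),
            )
        )
    for entry in data.get("reactions", []):
        model.add_reaction(
            Reaction(
                id=entry["id"],
                name=entry.get("name", ""),
                stoichiometry={k: float(v) for k, v in entry["stoichiometry"].items()},
                lb=float(entry.get("lb", -DEFAULT_MAX_FLUX)),
                ub=float(entry.get("ub", DEFAULT_MAX_FLUX)),
                gpr=parse_gpr(entry.get("gpr", "")),
                kind=ReactionKind(entry.get("kind", "enzymatic")),
                subsystem=entry.get("subsystem", ""),
                annotation=dict(entry.get("annotation", {})),
            )
        )
    model.objective = data.get("objective")
    return model


# ---------------------------------------------------------------------------
# SBML common
# ---------------------------------------------------------------------------


def _check_sbml_errors(doc: "libsbml.SBMLDocument", path: str) -> None:
    errors = []
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            errors.append(f"line {err.getLine()}: {err.getMessage().strip()}")
    if errors:
        raise ModelFormatError(f"invalid SBML in {path}: " + "; ".join(errors[:5]))


def _dnf_from_association(assoc, gene_labels: dict[str, str]) -> list[set[str]]:
    if assoc is None:
        return []
    if isinstance(assoc, libsbml.GeneProductRef):
        gid = assoc.getGeneProduct()
        return [{gene_labels.get(gid, gid)}]
    if isinstance(assoc, libsbml.FbcAnd):
        terms = [
            _dnf_from_association(assoc.getAssociation(i), gene_labels)
            for i in range(assoc.getNumAssociations())
        ]
        result = [set()]
        for term in terms:
            result = [a | b for a in result for b in term]
        return result
    if isinstance(assoc, libsbml.FbcOr):
        result: list[set[str]] = []
        for i in range(assoc.getNumAssociations()):
            result.extend(
                _dnf_from_association(assoc.getAssociation(i), gene_labels)
            )
        return result
    raise ModelFormatError(f"unsupported GPR association node: {assoc}")


def _gene_sid(gene: str) -> str:
    sid = re.sub(r"[^A-Za-z0-9_]", "_", gene)
    if not re.match(r"[A-Za-z_]", sid):
        sid = "G_" + sid
    return sid


# ---------------------------------------------------------------------------
# SBML FBC v2 writer / reader
# ---------------------------------------------------------------------------


def _write_sbml_fbc2(model: Model, path: str) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id or "model")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)

    notes = dict(model.annotation)
    notes["EXTRACELLULAR"] = model.extracellular
    _set_notes(sbml_model, notes)

    for comp_id, comp_name in model.compartments.items():
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setName(comp_name or comp_id)
        comp.setConstant(True)
        comp.setSize(1.0)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        splug.setCharge(met.charge)
        if met.formula is not None:
            splug.setChemicalFormula(formula_to_string(met.formula))
        _set_notes(sp, dict(met.annotation))

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"bnd_{len(bound_params)}"
            param = sbml_model.createParameter()
            param.setId(pid)
            param.setValue(value)
            param.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    genes_seen: set[str] = set()
    for rxn in model.reactions.values():
        sr = sbml_model.createReaction()
        sr.setId(rxn.id)
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.lb < 0)
        sr.setFast(False)
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(met_id)
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lb))
        rplug.setUpperFluxBound(bound_param(rxn.ub))
        if not rxn.gpr.is_empty:
            for gene in rxn.gpr.genes:
                if gene not in genes_seen:
                    genes_seen.add(gene)
                    gp = mplug.createGeneProduct()
                    gp.setId(_gene_sid(gene))
                    gp.setLabel(gene)
            gpa = rplug.createGeneProductAssociation()
            complexes = sorted(rxn.gpr.complexes, key=lambda c: sorted(c))
            if len(complexes) == 1:
                _build_association(gpa, complexes[0])
            else:
                or_node = gpa.createOr()
                for cplx in complexes:
                    _build_association(or_node, cplx)
        rxn_notes = dict(rxn.annotation)
        rxn_notes["KIND"] = rxn.kind.value
        if rxn.subsystem:
            rxn_notes["SUBSYSTEM"] = rxn.subsystem
        _set_notes(sr, rxn_notes)

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    if model.objective is not None:
        fo = objective.createFluxObjective()
        fo.setReaction(model.objective)
        fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def _build_association(parent, cplx: frozenset[str]) -> None:
    genes = sorted(cplx)
    if len(genes) == 1:
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(_gene_sid(genes[0]))
    else:
        and_node = parent.createAnd()
        for gene in genes:
            ref = and_node.createGeneProductRef()
            ref.setGeneProduct(_gene_sid(gene))


def _read_sbml_fbc2(doc: "libsbml.SBMLDocument", path: str) -> Model:
    sbml_model = doc.getModel()
    mplug = sbml_model.getPlugin("fbc")
    model_notes = _parse_notes(sbml_model)
    model = Model(
        sbml_model.getId() or Path(path).stem,
        extracellular=model_notes.get("EXTRACELLULAR", "e"),
        annotation=_split_annotation(model_notes),
    )
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        model.add_compartment(comp.getId(), comp.getName())

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        charge = 0
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = parse_formula(splug.getChemicalFormula())
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name=sp.getName(),
                compartment=sp.getCompartment(),
                formula=formula,
                charge=charge,
                annotation=_split_annotation(_parse_notes(sp)),
            )
        )

    gene_labels = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    def param_value(pid: str, default: float) -> float:
        param = sbml_model.getParameter(pid)
        return param.getValue() if param is not None else default

    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb = -DEFAULT_MAX_FLUX if sr.getReversible() else 0.0
        ub = DEFAULT_MAX_FLUX
        gpr = GPRExpression()
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = param_value(rplug.getLowerFluxBound(), lb)
            if rplug.isSetUpperFluxBound():
                ub = param_value(rplug.getUpperFluxBound(), ub)
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                dnf = _dnf_from_association(gpa.getAssociation(), gene_labels)
                gpr = GPRExpression.from_complexes(dnf)
        notes = _parse_notes(sr)
        model.add_reaction(
            Reaction(
                id=sr.getId(),
                name=sr.getName(),
                stoichiometry=stoich,
                lb=lb,
                ub=ub,
                gpr=gpr,
                kind=ReactionKind(notes.get("KIND", "enzymatic")),
                subsystem=notes.get("SUBSYSTEM", ""),
                annotation=_split_annotation(notes),
            )
        )

    if mplug is not None:
        objective = mplug.getActiveObjective()
        if objective is not None and objective.getNumFluxObjectives() > 0:
            model.objective = objective.getFluxObjective(0).getReaction()
    return model


# ---------------------------------------------------------------------------
# legacy COBRA dialect (SBML Level 2, notes-encoded GPRs)
# ---------------------------------------------------------------------------


def _write_sbml_cobra(model: Model, path: str) -> None:
    doc = libsbml.SBMLDocument(2, 4)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id or "model")
    notes = dict(model.annotation)
    notes["EXTRACELLULAR"] = model.extracellular
    if model.objective is not None:
        notes["OBJECTIVE"] = model.objective
    _set_notes(sbml_model, notes)

    for comp_id, comp_name in model.compartments.items():
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setName(comp_name or comp_id)
        comp.setSize(1.0)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        met_notes = dict(met.annotation)
        if met.formula is not None:
            met_notes["FORMULA"] = formula_to_string(met.formula)
        met_notes["CHARGE"] = str(met.charge)
        _set_notes(sp, met_notes)

    for rxn in model.reactions.values():
        sr = sbml_model.createReaction()
        sr.setId(rxn.id)
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.lb < 0)
        for met_id, coeff in rxn.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coeff))
        kl = sr.createKineticLaw()
        kl.setMath(libsbml.parseFormula("FLUX_VALUE"))
        for pid, value in (
            ("LOWER_BOUND", rxn.lb),
            ("UPPER_BOUND", rxn.ub),
            ("OBJECTIVE_COEFFICIENT", 1.0 if rxn.id == model.objective else 0.0),
            ("FLUX_VALUE", 0.0),
        ):
            param = kl.createParameter()
            param.setId(pid)
            param.setValue(value)
        rxn_notes = dict(rxn.annotation)
        rxn_notes["GENE_ASSOCIATION"] = rxn.gpr.to_string()
        rxn_notes["KIND"] = rxn.kind.value
        if rxn.subsystem:
            rxn_notes["SUBSYSTEM"] = rxn.subsystem
        _set_notes(sr, rxn_notes)

    libsbml.writeSBMLToFile(doc, str(path))


def _read_sbml_cobra(doc: "libsbml.SBMLDocument", path: str) -> Model:
    sbml_model = doc.getModel()
    model_notes = _parse_notes(sbml_model)
    model = Model(
        sbml_model.getId() or Path(path).stem,
        extracellular=model_notes.get("EXTRACELLULAR", "e"),
        annotation={
            k: v
            for k, v in _split_annotation(model_notes).items()
            if k != "OBJECTIVE"
        },
    )
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        model.add_compartment(comp.getId(), comp.getName())

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        notes = _parse_notes(sp)
        formula = parse_formula(notes["FORMULA"]) if "FORMULA" in notes else None
        charge = int(notes.get("CHARGE", "0"))
        model.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name=sp.getName(),
                compartment=sp.getCompartment(),
                formula=formula,
                charge=charge,
                annotation=_split_annotation(notes),
            )
        )

    objective_id = model_notes.get("OBJECTIVE")
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        lb = -DEFAULT_MAX_FLUX if sr.getReversible() else 0.0
        ub = DEFAULT_MAX_FLUX
        kl = sr.getKineticLaw()
        if kl is not None:
            for pid, setter in (("LOWER_BOUND", "lb"), ("UPPER_BOUND", "ub")):
                param = kl.getParameter(pid)
                if param is not None:
                    if setter == "lb":
                        lb = param.getValue()
                    else:
                        ub = param.getValue()
            obj_param = kl.getParameter("OBJECTIVE_COEFFICIENT")
            if obj_param is not None and obj_param.getValue() != 0 and objective_id is None:
                objective_id = sr.getId()
        notes = _parse_notes(sr)
        model.add_reaction(
            Reaction(
                id=sr.getId(),
                name=sr.getName(),
                stoichiometry=stoich,
                lb=lb,
                ub=ub,
                gpr=parse_gpr(notes.get("GENE_ASSOCIATION", "")),
                kind=ReactionKind(notes.get("KIND", "enzymatic")),
                subsystem=notes.get("SUBSYSTEM", ""),
                annotation=_split_annotation(notes),
            )
        )
    model.objective = objective_id
    return model


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def write_model(model: Model, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "native-json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1))
    elif dialect == "sbml-fbc2":
        _write_sbml_fbc2(model, str(path))
    elif dialect == "sbml-cobra":
        _write_sbml_cobra(model, str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def read_model(path: str | Path, dialect: str | None = None) -> Model:
    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"no such file: {path}")
    dialect = dialect or _infer_dialect(path)
    if dialect == "native-json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelFormatError(
                f"invalid JSON in {path} at line {exc.lineno}: {exc.msg}"
            ) from exc
        return _model_from_dict(data)
    doc = libsbml.readSBMLFromFile(str(path))
    _check_sbml_errors(doc, str(path))
    if doc.getModel() is None:
        raise ModelFormatError(f"{path}: file contains no SBML model")
    if dialect == "sbml-cobra" or (
        dialect is None and doc.getLevel() < 3
    ):
        return _read_sbml_cobra(doc, str(path))
    if dialect == "sbml-fbc2" or doc.getLevel() >= 3:
        return _read_sbml_fbc2(doc, str(path))
    return _read_sbml_cobra(doc, str(path))


def _infer_dialect(path: Path) -> str | None:
    if path.suffix == ".json":
        return "native-json"
    if path.suffix in (".xml", ".sbml"):
        if path.exists():
            doc = libsbml.readSBMLFromFile(str(path))
            if doc.getModel() is not None:
                return "sbml-fbc2" if doc.getLevel() >= 3 else "sbml-cobra"
        return "sbml-fbc2"
    return None
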