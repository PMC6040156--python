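"""SBML Level 3 (+fbc v2) reading and writing via python-libsbml.

The mapping follows community conventions: ``M_``/``R_``/``G_`` id
prefixes, flux bounds as fbc parameters, the objective as an fbc objective,
GPRs as fbc gene-product associations, and database annotations as
controlled-vocabulary ``bqbiol:is`` resource URIs of the form
``https://identifiers.org/<database>/<identifier>``; unknown databases are
preserved verbatim, which keeps the round trip lossless. Auxiliary fields
with no SBML home (genome position, protein length/mass/sequence, the
subsystem, the ATP-maintenance designation) travel in notes as
``key: value`` lines, again a common convention.
"""

from __future__ import annotations

import re
import warnings
from typing import Dict, Optional

import libsbml

from ..gpr import GprExpression, parse_gpr
from ..model import Gene, MetabolicModel, Metabolite, Reaction

__all__ = ["read_sbml", "write_sbml", "SbmlError"]


class SbmlError(ValueError):
    """Malformed or unsupported SBML input."""


_SID = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_IDENTIFIERS_PREFIXES = ("https://identifiers.org/", "http://identifiers.org/")


def _check_sid(raw: str, what: str) -> str:
    if not _SID.match(raw):
        raise SbmlError(f"{what} id {raw!r} is not a valid SBML SId")
    return raw


def _notes_string(pairs: Dict[str, object]) -> Optional[str]:
    lines = [
        f"<p>{k}: {v}</p>" for k, v in pairs.items() if v is not None and v != ""
    ]
    if not lines:
        return None
    return (
        '<body xmlns="http://www.w3.org/1999/xhtml">' + "".join(lines) + "</body>"
    )


def _parse_notes(sbase) -> Dict[str, str]:
    out: Dict[str, str] = {}
    if not sbase.isSetNotes():
        return out
    text = sbase.getNotesString()
    for m in re.finditer(r"<p>\s*([^<:]+?)\s*:\s*(.*?)\s*</p>", text, re.S):
        out[m.group(1)] = m.group(2)
    return out


def _write_annotations(sbase, annotations: Dict[str, str]) -> None:
    if not annotations:
        return
    if not sbase.isSetMetaId():
        sbase.setMetaId(f"meta_{sbase.getId()}")
    for db, ident in annotations.items():
        cv = libsbml.CVTerm()
        cv.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
        cv.setBiologicalQualifierType(libsbml.BQB_IS)
        cv.addResource(f"https://identifiers.org/{db}/{ident}")
        sbase.addCVTerm(cv)


def _read_annotations(sbase) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for i in range(sbase.getNumCVTerms()):
        cv = sbase.getCVTerm(i)
        for j in range(cv.getNumResources()):
            uri = cv.getResourceURI(j)
            for prefix in _IDENTIFIERS_PREFIXES:
                if uri.startswith(prefix):
                    rest = uri[len(prefix):]
                    db, _, ident = rest.partition("/")
                    if db and ident:
                        out[db] = ident
                    break
    return out


# --- GPR <-> fbc association ---------------------------------------------


def _build_association(parent, gpr: GprExpression) -> None:
    """Recursively build an fbc association under ``parent``."""
    if gpr.op == "gene":
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(f"G_{gpr.gene}")
        return
    node = parent.createAnd() if gpr.op == "and" else parent.createOr()
    for child in gpr.children:
        _build_association(node, child)


def _association_to_gpr(assoc) -> GprExpression:
    if assoc is None:
        return GprExpression.ALWAYS_ACTIVE
    if isinstance(assoc, libsbml.GeneProductRef):
        gid = assoc.getGeneProduct()
        return GprExpression(op="gene", gene=_strip_prefix(gid, "G_"))
    op = "and" if isinstance(assoc, libsbml.FbcAnd) else "or"
    children = tuple(
        _association_to_gpr(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    )
    return GprExpression(op=op, children=children)


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


# --- writing ---------------------------------------------------------------


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Serialize a model as SBML Level 3 Version 1 with fbc version 2."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_check_sid(re.sub(r"\W", "_", model.id) or "model", "model"))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    notes = _notes_string({"atp_maintenance": model.atp_maintenance_id})
    if notes:
        sm.setNotes(notes)

    compartments = sorted({m.compartment for m in model.metabolites.values()})
    for cid in compartments or ["c"]:
        comp = sm.createCompartment()
        comp.setId(_check_sid(cid, "compartment"))
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId("M_" + _check_sid(met.id, "metabolite"))
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if met.formula:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(int(met.charge))
        _write_annotations(sp, met.annotations)

    for gene in model.genes.values():
        gp = mplug.createGeneProduct()
        gp.setId("G_" + _check_sid(gene.id, "gene"))
        gp.setLabel(gene.id)
        if gene.name:
            gp.setName(gene.name)
        g_notes = _notes_string(
            {
                "genome_start": gene.genome_start,
                "protein_length": gene.protein_length,
                "protein_mass": gene.protein_mass,
                "protein_sequence": gene.protein_sequence,
            }
        )
        if g_notes:
            gp.setNotes(g_notes)
        _write_annotations(gp, gene.annotations)

    def bound_parameter(value: float, pid: str) -> str:
        p = sm.createParameter()
        p.setId(pid)
        p.setValue(float(value))
        p.setConstant(True)
        return pid

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        rid = _check_sid(rxn.id, "reaction")
        sr.setId("R_" + rid)
        sr.setName(rxn.name)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_parameter(rxn.lower_bound, f"lb_{rid}"))
        rplug.setUpperFluxBound(bound_parameter(rxn.upper_bound, f"ub_{rid}"))
        for mid, coeff in rxn.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies("M_" + mid)
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        if not rxn.gpr.is_always_active:
            gpa = rplug.createGeneProductAssociation()
            _build_association(gpa, rxn.gpr)
        r_notes = _notes_string({"subsystem": rxn.subsystem})
        if r_notes:
            sr.setNotes(r_notes)
        _write_annotations(sr, rxn.annotations)

    if model.objective_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + model.objective_id)
        fo.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise SbmlError(f"could not write SBML to {path!r}")


# --- reading ---------------------------------------------------------------


def read_sbml(path: str) -> MetabolicModel:
    """Load an SBML Level 3 (+fbc) model.

    Malformed XML raises :class:`SbmlError` with the parser messages; a
    missing fbc objective only warns, and the model loads with its
    objective unset.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage().strip()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise SbmlError(f"SBML parse error in {path!r}: " + "; ".join(msgs[:3]))
    sm = doc.getModel()
    if sm is None:
        raise SbmlError(f"no model element in {path!r}")
    mplug = sm.getPlugin("fbc")

    model = MetabolicModel(id=sm.getId() or "model")
    model_notes = _parse_notes(sm)

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.add_metabolite(
            Metabolite(
                id=_strip_prefix(sp.getId(), "M_"),
                name=sp.getName(),
                compartment=sp.getCompartment(),
                formula=formula,
                charge=charge,
                annotations=_read_annotations(sp),
            )
        )

    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            notes = _parse_notes(gp)
            model.add_gene(
                Gene(
                    id=gp.getLabel() or _strip_prefix(gp.getId(), "G_"),
                    name=gp.getName(),
                    genome_start=(
                        int(notes["genome_start"]) if "genome_start" in notes else None
                    ),
                    protein_length=(
                        int(notes["protein_length"])
                        if "protein_length" in notes
                        else None
                    ),
                    protein_mass=(
                        float(notes["protein_mass"])
                        if "protein_mass" in notes
                        else None
                    ),
                    protein_sequence=notes.get("protein_sequence"),
                    annotations=_read_annotations(gp),
                )
            )

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rplug = sr.getPlugin("fbc")
        stoich: Dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()

        lb, ub = -1000.0, 1000.0
        gpr = GprExpression.ALWAYS_ACTIVE
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                p = sm.getParameter(rplug.getLowerFluxBound())
                if p is not None:
                    lb = p.getValue()
            if rplug.isSetUpperFluxBound():
                p = sm.getParameter(rplug.getUpperFluxBound())
                if p is not None:
                    ub = p.getValue()
            if rplug.isSetGeneProductAssociation():
                gpr = _association_to_gpr(
                    rplug.getGeneProductAssociation().getAssociation()
                )
        notes = _parse_notes(sr)
        model.add_reaction(
            Reaction(
                id=_strip_prefix(sr.getId(), "R_"),
                name=sr.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                subsystem=notes.get("subsystem", ""),
                annotations=_read_annotations(sr),
            )
        )

    objective_set = False
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(mplug.getActiveObjectiveId()) or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective_id = _strip_prefix(
                obj.getFluxObjective(0).getReaction(), "R_"
            )
            objective_set = True
    if not objective_set:
        warnings.warn(f"SBML file {path!r} declares no objective; left unset")

    maint = model_notes.get("atp_maintenance")
    if maint and maint != "None" and maint in model.reactions:
        model.atp_maintenance_id = maint
    return model
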