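"""Domain types for a genome-scale metabolic model and core operations.

The central object is :class:`MetabolicModel`: metabolites, reactions with
stoichiometry/bounds/GPR, genes, a biomass objective and a non-growth ATP
maintenance reaction. Coefficient sign convention throughout: negative =
consumed (substrate), positive = produced, matching the steady-state
formulation ``S v = 0`` with uptake exchange fluxes negative.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd

from .gpr import GprExpression, evaluate_gpr

__all__ = [
    "Metabolite",
    "Gene",
    "Reaction",
    "MetabolicModel",
    "Finding",
    "ModelError",
    "MetaboliteMatch",
    "MatchResult",
    "build_stoichiometric_matrix",
    "apply_gene_knockout",
    "validate_model",
    "match_metabolites",
    "parse_formula",
]


class ModelError(ValueError):
    """Structural defect in a model or an operation's inputs."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    charge: Optional[int] = None
    annotations: Dict[str, str] = field(default_factory=dict)


@dataclass
class Gene:
    """A metabolic gene, identified by its locus tag (SCO-style)."""

    id: str
    name: str = ""
    genome_start: Optional[int] = None
    annotations: Dict[str, str] = field(default_factory=dict)
    protein_length: Optional[int] = None
    protein_mass: Optional[float] = None
    protein_sequence: Optional[str] = None


@dataclass
class Reaction:
    """A reaction with stoichiometry, flux bounds (mmol·gDW⁻¹·h⁻¹) and a GPR.

    An exchange reaction is a boundary pseudo-reaction with exactly one
    metabolite; negative flux is uptake, positive is secretion.
    """

    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: GprExpression = GprExpression.ALWAYS_ACTIVE
    subsystem: str = ""
    annotations: Dict[str, str] = field(default_factory=dict)

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    genes: Dict[str, Gene] = field(default_factory=dict)
    objective_id: Optional[str] = None
    atp_maintenance_id: Optional[str] = None

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def add_metabolite(self, met: Metabolite) -> None:
        if not met.id:
            raise ModelError("metabolite id must be non-empty")
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_gene(self, gene: Gene) -> None:
        if gene.id in self.genes:
            raise ModelError(f"duplicate gene id {gene.id!r}")
        self.genes[gene.id] = gene

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def reactions_for_gene(self, gene_id: str) -> List[str]:
        """Reaction ids whose GPR mentions ``gene_id`` (declaration order)."""
        return [
            r.id for r in self.reactions.values() if gene_id in r.gpr.genes()
        ]


# --- stoichiometric matrix ----------------------------------------------


def build_stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense stoichiometric matrix S (metabolites × reactions).

    Rows follow metabolite declaration order, columns reaction declaration
    order; entry (i, j) is the coefficient of metabolite i in reaction j.
    """
    met_index = {mid: i for i, mid in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions.values()):
        for mid, coeff in rxn.stoichiometry.items():
            if mid not in met_index:
                raise ModelError(
                    f"reaction {rxn.id!r} references undeclared metabolite {mid!r}"
                )
            S[met_index[mid], j] = coeff
    return S


# --- gene knockouts ------------------------------------------------------


def apply_gene_knockout(model: MetabolicModel, genes: Iterable[str]) -> MetabolicModel:
    """Return a copy with reactions disabled whose GPR fails without ``genes``.

    A reaction whose GPR evaluates False with the given genes absent gets
    both bounds set to zero; all other reactions are untouched. The input
    model is not mutated.
    """
    knocked = set(genes)
    unknown = knocked - set(model.genes)
    if unknown:
        raise ModelError(f"unknown gene id(s): {sorted(unknown)}")
    out = model.copy()
    for rxn in out.reactions.values():
        if not evaluate_gpr(rxn.gpr, knocked):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


# --- validation -----------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse an elemental formula like ``C6H12O6`` into element counts."""
    counts: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ModelError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ModelError(f"cannot parse formula {formula!r}")
    return counts


@dataclass
class Finding:
    severity: str  # "error" | "warning" | "info"
    location: str
    message: str


def _elemental_imbalance(model: MetabolicModel, rxn: Reaction) -> Optional[Dict[str, float]]:
    """Net element counts of a reaction, or None if any formula is missing."""
    balance: Dict[str, float] = {}
    for mid, coeff in rxn.stoichiometry.items():
        met = model.metabolites.get(mid)
        if met is None or not met.formula:
            return None
        for elem, n in parse_formula(met.formula).items():
            balance[elem] = balance.get(elem, 0.0) + coeff * n
    return {e: v for e, v in balance.items() if abs(v) > 1e-9}


def validate_model(model: MetabolicModel) -> List[Finding]:
    """Structural and annotation-quality audit of a model.

    All problems are reported as findings (never raised): dangling
    references, inverted bounds, missing objective, duplicate ids, elemental
    imbalance where all formulas are known (exchange reactions exempt), plus
    info-level annotation-coverage statistics.
    """
    findings: List[Finding] = []

    for rxn in model.reactions.values():
        if not rxn.stoichiometry:
            findings.append(Finding("error", rxn.id, "empty stoichiometry"))
        for mid in rxn.stoichiometry:
            if mid not in model.metabolites:
                findings.append(
                    Finding("error", rxn.id, f"undeclared metabolite {mid!r}")
                )
        if rxn.lower_bound > rxn.upper_bound:
            findings.append(
                Finding(
                    "error",
                    rxn.id,
                    f"lower_bound {rxn.lower_bound} > upper_bound {rxn.upper_bound}",
                )
            )
        for gid in rxn.gpr.genes():
            if gid not in model.genes:
                findings.append(Finding("error", rxn.id, f"undeclared gene {gid!r}"))

    if model.objective_id is None:
        findings.append(Finding("warning", "model", "no objective reaction set"))
    elif model.objective_id not in model.reactions:
        findings.append(
            Finding("error", "model", f"objective {model.objective_id!r} not a reaction")
        )
    if (
        model.atp_maintenance_id is not None
        and model.atp_maintenance_id not in model.reactions
    ):
        findings.append(
            Finding(
                "error",
                "model",
                f"ATP maintenance {model.atp_maintenance_id!r} not a reaction",
            )
        )

    for gene in model.genes.values():
        if gene.genome_start is not None and gene.genome_start < 1:
            findings.append(
                Finding("error", gene.id, f"genome_start {gene.genome_start} < 1")
            )

    # mass balance: only internal reactions where every participant has a formula
    for rxn in model.reactions.values():
        if rxn.is_exchange:
            continue
        imbalance = _elemental_imbalance(model, rxn)
        if imbalance:
            findings.append(
                Finding("error", rxn.id, f"elemental imbalance: {imbalance}")
            )

    # annotation coverage statistics (informational)
    n_m = len(model.metabolites) or 1
    n_g = len(model.genes) or 1
    for db in ("inchi", "chebi", "pubchem"):
        frac = sum(
            1
            for m in model.metabolites.values()
            if any(k.lower() == db for k in m.annotations)
        ) / n_m
        findings.append(
            Finding("info", "model", f"metabolite {db} annotation coverage: {frac:.2f}")
        )
    frac_uni = sum(
        1
        for g in model.genes.values()
        if any(k.lower() == "uniprot" for k in g.annotations)
    ) / n_g
    findings.append(
        Finding("info", "model", f"gene uniprot annotation coverage: {frac_uni:.2f}")
    )
    return findings


# --- metabolite identifier matching --------------------------------------

_MATCH_PRIORITY = ("inchi", "chebi", "pubchem", "name")


@dataclass
class MetaboliteMatch:
    feature_index: int
    metabolite_ids: List[str]  # >1 means ambiguous (same species, compartments)
    matched_by: Optional[str]  # identifier class that won, None if unmatched

    @property
    def ambiguous(self) -> bool:
        return len(self.metabolite_ids) > 1


@dataclass
class MatchResult:
    matches: List[MetaboliteMatch]
    coverage: float  # matched features / total features


def match_metabolites(model: MetabolicModel, features: pd.DataFrame) -> MatchResult:
    """Match annotated metabolomics features onto model metabolites.

    Each feature is matched by identifier priority InChI > ChEBI > PubChem >
    exact name (case-insensitive). When two model metabolites share the
    winning identifier (the same chemical species in two compartments), the
    feature matches all of them and is flagged ambiguous.
    """
    if features is None or len(features) == 0:
        raise ModelError("empty feature table")
    cols = {c.lower(): c for c in features.columns}
    if not any(k in cols for k in _MATCH_PRIORITY):
        raise ModelError(
            f"feature table needs at least one of columns {_MATCH_PRIORITY}"
        )

    # index model metabolites by each identifier class
    index: Dict[str, Dict[str, List[str]]] = {k: {} for k in _MATCH_PRIORITY}
    for met in model.metabolites.values():
        for db, val in met.annotations.items():
            db_l = db.lower()
            if db_l in index and val:
                index[db_l].setdefault(str(val).strip().lower(), []).append(met.id)
        index["name"].setdefault(met.name.strip().lower(), []).append(met.id)

    matches: List[MetaboliteMatch] = []
    n_matched = 0
    for i, (_, row) in enumerate(features.iterrows()):
        hit: Optional[MetaboliteMatch] = None
        for key in _MATCH_PRIORITY:
            if key not in cols:
                continue
            val = row[cols[key]]
            if pd.isna(val) or str(val).strip() == "":
                continue
            ids = index[key].get(str(val).strip().lower())
            if ids:
                hit = MetaboliteMatch(i, sorted(set(ids)), key)
                break
        if hit is None:
            hit = MetaboliteMatch(i, [], None)
        else:
            n_matched += 1
        matches.append(hit)
    return MatchResult(matches=matches, coverage=n_matched / len(features))
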