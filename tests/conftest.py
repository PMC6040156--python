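"""Shared fixtures: the toy model, small LP fixture networks, and an
independent cobra-based solver used as the oracle for FBA results."""

from __future__ import annotations

import numpy as np
import pytest

from fluxkit import MetabolicModel, Metabolite, Reaction, make_toy_model
from fluxkit.gpr import parse_gpr


def small_model(mets, rxns, objective=None, maintenance=None) -> MetabolicModel:
    """Compact builder: mets = ids, rxns = (id, stoich, lb, ub[, gpr])."""
    m = MetabolicModel(id="fixture")
    for mid in mets:
        m.add_metabolite(Metabolite(mid, name=mid))
    for spec in rxns:
        rid, stoich, lb, ub = spec[:4]
        gpr = parse_gpr(spec[4]) if len(spec) > 4 else parse_gpr("")
        for g in gpr.genes():
            if g not in m.genes:
                from fluxkit import Gene

                m.add_gene(Gene(g))
        m.add_reaction(
            Reaction(rid, stoichiometry=dict(stoich), lower_bound=lb,
                     upper_bound=ub, gpr=gpr)
        )
    m.objective_id = objective
    m.atp_maintenance_id = maintenance
    return m


def chain_model() -> MetabolicModel:
    """EX_A (uptake 10) -> A -> 0.5 B -> EX_B; optimum on EX_B is 5."""
    return small_model(
        ["A", "B"],
        [
            ("EX_A", {"A": -1}, -10, 1000),
            ("CONV", {"A": -1, "B": 0.5}, 0, 1000),
            ("EX_B", {"B": -1}, 0, 1000),
        ],
        objective="EX_B",
    )


def two_route_model() -> MetabolicModel:
    """A -> B directly (1 reaction) or via C (2 reactions); pFBA should
    pick the direct route."""
    return small_model(
        ["A", "B", "C"],
        [
            ("EX_A", {"A": -1}, -10, 1000),
            ("DIRECT", {"A": -1, "B": 1}, 0, 1000),
            ("VIA1", {"A": -1, "C": 1}, 0, 1000),
            ("VIA2", {"C": -1, "B": 1}, 0, 1000),
            ("EX_B", {"B": -1}, 0, 1000),
        ],
        objective="EX_B",
    )


def diamond_model() -> MetabolicModel:
    """Reversible diamond with an energy-coupled branch."""
    return small_model(
        ["A", "B", "C", "D"],
        [
            ("EX_A", {"A": -1}, -4, 1000),
            ("R1", {"A": -1, "B": 1}, -1000, 1000),
            ("R2", {"B": -1, "C": 2}, 0, 1000),
            ("R3", {"A": -1, "C": 1}, 0, 3),
            ("R4", {"C": -1, "D": 1}, 0, 1000),
            ("EX_D", {"D": -1}, 0, 1000),
        ],
        objective="EX_D",
    )


def dead_end_model() -> MetabolicModel:
    """Objective cut off from the only carbon source (optimum 0)."""
    return small_model(
        ["A", "B", "C"],
        [
            ("EX_A", {"A": -1}, -10, 1000),
            ("R1", {"A": -1, "B": 1}, 0, 1000),
            ("EX_B", {"B": -1}, 0, 1000),
            ("EX_C", {"C": -1}, 0, 1000),
        ],
        objective="EX_C",
    )


FIXTURE_MODELS = {
    "chain": chain_model,
    "two_route": two_route_model,
    "diamond": diamond_model,
    "dead_end": dead_end_model,
}


def to_cobra(model: MetabolicModel):
    """Convert to a cobra model (used purely as an independent solver)."""
    import cobra

    cm = cobra.Model(model.id)
    for met in model.metabolites.values():
        cmet = cobra.Metabolite(met.id, name=met.name,
                                compartment=met.compartment or "c")
        cm.add_metabolites([cmet])
    rxns = []
    for rxn in model.reactions.values():
        cr = cobra.Reaction(rxn.id, name=rxn.name,
                            lower_bound=rxn.lower_bound,
                            upper_bound=rxn.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for rxn in model.reactions.values():
        cm.reactions.get_by_id(rxn.id).add_metabolites(
            {cm.metabolites.get_by_id(m): c for m, c in rxn.stoichiometry.items()}
        )
        gpr_str = rxn.gpr.to_string()
        if gpr_str:
            cm.reactions.get_by_id(rxn.id).gene_reaction_rule = gpr_str
    if model.objective_id:
        cm.objective = model.objective_id
    return cm


@pytest.fixture(scope="session")
def toy_model() -> MetabolicModel:
    return make_toy_model("mini-coelicolor", seed=0)


@pytest.fixture(params=sorted(FIXTURE_MODELS))
def fixture_model(request) -> MetabolicModel:
    return FIXTURE_MODELS[request.param]()
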