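"""Flux balance analysis as linear programming.

FBA maximizes (or minimizes) the flux through an objective reaction subject
to the steady-state constraint S·v = 0 and the flux bounds lb ≤ v ≤ ub.
Parsimonious FBA (pFBA) then minimizes the total absolute flux Σ|v| among
vectors attaining the FBA optimum, which removes the arbitrariness of
degenerate alternate optima; all downstream per-reaction analyses use pFBA
vectors for that reason.

The linear programs are solved with the HiGHS solver behind
``scipy.optimize.linprog``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, ModelError, build_stoichiometric_matrix

__all__ = [
    "FluxSolution",
    "set_medium",
    "fix_measured_rates",
    "solve_fba",
    "solve_pfba",
    "LP_TOLERANCE",
    "FEASIBILITY_TOLERANCE",
]

LP_TOLERANCE = 1e-9  # primal/dual feasibility tolerance handed to HiGHS
FEASIBILITY_TOLERANCE = 1e-6  # post-hoc |S v| check
PFBA_OPTIMALITY_FRACTION = 1e-6  # v_obj >= (1 - this) * FBA optimum


@dataclass
class FluxSolution:
    """One steady-state flux vector with its objective value and status.

    ``objective_value`` is the flux through the objective reaction; for the
    biomass objective this is the specific growth rate μ in h⁻¹. ``status``
    is ``"optimal"``, ``"infeasible"`` or ``"unbounded"``.
    """

    fluxes: Dict[str, float] = field(default_factory=dict)
    objective_value: float = float("nan")
    status: str = "infeasible"
    objective_id: str | None = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def total_flux(self) -> float:
        """Σ|v| over all reactions."""
        return float(sum(abs(v) for v in self.fluxes.values()))

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


# --- condition-specific constraints --------------------------------------


def set_medium(
    model: MetabolicModel, medium: Mapping[str, float]
) -> MetabolicModel:
    """Constrain uptake to the given medium composition.

    Exchanges named in ``medium`` get ``lower_bound = -max_uptake`` (uptake
    is negative flux); every other exchange gets ``lower_bound = 0`` so that
    exometabolites absent from the medium cannot be taken up. Secretion
    stays open: every exchange keeps ``upper_bound >= 0`` so by-products can
    always leave. Returns a modified copy.
    """
    out = model.copy()
    exchange_ids = {r.id for r in out.exchanges()}
    for rid in medium:
        if rid not in exchange_ids:
            raise ModelError(f"{rid!r} is not an exchange reaction")
    for rxn in out.reactions.values():
        if not rxn.is_exchange:
            continue
        if rxn.id in medium:
            rate = float(medium[rxn.id])
            if rate < 0:
                raise ModelError(f"medium uptake rate for {rxn.id!r} must be >= 0")
            rxn.lower_bound = -rate
        else:
            rxn.lower_bound = 0.0
        rxn.upper_bound = max(rxn.upper_bound, 0.0)
    return out


def fix_measured_rates(
    model: MetabolicModel,
    measured: Mapping[str, float],
    band: float = 0.0,
) -> MetabolicModel:
    """Pin named exchange fluxes to measured rates within a relative band.

    Each exchange in ``measured`` gets bounds ``rate*(1±band)`` ordered
    correctly; ``band = 0`` produces an equality constraint. Rates follow
    the sign convention (uptake negative, production positive). An
    over-constrained combination shows up as an infeasible solve, not as an
    exception here.
    """
    if band < 0:
        raise ModelError("band must be >= 0")
    out = model.copy()
    for rid, rate in measured.items():
        if rid not in out.reactions:
            raise ModelError(f"unknown reaction {rid!r}")
        rxn = out.reactions[rid]
        if not rxn.is_exchange:
            raise ModelError(f"{rid!r} is not an exchange reaction")
        lo, hi = rate * (1 + band), rate * (1 - band)
        if lo > hi:
            lo, hi = hi, lo
        rxn.lower_bound, rxn.upper_bound = float(lo), float(hi)
    return out


# --- solvers --------------------------------------------------------------


def _statuses(res) -> str:
    return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "infeasible")


def _solve_lp(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": LP_TOLERANCE,
            "dual_feasibility_tolerance": LP_TOLERANCE,
        },
    )


def solve_fba(
    model: MetabolicModel,
    objective: str | None = None,
    direction: str = "max",
) -> FluxSolution:
    """Solve {optimize v_objective subject to S·v = 0, lb ≤ v ≤ ub}.

    ``objective`` defaults to the model's objective reaction (biomass).
    Infeasibility and unboundedness are reported via ``status``; the flux
    map is empty in those cases.
    """
    objective = objective or model.objective_id
    if objective is None or objective not in model.reactions:
        raise ModelError(f"objective reaction {objective!r} not in model")
    if direction not in ("max", "min"):
        raise ModelError(f"direction must be 'max' or 'min', got {direction!r}")

    rxn_ids = list(model.reactions)
    S = build_stoichiometric_matrix(model)
    n = len(rxn_ids)
    c = np.zeros(n)
    c[rxn_ids.index(objective)] = -1.0 if direction == "max" else 1.0
    bounds = [
        (r.lower_bound, r.upper_bound) for r in model.reactions.values()
    ]
    res = _solve_lp(c, S, np.zeros(S.shape[0]), bounds)
    status = _statuses(res)
    if status != "optimal":
        return FluxSolution(status=status, objective_id=objective)
    v = res.x
    return FluxSolution(
        fluxes={rid: float(v[i]) for i, rid in enumerate(rxn_ids)},
        objective_value=float(v[rxn_ids.index(objective)]),
        status="optimal",
        objective_id=objective,
    )


def solve_pfba(model: MetabolicModel, objective: str | None = None) -> FluxSolution:
    """Parsimonious FBA: minimize Σ|v| at the FBA optimum.

    The FBA optimum is first computed, then enforced as
    ``v_obj ≥ (1 − 1e−6)·optimum`` (a strict equality is numerically
    brittle) while total absolute flux is minimized via auxiliary variables
    ``t_i ≥ |v_i|``. The reported ``objective_value`` is the realized flux
    through the objective, equal to the FBA optimum within tolerance.
    """
    objective = objective or model.objective_id
    fba = solve_fba(model, objective=objective, direction="max")
    if not fba.ok:
        return fba

    rxn_ids = list(model.reactions)
    n = len(rxn_ids)
    S = build_stoichiometric_matrix(model)
    m = S.shape[0]
    obj_idx = rxn_ids.index(objective)

    # variables x = [v (n), t (n)]; minimize sum(t)
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([S, np.zeros((m, n))])
    b_eq = np.zeros(m)

    # t_i >= |v_i|  <=>  v_i - t_i <= 0 and -v_i - t_i <= 0
    I = np.eye(n)
    A_ub = np.vstack(
        [
            np.hstack([I, -I]),
            np.hstack([-I, -I]),
        ]
    )
    b_ub = np.zeros(2 * n)

    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions.values()]
    # pin the objective near its optimum (direction-aware margin)
    opt = fba.objective_value
    margin = PFBA_OPTIMALITY_FRACTION * max(abs(opt), 1.0)
    lo = max(bounds[obj_idx][0], opt - margin)
    bounds[obj_idx] = (lo, bounds[obj_idx][1])
    bounds += [(0.0, None)] * n

    res = _solve_lp(c, A_eq, b_eq, bounds, A_ub=A_ub, b_ub=b_ub)
    status = _statuses(res)
    if status != "optimal":  # pragma: no cover - guarded by the FBA solve
        return FluxSolution(status=status, objective_id=objective)
    v = res.x[:n]
    return FluxSolution(
        fluxes={rid: float(v[i]) for i, rid in enumerate(rxn_ids)},
        objective_value=float(v[obj_idx]),
        status="optimal",
        objective_id=objective,
    )
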