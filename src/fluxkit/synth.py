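"""Synthetic data with known ground truth.

Everything the pipeline consumes can be generated here: a small feasible
genome-scale-style model ("mini-coelicolor"), chemostat steady-state series
produced from a known GAM/NGAM pair, a fermenter time course consistent
with a known growth-rate profile (including a metabolic-switch drop and
antibiotic production turning on afterwards), and expression matrices that
are controllably (anti-)correlated with the predicted fluxes.

All generators are pure functions of their configuration and seed.

The toy network is a deliberate miniature of an actinomycete central
metabolism: glucose/glutamate/phosphate/O2 exchanges, lumped glycolysis,
lumped TCA, an NADH-dehydrogenase step carrying two isoenzyme genes on an
OR rule (the nuo/ndh situation), an ATP-hydrolysis maintenance reaction,
a biomass reaction with a growth-associated ATP term, and two secondary
metabolite pathways standing in for γ-actinorhodin and undecylprodigiosin.

Designed energetics (used by tests as the hand-derived oracle):
full oxidation of one glucose yields 24 ATP (2 glycolytic + 2 TCA +
10 NADH × 2); diverting the biomass precursor drain costs 72 ATP per unit
growth; so with glucose uptake q the optimum is
``μ = (24 q − NGAM) / (72 + GAM + precursor ATP)``.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import ChemostatRecord, OmicsMatrix, TimeCoursePoint
from .fba import FluxSolution, solve_fba, solve_pfba
from .gpr import parse_gpr
from .model import Gene, MetabolicModel, Metabolite, ModelError, Reaction

__all__ = [
    "TRUE_GAM",
    "TRUE_NGAM",
    "make_toy_model",
    "make_chemostat_data",
    "make_fermenter_timecourse",
    "make_expression_data",
    "default_mu_profile",
    "toy_optimum",
]

# Maintenance truth values used as the toy model's defaults: the
# growth-associated maintenance (mmol ATP per gDW biomass) and the
# non-growth-associated maintenance (mmol ATP per gDW per h).
TRUE_GAM = 75.79
TRUE_NGAM = 2.64

# biomass precursor drains (mmol per gDW)
_BIOMASS_PYR = 8.0
_BIOMASS_GLU = 2.0
_BIOMASS_PI = 0.5

#: ATP a unit of biomass forgoes by consuming precursors instead of
#: oxidizing them: 8 pyruvate × (1 TCA ATP + 4 NADH × 2 ATP) = 72.
_PRECURSOR_ATP_COST = _BIOMASS_PYR * 9.0
_ATP_PER_GLUCOSE = 24.0


def toy_optimum(glucose_uptake: float, gam: float = TRUE_GAM, ngam: float = TRUE_NGAM) -> float:
    """Closed-form optimal growth rate of the toy model on glucose alone."""
    return (_ATP_PER_GLUCOSE * glucose_uptake - ngam) / (
        _PRECURSOR_ATP_COST + gam
    )


_GENES: List[Tuple[str, str, int]] = [
    ("SCO1001", "glycolysis subunit alpha", 1_090_000),
    ("SCO1002", "glycolysis subunit beta", 1_091_500),
    ("SCO2180", "TCA cycle lumped enzyme", 2_350_000),
    ("SCO4142", "phosphate transporter", 4_540_000),
    ("SCO4562", "NADH dehydrogenase I (nuo-type)", 4_990_000),
    ("SCO4563", "NADH dehydrogenase II (ndh-type)", 4_992_000),
    ("SCO5001", "glucose permease", 5_450_000),
    ("SCO5002", "glutamate permease", 5_452_000),
    ("SCO5083", "actinorhodin exporter", 5_510_000),
    ("SCO5087", "actinorhodin synthase I", 5_513_000),
    ("SCO5088", "actinorhodin synthase II", 5_514_500),
    ("SCO5877", "prodiginine synthase I", 6_400_000),
    ("SCO5878", "prodiginine synthase II", 6_401_800),
    ("SCO5881", "prodiginine exporter", 6_405_000),
]


def make_toy_model(preset: str = "mini-coelicolor", seed: int = 0) -> MetabolicModel:
    """Build the ~21-reaction toy model with GAM/NGAM defaults baked in.

    The construction is deterministic (identical for any seed); the seed is
    accepted for interface uniformity with the other generators.
    """
    if preset != "mini-coelicolor":
        raise ModelError(f"unknown preset {preset!r}")
    m = MetabolicModel(id=f"{preset}")

    mets = [
        Metabolite("glc_e", "D-glucose", "e", "C6H12O6", 0,
                   {"ChEBI": "CHEBI:17634", "PubChem": "5793",
                    "KEGG": "C00031",
                    "InChI": "InChI=1S/C6H12O6/c7-1-2-3(8)4(9)5(10)6(11)12-2/h2-11H,1H2"}),
        Metabolite("glc_c", "D-glucose", "c", "C6H12O6", 0,
                   {"ChEBI": "CHEBI:17634", "KEGG": "C00031"}),
        Metabolite("glu_e", "L-glutamate", "e", "C5H9NO4", 0,
                   {"ChEBI": "CHEBI:16015", "PubChem": "33032"}),
        Metabolite("glu_c", "L-glutamate", "c", "C5H9NO4", 0,
                   {"ChEBI": "CHEBI:16015"}),
        Metabolite("pi_e", "phosphate", "e", "HO4P", -2, {"ChEBI": "CHEBI:43474"}),
        Metabolite("pi_c", "phosphate", "c", "HO4P", -2, {"ChEBI": "CHEBI:43474"}),
        Metabolite("o2_e", "dioxygen", "e", "O2", 0, {"ChEBI": "CHEBI:15379"}),
        Metabolite("o2_c", "dioxygen", "c", "O2", 0, {"ChEBI": "CHEBI:15379"}),
        Metabolite("co2_e", "carbon dioxide", "e", "CO2", 0,
                   {"ChEBI": "CHEBI:16526", "PubChem": "280"}),
        Metabolite("co2_c", "carbon dioxide", "c", "CO2", 0, {"ChEBI": "CHEBI:16526"}),
        Metabolite("pyr_c", "pyruvate", "c", "C3H3O3", -1,
                   {"ChEBI": "CHEBI:15361",
                    "InChI": "InChI=1S/C3H4O3/c1-2(4)3(5)6/h1H3,(H,5,6)/p-1"}),
        # cofactors left formula-free: the lumped reactions are intentionally
        # not elementally balanced and must be exempt from the balance audit
        Metabolite("atp_c", "ATP", "c", None, None, {"ChEBI": "CHEBI:30616"}),
        Metabolite("adp_c", "ADP", "c", None, None, {"ChEBI": "CHEBI:456216"}),
        Metabolite("nad_c", "NAD+", "c", None, None, {"ChEBI": "CHEBI:57540"}),
        Metabolite("nadh_c", "NADH", "c", None, None, {"ChEBI": "CHEBI:57945"}),
        Metabolite("act_c", "gamma-actinorhodin (toy)", "c", None, None,
                   {"ChEBI": "CHEBI:2437"}),
        Metabolite("act_e", "gamma-actinorhodin (toy)", "e", None, None,
                   {"ChEBI": "CHEBI:2437"}),
        Metabolite("red_c", "undecylprodigiosin (toy)", "c", None, None,
                   {"ChEBI": "CHEBI:78642"}),
        Metabolite("red_e", "undecylprodigiosin (toy)", "e", None, None,
                   {"ChEBI": "CHEBI:78642"}),
    ]
    for met in mets:
        m.add_metabolite(met)

    for gid, name, start in _GENES:
        m.add_gene(Gene(gid, name=name, genome_start=start,
                        annotations={"UniProt": f"Q{abs(hash(gid)) % 90000 + 10000}"}))

    def rxn(rid, stoich, lb, ub, gpr="", name="", subsystem=""):
        m.add_reaction(
            Reaction(rid, name=name or rid, stoichiometry=stoich,
                     lower_bound=lb, upper_bound=ub, gpr=parse_gpr(gpr),
                     subsystem=subsystem)
        )

    # exchanges (uptake negative)
    rxn("EX_glc_e", {"glc_e": -1}, -2.0, 1000, name="glucose exchange",
        subsystem="exchange")
    rxn("EX_glu_e", {"glu_e": -1}, -5.0, 1000, name="glutamate exchange",
        subsystem="exchange")
    rxn("EX_pi_e", {"pi_e": -1}, -10.0, 1000, name="phosphate exchange",
        subsystem="exchange")
    rxn("EX_o2_e", {"o2_e": -1}, -40.0, 1000, name="oxygen exchange",
        subsystem="exchange")
    rxn("EX_co2_e", {"co2_e": -1}, 0.0, 1000, name="CO2 exchange",
        subsystem="exchange")
    rxn("EX_act_e", {"act_e": -1}, 0.0, 1000, name="actinorhodin exchange",
        subsystem="exchange")
    rxn("EX_red_e", {"red_e": -1}, 0.0, 1000, name="prodiginine exchange",
        subsystem="exchange")

    # transport
    rxn("GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000, "SCO5001",
        name="glucose transport", subsystem="transport")
    rxn("GLUt", {"glu_e": -1, "glu_c": 1}, 0, 1000, "SCO5002",
        name="glutamate transport", subsystem="transport")
    rxn("PIt", {"pi_e": -1, "pi_c": 1}, 0, 1000, "SCO4142",
        name="phosphate transport", subsystem="transport")
    rxn("O2t", {"o2_e": -1, "o2_c": 1}, 0, 1000,
        name="oxygen diffusion", subsystem="transport")
    rxn("CO2t", {"co2_c": -1, "co2_e": 1}, 0, 1000,
        name="CO2 diffusion", subsystem="transport")

    # central metabolism (lumped)
    rxn("GLYC",
        {"glc_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2,
         "pyr_c": 2, "atp_c": 2, "nadh_c": 2},
        0, 1000, "SCO1001 and SCO1002",
        name="glycolysis (lumped)", subsystem="central")
    rxn("TCA",
        {"pyr_c": -1, "nad_c": -4, "adp_c": -1, "pi_c": -1,
         "co2_c": 3, "nadh_c": 4, "atp_c": 1},
        0, 1000, "SCO2180",
        name="pyruvate oxidation + TCA (lumped)", subsystem="central")
    rxn("NADHDH",
        {"nadh_c": -1, "o2_c": -0.5, "adp_c": -2, "pi_c": -2,
         "nad_c": 1, "atp_c": 2},
        0, 1000, "SCO4562 or SCO4563",
        name="NADH dehydrogenase + oxidative phosphorylation",
        subsystem="oxidative phosphorylation")

    # ATP maintenance (non-growth-associated); lower bound enforces NGAM
    rxn("ATPM", {"atp_c": -1, "adp_c": 1, "pi_c": 1}, TRUE_NGAM, 1000,
        name="ATP maintenance requirement", subsystem="maintenance")

    # biomass with GAM ATP hydrolysis folded in
    rxn("BIOMASS",
        {"pyr_c": -_BIOMASS_PYR, "glu_c": -_BIOMASS_GLU,
         "pi_c": -_BIOMASS_PI + TRUE_GAM, "atp_c": -TRUE_GAM,
         "adp_c": TRUE_GAM},
        0, 1000, name="biomass", subsystem="biomass")

    # secondary metabolite pathways
    rxn("ACTS",
        {"pyr_c": -3, "atp_c": -6, "act_c": 1, "co2_c": 2,
         "adp_c": 6, "pi_c": 6},
        0, 1000, "SCO5087 and SCO5088",
        name="actinorhodin biosynthesis (lumped)",
        subsystem="secondary metabolism")
    rxn("ACTt", {"act_c": -1, "act_e": 1}, 0, 1000, "SCO5083",
        name="actinorhodin export", subsystem="transport")
    rxn("REDS",
        {"pyr_c": -2, "glu_c": -1, "atp_c": -4, "red_c": 1, "co2_c": 1,
         "adp_c": 4, "pi_c": 4},
        0, 1000, "SCO5877 and SCO5878",
        name="prodiginine biosynthesis (lumped)",
        subsystem="secondary metabolism")
    rxn("REDt", {"red_c": -1, "red_e": 1}, 0, 1000, "SCO5881",
        name="prodiginine export", subsystem="transport")

    m.objective_id = "BIOMASS"
    m.atp_maintenance_id = "ATPM"
    return m


# --- chemostat series -----------------------------------------------------

_CHEMOSTAT_EXCHANGES = ("EX_glc_e", "EX_o2_e", "EX_co2_e", "EX_act_e")


def make_chemostat_data(
    model: MetabolicModel,
    gam: float = TRUE_GAM,
    ngam: float = TRUE_NGAM,
    dilution_rates: Sequence[float] = (0.03, 0.06, 0.09, 0.12, 0.15, 0.18, 0.21),
    sigma: float = 0.0,
    seed: int = 0,
) -> List[ChemostatRecord]:
    """Simulate glucose-limited chemostat steady states.

    For each dilution rate D the model (with maintenance set to the given
    GAM/NGAM truth) is fixed to μ = D and solved minimizing glucose uptake;
    the resulting glucose, O2, CO2 and actinorhodin exchange fluxes form the
    record. Gaussian noise of standard deviation ``sigma`` is added to the
    rates, truncated so uptake stays ≤ 0 and production ≥ 0.

    The seven-condition default mirrors a typical published chemostat design.
    """
    from .maintenance import set_maintenance  # local import, avoids a cycle

    rng = np.random.default_rng(seed)
    base = set_maintenance(model, gam, ngam)
    records: List[ChemostatRecord] = []
    for i, d in enumerate(dilution_rates):
        if d <= 0:
            raise ModelError(f"dilution rate must be > 0, got {d}")
        cond = base.copy()
        bio = cond.reactions[cond.objective_id]
        bio.lower_bound = bio.upper_bound = float(d)
        glc = cond.reactions["EX_glc_e"]
        glc.lower_bound = -1000.0
        sol = solve_fba(cond, objective="EX_glc_e", direction="max")
        if not sol.ok:
            dmax = _max_growth(base)
            raise ModelError(
                f"dilution rate {d} infeasible; feasible range is (0, {dmax:.4f}]"
            )
        rates: Dict[str, float] = {}
        for ex in _CHEMOSTAT_EXCHANGES:
            rates[ex] = _noised(sol.fluxes[ex], sigma, rng)
        records.append(
            ChemostatRecord(dilution_rate=float(d), exchange_rates=rates,
                            condition=f"D{i + 1}")
        )
    return records


def _noised(value: float, sigma: float, rng: np.random.Generator) -> float:
    """Gaussian measurement noise, truncated so the rate keeps its sign.

    A rate that is exactly zero stays zero: noise cannot invent uptake of a
    product (or secretion of a pure substrate) that the culture never
    exchanged, which would over-constrain downstream solves.
    """
    if sigma <= 0 or value == 0.0:
        return 0.0 if value == 0.0 else value
    noised = value + rng.normal(0.0, sigma)
    return min(noised, 0.0) if value < 0 else max(noised, 0.0)


def _max_growth(model: MetabolicModel) -> float:
    probe = model.copy()
    probe.reactions["EX_glc_e"].lower_bound = -1000.0
    sol = solve_fba(probe)
    return sol.objective_value if sol.ok else 0.0


# --- fermenter time course ------------------------------------------------

DEFAULT_SWITCH_TIME = 34.0  # h, end of the metabolic-switch decline
DEFAULT_ANTIBIOTIC_ONSET = 38.0  # h, antibiotics on once mu is flat again


def default_mu_profile(t: float) -> float:
    """Reference growth-rate profile (h⁻¹): exponential phase at 0.22, a
    metabolic-switch decline between 30 h and 34 h, stationary 0.04 after.
    Piecewise linear with kinks on the default 2-h grid, so that interval-
    mean integration of the profile is exact."""
    if t < 30.0:
        return 0.22
    if t < DEFAULT_SWITCH_TIME:
        return 0.22 + (0.04 - 0.22) * (t - 30.0) / (DEFAULT_SWITCH_TIME - 30.0)
    return 0.04


_TIMECOURSE_EXCHANGES = ("EX_glc_e", "EX_o2_e", "EX_co2_e", "EX_pi_e", "EX_glu_e")


def make_fermenter_timecourse(
    model: MetabolicModel,
    mu_profile: Callable[[float], float] = default_mu_profile,
    time_grid: Optional[Sequence[float]] = None,
    sigma: float = 0.0,
    seed: int = 0,
    x0: float = 0.1,
    act_rate: float = 0.05,
    red_rate: float = 0.03,
    antibiotic_onset: float = DEFAULT_ANTIBIOTIC_ONSET,
) -> Tuple[List[TimeCoursePoint], np.ndarray, List[FluxSolution]]:
    """Simulate a fermenter run with a known growth-rate profile.

    At each grid time the model is fixed to μ(t) (antibiotic exchanges
    forced to their production rates once ``t ≥ antibiotic_onset``,
    emulating the post-switch activation of secondary metabolism) and
    solved with parsimonious FBA minimizing glucose uptake. The emitted
    point carries the five constraint exchanges (glucose, O2, CO2,
    phosphate, glutamate), the antibiotic production rates, and the true
    biomass integrated exponentially from ``x0``.

    Returns ``(points, true_biomass, pfba_solutions)``; noise ``sigma`` is
    applied to the exchange rates only, never to the biomass curve.
    """
    from .dynamics import integrate_biomass

    rng = np.random.default_rng(seed)
    if time_grid is None:
        time_grid = np.linspace(20.0, 58.0, 20)
    times = [float(t) for t in time_grid]
    if x0 <= 0:
        raise ModelError("x0 must be > 0")

    mus = [float(mu_profile(t)) for t in times]
    if any(mu < 0 for mu in mus):
        raise ModelError("mu_profile must be >= 0 on the grid")
    biomass = integrate_biomass(times, mus, x0)

    points: List[TimeCoursePoint] = []
    solutions: List[FluxSolution] = []
    for i, t in enumerate(times):
        mu = mus[i]
        cond = model.copy()
        bio = cond.reactions[cond.objective_id]
        bio.lower_bound = bio.upper_bound = mu
        cond.reactions["EX_glc_e"].lower_bound = -1000.0
        on = t >= antibiotic_onset
        a, r = (act_rate, red_rate) if on else (0.0, 0.0)
        for ex, rate in (("EX_act_e", a), ("EX_red_e", r)):
            cond.reactions[ex].lower_bound = rate
            cond.reactions[ex].upper_bound = rate
        sol = solve_pfba(cond, objective="EX_glc_e")
        if not sol.ok:
            raise ModelError(f"growth rate {mu} infeasible at t = {t}")
        solutions.append(sol)

        rates: Dict[str, float] = {}
        for ex in _TIMECOURSE_EXCHANGES:
            rates[ex] = _noised(sol.fluxes[ex], sigma, rng)
        points.append(
            TimeCoursePoint(
                time=t,
                biomass=float(biomass[i]),
                exchange_rates=rates,
                antibiotic_rates={"act": a, "red": r},
            )
        )
    return points, biomass, solutions


# --- expression matrices --------------------------------------------------


def make_expression_data(
    flux_series: Dict[str, np.ndarray],
    sigma: float = 0.0,
    anti_fraction: float = 0.0,
    seed: int = 0,
    times: Optional[Sequence[float]] = None,
) -> OmicsMatrix:
    """Generate a gene × time expression matrix tied to predicted fluxes.

    Each gene's base series is a positive affine transform ``a·flux + b``
    (a, b seeded) of its flux series; a seeded fraction ``anti_fraction`` of
    the genes with non-constant flux gets the slope negated (the
    anti-correlated cohort, emulating regulatory decoupling such as the
    nuo-operon case). Gaussian noise ``sigma`` is added, then each series is
    shifted to be strictly positive (a per-gene constant shift, which
    preserves all correlations).

    Ground truth lands in ``matrix.meta``: ``anti_genes`` is the exact set
    of negated genes.
    """
    import pandas as pd

    if not flux_series:
        raise ModelError("empty flux series map")
    if not 0.0 <= anti_fraction <= 1.0:
        raise ModelError(f"anti_fraction must be in [0, 1], got {anti_fraction}")
    rng = np.random.default_rng(seed)
    genes = list(flux_series)
    n_t = len(next(iter(flux_series.values())))
    if times is None:
        times = list(range(n_t))

    eligible = [g for g in genes if np.ptp(np.asarray(flux_series[g], float)) > 1e-12]
    n_anti = int(round(anti_fraction * len(eligible)))
    anti = set(rng.choice(eligible, size=n_anti, replace=False)) if n_anti else set()

    rows = np.empty((len(genes), n_t))
    for i, g in enumerate(genes):
        flux = np.asarray(flux_series[g], dtype=float)
        a = rng.uniform(0.5, 2.0)
        b = rng.uniform(0.0, 5.0)
        if g in anti:
            a = -a
        series = a * flux + b + (rng.normal(0.0, sigma, n_t) if sigma > 0 else 0.0)
        lo = series.min()
        if lo < 1.0:
            series = series - lo + 1.0  # constant shift: correlations unchanged
        rows[i] = series
    frame = pd.DataFrame(rows, index=genes, columns=[float(t) for t in times])
    return OmicsMatrix(
        frame,
        meta={"anti_genes": sorted(str(g) for g in anti), "sigma": sigma,
              "anti_fraction": anti_fraction, "seed": seed},
    )
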