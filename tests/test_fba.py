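"""FBA/pFBA solver behaviour, medium handling, and oracle equivalence
against an independent solver (cobra) on all small fixture networks."""

import numpy as np
import pytest

from fluxkit import (
    ModelError,
    build_stoichiometric_matrix,
    fix_measured_rates,
    set_medium,
    solve_fba,
    solve_pfba,
)
from fluxkit.synth import toy_optimum

from conftest import FIXTURE_MODELS, chain_model, to_cobra, two_route_model


class TestSetMedium:
    def test_glucose_only_closes_other_uptakes(self, toy_model):
        m = set_medium(toy_model, {"EX_glc_e": 10.0, "EX_o2_e": 40.0,
                                   "EX_pi_e": 10.0, "EX_glu_e": 5.0})
        m2 = set_medium(toy_model, {"EX_glc_e": 10.0})
        assert m2.reactions["EX_glc_e"].lower_bound == -10.0
        assert m2.reactions["EX_glu_e"].lower_bound == 0.0
        assert m2.reactions["EX_o2_e"].lower_bound == 0.0
        # secretion always open
        assert all(r.upper_bound >= 0 for r in m2.exchanges())
        assert m.reactions["EX_glu_e"].lower_bound == -5.0

    def test_empty_medium_starves_the_model(self, toy_model):
        """No carbon source means no biomass: with the maintenance floor
        relaxed the optimum is exactly zero; with the floor in place the
        cell cannot even pay its upkeep and the LP is infeasible."""
        relaxed = toy_model.copy()
        relaxed.reactions["ATPM"].lower_bound = 0.0
        m = set_medium(relaxed, {})
        assert solve_fba(m).objective_value == pytest.approx(0.0, abs=1e-8)
        assert solve_fba(set_medium(toy_model, {})).status == "infeasible"

    def test_non_exchange_key_rejected(self, toy_model):
        with pytest.raises(ModelError, match="not an exchange"):
            set_medium(toy_model, {"GLYC": 1.0})


class TestFixMeasuredRates:
    def test_zero_band_is_equality(self, toy_model):
        m = fix_measured_rates(toy_model, {"EX_glc_e": -5.0}, band=0.0)
        assert m.reactions["EX_glc_e"].lower_bound == -5.0
        assert m.reactions["EX_glc_e"].upper_bound == -5.0

    def test_band_widens_symmetrically_ordered(self, toy_model):
        m = fix_measured_rates(toy_model, {"EX_glc_e": -5.0}, band=0.05)
        assert m.reactions["EX_glc_e"].lower_bound == pytest.approx(-5.25)
        assert m.reactions["EX_glc_e"].upper_bound == pytest.approx(-4.75)

    def test_negative_band_rejected(self, toy_model):
        with pytest.raises(ModelError, match="band"):
            fix_measured_rates(toy_model, {"EX_glc_e": -5.0}, band=-0.1)

    def test_contradictory_rates_yield_infeasible_status(self, toy_model):
        # forcing CO2 production with all uptakes shut is impossible
        m = fix_measured_rates(
            toy_model,
            {"EX_glc_e": 0.0, "EX_glu_e": 0.0, "EX_co2_e": 5.0},
            band=0.0,
        )
        sol = solve_fba(m)
        assert sol.status == "infeasible"
        assert sol.fluxes == {}


class TestSolveFba:
    def test_hand_solvable_chain(self):
        """EX_A uptake 10 through a 0.5-yield conversion gives optimum 5."""
        sol = solve_fba(chain_model())
        assert sol.objective_value == pytest.approx(5.0, abs=1e-9)

    def test_all_uptakes_closed_zero_growth(self, toy_model):
        m = toy_model.copy()
        m.reactions["ATPM"].lower_bound = 0.0  # no upkeep demand to strand
        for ex in m.exchanges():
            ex.lower_bound = max(ex.lower_bound, 0.0)
        assert solve_fba(m).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_toy_model_matches_designed_yield(self, toy_model):
        sol = solve_fba(toy_model)
        assert sol.objective_value == pytest.approx(toy_optimum(2.0), rel=1e-9)

    @pytest.mark.parametrize("name", sorted(FIXTURE_MODELS))
    def test_optimum_matches_independent_solver(self, name):
        """On every fixture network the optimum agrees with cobra
        (a second, independent LP implementation) to 1e-6."""
        model = FIXTURE_MODELS[name]()
        mine = solve_fba(model)
        oracle = to_cobra(model).optimize()
        assert mine.status == "optimal" == oracle.status
        assert mine.objective_value == pytest.approx(
            oracle.objective_value, abs=1e-6
        )

    def test_steady_state_residual(self, toy_model):
        sol = solve_fba(toy_model)
        S = build_stoichiometric_matrix(toy_model)
        v = np.array([sol.fluxes[r] for r in toy_model.reactions])
        assert np.max(np.abs(S @ v)) < 1e-6

    def test_fluxes_within_bounds(self, toy_model):
        sol = solve_fba(toy_model)
        for rid, rxn in toy_model.reactions.items():
            assert rxn.lower_bound - 1e-6 <= sol.fluxes[rid] <= rxn.upper_bound + 1e-6

    @pytest.mark.parametrize("k", [0.0, 0.5, 1.0, 2.0])
    def test_uptake_scaling_scales_optimum_linearly(self, toy_model, k):
        base = solve_fba(toy_model).objective_value
        m = toy_model.copy()
        m.reactions["ATPM"].lower_bound = 0.0  # remove the affine NGAM offset
        mu0 = solve_fba(m).objective_value
        for ex in m.exchanges():
            ex.lower_bound *= k
        assert solve_fba(m).objective_value == pytest.approx(k * mu0, rel=1e-6, abs=1e-9)
        assert base <= mu0  # NGAM can only cost growth

    def test_relaxing_bound_never_decreases_optimum(self, toy_model):
        tight = solve_fba(toy_model).objective_value
        m = toy_model.copy()
        m.reactions["EX_glc_e"].lower_bound = -4.0
        assert solve_fba(m).objective_value >= tight - 1e-9

    def test_min_direction(self):
        sol = solve_fba(chain_model(), objective="EX_B", direction="min")
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


class TestSolvePfba:
    def test_prefers_direct_route(self):
        """With a 1-step and a 2-step route to the same product, minimizing
        total flux puts everything on the direct reaction."""
        sol = solve_pfba(two_route_model())
        assert sol.fluxes["DIRECT"] == pytest.approx(10.0, rel=1e-5)
        assert sol.fluxes["VIA1"] == pytest.approx(0.0, abs=1e-6)
        assert sol.fluxes["VIA2"] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("name", sorted(FIXTURE_MODELS))
    def test_attains_fba_optimum_with_no_more_flux(self, name):
        model = FIXTURE_MODELS[name]()
        fba = solve_fba(model)
        pfba = solve_pfba(model)
        assert pfba.objective_value == pytest.approx(
            fba.objective_value, rel=1e-5, abs=1e-6
        )
        assert pfba.total_flux() <= fba.total_flux() + 1e-6

    def test_repeat_solves_identical(self, toy_model):
        t1 = solve_pfba(toy_model).total_flux()
        t2 = solve_pfba(toy_model).total_flux()
        assert abs(t1 - t2) < 1e-9

    def test_propagates_infeasibility(self, toy_model):
        m = fix_measured_rates(
            toy_model, {"EX_glc_e": 0.0, "EX_glu_e": 0.0, "EX_co2_e": 5.0}, band=0.0
        )
        assert solve_pfba(m).status == "infeasible"
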