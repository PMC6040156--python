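"""GAM/NGAM estimation and the chemostat growth-prediction benchmark."""

import numpy as np
import pytest

from fluxkit import (
    ModelError,
    fit_maintenance,
    maintenance_regression,
    make_chemostat_data,
    set_maintenance,
    solve_fba,
    strip_growth_associated_atp,
    validate_chemostat,
)
from fluxkit.data import ChemostatRecord
from fluxkit.synth import TRUE_GAM, TRUE_NGAM


class TestSetAndStripMaintenance:
    def test_strip_removes_biomass_atp_term(self, toy_model):
        stripped = strip_growth_associated_atp(toy_model)
        bio = stripped.reactions["BIOMASS"].stoichiometry
        assert "atp_c" not in bio
        assert "adp_c" not in bio
        # structural phosphate demand survives the strip
        assert bio["pi_c"] == pytest.approx(-0.5)

    def test_set_maintenance_round_trips(self, toy_model):
        m = set_maintenance(toy_model, 50.0, 1.0)
        assert m.reactions["BIOMASS"].stoichiometry["atp_c"] == pytest.approx(-50.0)
        assert m.reactions["ATPM"].lower_bound == 1.0
        back = set_maintenance(m, TRUE_GAM, TRUE_NGAM)
        assert back.reactions["BIOMASS"].stoichiometry == pytest.approx(
            toy_model.reactions["BIOMASS"].stoichiometry
        )

    def test_raising_maintenance_burden_lowers_growth(self, toy_model):
        """v_ATP demand is monotone: more NGAM means less biomass at fixed
        substrate."""
        mus = []
        for ngam in (0.0, 2.64, 10.0):
            m = set_maintenance(toy_model, TRUE_GAM, ngam)
            mus.append(solve_fba(m).objective_value)
        assert mus[0] > mus[1] > mus[2]


class TestFitMaintenance:
    def test_recovers_truth_from_noiseless_data(self, toy_model):
        """Chemostat series generated with the canonical truth pair
        (GAM 75.79, NGAM 2.64) refits to within 1e-4."""
        records = make_chemostat_data(
            toy_model, gam=TRUE_GAM, ngam=TRUE_NGAM, sigma=0.0, seed=0
        )
        fit = fit_maintenance(toy_model, records)
        assert fit.gam == pytest.approx(TRUE_GAM, abs=1e-4)
        assert fit.ngam == pytest.approx(TRUE_NGAM, abs=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    # truth pairs in the energy-limited regime (GAM above the toy network's
    # carbon-limitation ceiling of 24 ATP per glucose-equivalent), where the
    # chemostat protocol identifies maintenance
    @pytest.mark.parametrize("gam,ngam", [(40.0, 0.5), (120.0, 8.0), (75.79, 2.64)])
    def test_recovery_for_energy_limited_truth_pairs(self, toy_model, gam, ngam):
        records = make_chemostat_data(toy_model, gam=gam, ngam=ngam, sigma=0.0)
        fit = fit_maintenance(toy_model, records)
        assert fit.gam == pytest.approx(gam, abs=1e-6)
        assert fit.ngam == pytest.approx(ngam, abs=1e-6)

    def test_two_records_line_through_points(self, toy_model):
        records = make_chemostat_data(toy_model, dilution_rates=(0.05, 0.15))
        fit = fit_maintenance(toy_model, records)
        assert len(fit.residuals) == 2
        assert np.allclose(fit.residuals, 0.0, atol=1e-9)

    def test_noise_bias_shrinks_with_record_count(self):
        """Monte-Carlo over replicates: with Gaussian-noised v_ATP the
        estimator's bias (and spread) shrinks going from 5 to 50 records."""
        rng = np.random.default_rng(42)
        sigma = 0.5

        def mean_abs_bias(n_records, replicates=200):
            d = np.linspace(0.03, 0.25, n_records)
            biases = np.empty(replicates)
            for k in range(replicates):
                v = TRUE_GAM * d + TRUE_NGAM + rng.normal(0, sigma, n_records)
                fit = maintenance_regression(d, v)
                biases[k] = fit.gam - TRUE_GAM
            return abs(biases.mean()), biases.std()

        bias5, sd5 = mean_abs_bias(5)
        bias50, sd50 = mean_abs_bias(50)
        assert bias50 < bias5
        assert sd50 < sd5

    def test_equal_dilution_rates_rejected(self, toy_model):
        records = make_chemostat_data(toy_model, dilution_rates=(0.1, 0.15))
        for r in records:
            r.dilution_rate = 0.1
        with pytest.raises(ModelError, match="distinct|equal"):
            fit_maintenance(toy_model, records)

    def test_infeasible_condition_names_it(self, toy_model):
        records = make_chemostat_data(toy_model, dilution_rates=(0.05, 0.15))
        # a condition demanding growth with no carbon is impossible
        records[1].exchange_rates["EX_glc_e"] = 0.0
        records[1].exchange_rates["EX_glu_e"] = 0.0
        with pytest.raises(ModelError, match="D2"):
            fit_maintenance(toy_model, records)


class TestValidateChemostat:
    def test_self_consistency_zero_error(self, toy_model):
        """Records simulated from the model itself are predicted with 0%
        average error."""
        records = make_chemostat_data(toy_model, sigma=0.0, seed=0)
        result = validate_chemostat(toy_model, records)
        assert result.average_error_percent == pytest.approx(0.0, abs=1e-6)
        assert result.predicted_mu == pytest.approx(
            [r.dilution_rate for r in records], rel=1e-6
        )

    def test_error_invariant_to_record_order(self, toy_model):
        records = make_chemostat_data(
            toy_model, dilution_rates=(0.1, 0.15, 0.2, 0.25),
            sigma=0.01, seed=3,
        )
        forward = validate_chemostat(toy_model, records, band=0.1)
        backward = validate_chemostat(toy_model, records[::-1], band=0.1)
        assert forward.average_error_percent > 0  # noise must cost something
        assert forward.average_error_percent == pytest.approx(
            backward.average_error_percent, rel=1e-12
        )

    def test_halving_glucose_halves_predicted_growth_nearly(self, toy_model):
        """On the glucose-limited toy model, scaling one record's glucose
        uptake scales that record's prediction linearly (up to the constant
        NGAM offset, removed here)."""
        m = set_maintenance(toy_model, TRUE_GAM, 0.0)
        records = make_chemostat_data(m, gam=TRUE_GAM, ngam=0.0,
                                      dilution_rates=(0.1,))
        halved = ChemostatRecord(
            dilution_rate=records[0].dilution_rate,
            exchange_rates={k: v / 2 for k, v in records[0].exchange_rates.items()},
            condition="half",
        )
        full = validate_chemostat(m, records).predicted_mu[0]
        half = validate_chemostat(m, [halved]).predicted_mu[0]
        assert half == pytest.approx(full / 2, rel=1e-6)

    def test_infeasible_condition_flagged_and_excluded(self, toy_model):
        records = make_chemostat_data(toy_model, dilution_rates=(0.05, 0.15))
        records[0].exchange_rates["EX_co2_e"] = 50.0  # impossible CO2 output
        result = validate_chemostat(toy_model, records)
        assert result.failed_conditions == ["D1"]
        assert len(result.relative_errors) == 1
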