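"""Campaign behavior: redox scenarios, sweeps, strain series, determinism."""

import numpy as np
import pytest

from fucsim.campaigns import (
    ScenarioSpec,
    apply_scenario,
    oxygen_sweep,
    run_redox_scenarios,
    strain_series,
    substrate_ratio_scan,
)
from fucsim.fba import enumerate_vertices_oracle, solve_fba
from fucsim.model import ModelError
from fucsim.synth import build_fuculose_motif


class TestScenarios:
    def test_anaerobic_routes_all_lad_to_pdo(self, extended):
        res = run_redox_scenarios(extended)["anaerobic"]
        table = res.table.set_index("reaction")
        assert table.loc["EX_lad", "flux"] == pytest.approx(-5.0, abs=1e-6)
        assert table.loc["EX_pdo", "flux"] == pytest.approx(5.0, abs=1e-6)
        # robust across the whole optimal face, not just one vertex
        assert table.loc["EX_lad", "fva_max"] == pytest.approx(-5.0, abs=1e-4)
        assert table.loc["EX_pdo", "fva_min"] == pytest.approx(5.0, abs=1e-4)

    def test_anaerobic_fuculose_range_is_zero(self, extended):
        table = run_redox_scenarios(extended)["anaerobic"].table.set_index("reaction")
        assert abs(table.loc["EX_fcl", "fva_min"]) <= 1e-4
        assert abs(table.loc["EX_fcl", "fva_max"]) <= 1e-4

    def test_aerobic_allows_fuculose_at_reduced_growth(self, extended):
        res = run_redox_scenarios(extended)["aerobic"]
        assert res.product_max > 0.1

    def test_unextended_model_rejected(self, mini_core):
        with pytest.raises(ModelError, match="EX_fcl"):
            run_redox_scenarios(mini_core)

    def test_infeasible_scenario_recorded_not_fatal(self, extended):
        broken = extended.copy()
        broken.get_reaction("ATPM").lower_bound = 1e5
        res = run_redox_scenarios(broken)
        assert res["aerobic"].status == "infeasible"
        assert np.isnan(res["aerobic"].growth)

    def test_bound_override_validation(self, extended):
        with pytest.raises(ValueError, match="lb"):
            apply_scenario(extended, ScenarioSpec("bad", {"EX_o2": (1.0, -1.0)}))


class TestOxygenSweep:
    def test_columns_monotone_and_anaerobic_zero(self, extended):
        table = oxygen_sweep(extended)
        growth = table["max_growth"].to_numpy()
        product = table["max_fuculose"].to_numpy()
        assert np.all(np.diff(growth) >= -1e-6)
        assert np.all(np.diff(product) >= -1e-6)
        anaerobic = table[table["o2_lower_bound"] == 0.0].iloc[0]
        assert anaerobic["max_fuculose"] == 0.0
        assert (product > 1e-6).any()

    @pytest.mark.parametrize("fraction", [0.0, 0.25, 0.5, 0.9])
    def test_monotone_for_every_fraction(self, extended, fraction):
        table = oxygen_sweep(extended, biomass_fraction=fraction)
        assert np.all(np.diff(table["max_growth"].to_numpy()) >= -1e-6)
        assert np.all(np.diff(table["max_fuculose"].to_numpy()) >= -1e-6)

    def test_fraction_zero_plateaus_at_lad_bound(self, extended):
        table = oxygen_sweep(extended, biomass_fraction=0.0)
        assert table["max_fuculose"].iloc[-1] == pytest.approx(5.0, abs=1e-6)

    def test_single_anaerobic_point(self, extended):
        table = oxygen_sweep(extended, o2_grid=[0.0])
        assert table["max_fuculose"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_empty_grid_rejected(self, extended):
        with pytest.raises(ValueError, match="non-empty"):
            oxygen_sweep(extended, o2_grid=[])

    def test_positive_grid_value_rejected(self, extended):
        with pytest.raises(ValueError, match="<= 0"):
            oxygen_sweep(extended, o2_grid=[0.0, 2.0])

    def test_rerun_is_byte_identical(self, extended):
        a = oxygen_sweep(extended).to_csv(index=False, float_format="%.6f")
        b = oxygen_sweep(extended).to_csv(index=False, float_format="%.6f")
        assert a == b


class TestSubstrateScan:
    def test_no_glucose_no_fuculose_and_monotone(self, extended):
        table = substrate_ratio_scan(extended)
        assert table["max_fuculose"].iloc[0] == 0.0  # glc bound 0
        assert np.all(np.diff(table["max_fuculose"].to_numpy()) >= -1e-6)

    def test_production_requires_glucose_at_least_matching_lad(self, extended):
        table = substrate_ratio_scan(extended).set_index("glc_lower_bound")
        assert table.loc[-2.5, "max_fuculose"] == 0.0
        assert table.loc[-5.0, "max_fuculose"] > 1e-6

    def test_stoichiometric_ceiling_two_dhap_per_glucose(self, extended):
        table = substrate_ratio_scan(extended, biomass_fraction=0.0)
        for _, row in table.iterrows():
            assert row["max_fuculose"] <= 2.0 * abs(row["glc_lower_bound"]) + 1e-6


class TestStrainSeries:
    def test_deleted_reactions_carry_no_flux(self, extended):
        table = strain_series(extended).set_index("strain")
        gene_to_rxn = {"fucI": "FUCI", "fucK": "FCLK", "tpiA": "TPI",
                       "fucO": "FUCO", "aldA": "ALDA"}
        for strain, row in table.iterrows():
            for gene in filter(None, row["deletions"].split(";")):
                rid = gene_to_rxn[gene]
                assert row[f"{rid}_fva_min"] == 0.0
                assert row[f"{rid}_fva_max"] == 0.0

    def test_wild_type_growth_dominates_engineered_strains(self, extended):
        table = strain_series(extended).set_index("strain")
        wt = table.loc["wild-type", "max_growth"]
        for strain in ("Fuc1", "Fuc2", "Fuc3", "Fuc4"):
            assert table.loc[strain, "max_growth"] <= wt + 1e-9

    def test_fuc3_pdo_secretion_blocked_in_model(self, extended):
        # with FucO deleted the model predicts zero 1,2-PDO, in contrast to the
        # residual conversion observed in vivo (other oxidoreductases)
        table = strain_series(extended).set_index("strain")
        assert table.loc["Fuc3", "FUCO_fva_max"] == 0.0


class TestOracleAgreementOnMotif:
    """The reduced fuculose motif reproduces the scenario structure at a size
    the exhaustive vertex oracle can certify."""

    CASES = {
        "anaerobic_growth": (0.0, "EX_bio", None),
        "aerobic_growth": (-4.0, "EX_bio", None),
        "aerobic_fuculose_at_half_growth": (-4.0, "EX_fcl", 0.5),
        "anaerobic_fuculose_at_optimum": (0.0, "EX_fcl", 1.0),
    }

    @pytest.mark.parametrize("case", sorted(CASES))
    def test_solver_matches_oracle(self, case):
        o2, objective, growth_fraction = self.CASES[case]
        m = build_fuculose_motif(o2_bound=o2)
        if growth_fraction is not None:
            mu = solve_fba(m, "EX_bio").objective_value
            m.get_reaction("EX_bio").lower_bound = growth_fraction * mu
        a = solve_fba(m, objective)
        b = enumerate_vertices_oracle(m, objective)
        assert a.status == b.status == "optimal"
        assert abs(a.objective_value - b.objective_value) <= 1e-6

    def test_motif_reproduces_anaerobic_routing(self):
        m = build_fuculose_motif(o2_bound=0.0)
        sol = solve_fba(m, "EX_bio")
        assert sol.fluxes["EX_lad"] == pytest.approx(-1.0, abs=1e-6)
        assert sol.fluxes["EX_pdo"] == pytest.approx(1.0, abs=1e-6)
        mu = sol.objective_value
        m.get_reaction("EX_bio").lower_bound = mu
        best_fcl = enumerate_vertices_oracle(m, "EX_fcl")
        assert best_fcl.objective_value == pytest.approx(0.0, abs=1e-6)
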