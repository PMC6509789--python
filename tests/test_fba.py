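"""FBA/FVA/knockout engine against independent LP oracles and closed forms."""

import math

import numpy as np
import pytest

from paretoflux import (
    FluxObjective,
    apply_medium,
    doubling_time,
    fba,
    fit_uptake_to_target,
    fva,
    knockout_scan,
    make_toy,
    minimize_total_transport,
    MediumConfig,
)
from paretoflux.fba import ModelProgram

from .oracles import cobra_fva, cobra_optimum


class TestFba:
    def test_toy_growth_matches_oracle_and_closed_form(self, toy):
        sol = fba(toy)
        assert sol.optimal
        # carbon-limited: 10 acetate-C -> exactly one biomass unit
        assert sol.objective_value == pytest.approx(1.0, abs=1e-9)
        assert sol.objective_value == pytest.approx(
            cobra_optimum(toy, "EX_biomass"), abs=1e-9
        )

    def test_atp_limited_regime(self):
        # photon cap 11 -> 22 ATP; growth b solves 33 b = 22 (15 ATP biosynthesis
        # + 18 ATP to expel the 9 b excess reducing equivalents as H2)
        toy = make_toy(P=11.0, A=10.0)
        sol = fba(toy)
        assert sol.objective_value == pytest.approx(22.0 / 33.0, abs=1e-9)
        assert sol.objective_value == pytest.approx(
            cobra_optimum(toy, "EX_biomass"), abs=1e-9
        )

    def test_steady_state_and_bounds_hold(self, toy):
        sol = fba(toy)
        S_int, _ = toy.steady_state_matrix()
        v = np.array([sol[r.id] for r in toy.reactions])
        assert np.abs(S_int @ v).max() < 1e-8
        for r in toy.reactions:
            assert r.lower_bound - 1e-9 <= sol[r.id] <= r.upper_bound + 1e-9

    def test_closed_uptakes_give_zero_growth(self, toy):
        starved = apply_medium(toy, MediumConfig({}))
        assert fba(starved).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_refinement_keeps_optimum_and_minimizes_total_flux(self, toy):
        raw = fba(toy, refine="none")
        refined = fba(toy, refine="min_total_flux")
        assert refined.objective_value == pytest.approx(raw.objective_value, abs=1e-9)
        assert refined.total_flux() <= raw.total_flux() + 1e-6
        # futile OX+FIX cycles carry no flux in the parsimonious solution
        assert refined["FIX_A"] == pytest.approx(0.0, abs=1e-9)
        assert refined["OX"] == pytest.approx(0.0, abs=1e-9)

    def test_cheaper_fixation_route_preferred_when_atp_limited(self):
        # mixotrophy: CO2 uptake opened; the rTCA-like route (2 ATP) should
        # carry the fixation flux in the parsimonious optimum, not the
        # CBB-like route (3 ATP)
        toy = make_toy(P=50.0, A=10.0)
        toy.reaction("EX_co2").lower_bound = -1e6
        sol = fba(toy)
        assert sol.objective_value == pytest.approx(20.0 / 11.0, abs=1e-9)
        assert sol["FIX_B"] > 1.0
        assert sol["FIX_A"] == pytest.approx(0.0, abs=1e-9)

    def test_strong_duality(self, toy):
        prog = ModelProgram(toy)
        c = prog.cost({"EX_biomass": 1.0})
        res = prog.lp.solve(c, maximize=True)
        dual = (
            float(np.dot(res.duals_lower, prog.lp.lower))
            + float(np.dot(res.duals_upper, prog.lp.upper))
        )  # equality rhs are all zero
        assert dual == pytest.approx(res.objective, rel=1e-6, abs=1e-9)

    def test_optimum_monotone_in_relaxed_bound(self):
        values = [fba(make_toy(P=p, A=10.0)).objective_value for p in (0, 5, 11, 33, 50, 80)]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))
        # light-limited then carbon-limited: saturates at 1.0
        assert values[0] == pytest.approx(0.0, abs=1e-12)
        assert values[-1] == pytest.approx(1.0, abs=1e-9)
        assert values[-2] == pytest.approx(1.0, abs=1e-9)


class TestFva:
    def test_linear_chain_envelope(self):
        from paretoflux import Metabolite, Reaction, StoichiometricModel

        chain = StoichiometricModel(
            [Metabolite("A"), Metabolite("B"), Metabolite("C")],
            [
                Reaction("EX_A", {"A": -1}, -2.0, 0.0),
                Reaction("R1", {"A": -1, "B": 1}, 0.0, 1e3),
                Reaction("R2", {"B": -1, "C": 1}, 0.0, 1e3),
                Reaction("EX_C", {"C": -1}, 0.0, 1e3),
            ],
        )
        env = fva(chain)
        assert env["R1"] == pytest.approx((0.0, 2.0))
        assert env["R2"] == pytest.approx((0.0, 2.0))
        assert env["EX_A"] == pytest.approx((-2.0, 0.0))

    def test_toy_envelopes_match_oracle(self, toy):
        env = fva(toy)
        oracle = cobra_fva(toy, toy.reaction_ids)
        for rxn_id, (lo, hi) in env.ranges.items():
            olo, ohi = oracle[rxn_id]
            assert lo == pytest.approx(olo, abs=1e-6), rxn_id
            assert hi == pytest.approx(ohi, abs=1e-6), rxn_id

    def test_blocked_reaction_envelope_is_zero(self, toy):
        blocked = toy.copy()
        blocked.reaction("BYP").lower_bound = blocked.reaction("BYP").upper_bound = 0.0
        env = fva(blocked, reactions=["BYP"])
        assert env["BYP"] == (0.0, 0.0)

    def test_envelopes_contain_fba_solution(self, toy):
        sol = fba(toy)
        env = fva(toy)
        for rxn_id, (lo, hi) in env.ranges.items():
            assert lo - 1e-6 <= sol[rxn_id] <= hi + 1e-6

    def test_biomass_floor_narrows_envelopes(self, toy):
        free = fva(toy, biomass_fraction=0.0, reactions=["EX_h2"])
        floored = fva(toy, biomass_fraction=1.0, reactions=["EX_h2"])
        # at full growth the excess reducing equivalents fix H2 export at 9
        assert floored["EX_h2"] == pytest.approx((9.0, 9.0), abs=1e-6)
        assert free["EX_h2"][1] > floored["EX_h2"][1]

    def test_infeasible_base_errors(self, toy):
        bad = toy.copy()
        bad.reaction("EX_biomass").lower_bound = 5.0  # unreachable forced growth
        with pytest.raises(ValueError, match="infeasible"):
            fva(bad, biomass_fraction=0.5)


class TestMinimizeTotalTransport:
    def test_growth_pinned_to_zero_closes_all_transport(self, toy):
        sol = minimize_total_transport(toy, fixed={"EX_biomass": 0.0})
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_at_growth_optimum_matches_hand_count(self, toy):
        # at b=1: photon 33/2=16.5 in, acetate 10 in, H2 9 out, biomass 1 out
        sol = minimize_total_transport(toy, fixed={"EX_biomass": 1.0})
        assert sol.objective_value == pytest.approx(16.5 + 10 + 9 + 1, abs=1e-6)

    def test_minimal_medium_transport_profile_unique(self, toy):
        """At the pinned optimum the exchange envelopes collapse to points."""
        pinned = toy.copy()
        pinned.reaction("EX_biomass").lower_bound = 1.0
        env = fva(pinned, reactions=[r.id for r in toy.exchange_reactions])
        sol = minimize_total_transport(toy, fixed={"EX_biomass": 1.0})
        for rxn_id, (lo, hi) in env.ranges.items():
            if rxn_id == "EX_photon":
                continue  # photon uptake trades off against nothing material
            assert hi - lo < 1e-6, rxn_id
            assert sol[rxn_id] == pytest.approx(lo, abs=1e-6)

    def test_infeasible_pin_reported(self, toy):
        sol = minimize_total_transport(toy, fixed={"EX_biomass": 99.0})
        assert sol.status == "infeasible"


class TestKnockouts:
    def test_scan_matches_reaction_deletion_oracle(self, toy):
        table = knockout_scan(toy).set_index("gene")
        # oracle: remove the reactions each gene uniquely enables, re-solve via cobra
        single = {"gLHC": "LHC", "gACT": "ACT", "gOX": "OX", "gCBB": "FIX_A",
                  "gRTCA": "FIX_B"}
        for gene, rxn_id in single.items():
            mutant = toy.copy()
            mutant.reaction(rxn_id).upper_bound = 0.0
            expected = cobra_optimum(mutant, "EX_biomass")
            assert table.loc[gene, "objective_value"] == pytest.approx(expected, abs=1e-9)

    def test_light_and_nitrogenase_essential_others_not(self, toy):
        table = knockout_scan(toy).set_index("gene")
        # no light -> no ATP; no H2 valve -> electron balance forbids growth
        for gene in ("gLHC", "gNIF1", "gNIF2", "gACT"):
            assert table.loc[gene, "essential"], gene
        for gene in ("gOX", "gCBB", "gRTCA", "gBYP1", "gBYP2"):
            assert not table.loc[gene, "essential"], gene

    def test_isozyme_pair_single_vs_double(self, toy):
        from paretoflux import evaluate_gpr

        gpr = toy.reaction("BYP").gpr
        assert evaluate_gpr(gpr, {"gBYP1"})
        assert evaluate_gpr(gpr, {"gBYP2"})
        assert not evaluate_gpr(gpr, {"gBYP1", "gBYP2"})

    def test_gene_absent_from_gprs_is_wild_type(self, toy):
        wild = fba(toy, refine="none").objective_value
        table = knockout_scan(toy, genes=["ghost"]).set_index("gene")
        assert table.loc["ghost", "objective_value"] == pytest.approx(wild, abs=1e-12)
        assert table.loc["ghost", "n_disabled_reactions"] == 0


class TestDoublingTime:
    def test_inverse_identity(self):
        assert doubling_time(math.log(2) / 6.4) == pytest.approx(6.4)

    def test_measured_growth_rate(self):
        assert doubling_time(0.0825) == pytest.approx(8.4, abs=0.05)

    @pytest.mark.parametrize("mu", [0.0, -1.0])
    def test_nonpositive_rate_rejected(self, mu):
        with pytest.raises(ValueError):
            doubling_time(mu)


class TestFitUptake:
    def test_matches_brute_force_scan(self, growth_objective):
        toy = make_toy(P=50.0, A=10.0)
        target = 0.5  # half of the carbon-limited optimum, in the ATP-limited regime
        cap = fit_uptake_to_target(toy, "EX_photon", growth_objective, target,
                                   tol=1e-8, bracket=(0.0, 50.0))
        # brute force: finest photon cap whose optimum reaches the target
        caps = np.arange(0.0, 50.0, 1e-4)
        optima = 2 * caps / 33.0  # closed form in the light-limited regime
        brute = caps[np.searchsorted(optima, target)]
        assert cap == pytest.approx(brute, abs=1e-3)
        assert cap == pytest.approx(33.0 * target / 2.0, abs=1e-6)

    def test_acetate_dial(self, growth_objective):
        toy = make_toy(P=1000.0, A=10.0)
        cap = fit_uptake_to_target(toy, "EX_ac", growth_objective, 0.5,
                                   tol=1e-8, bracket=(0.0, 10.0))
        assert cap == pytest.approx(5.0, abs=1e-6)  # growth = A/10 when carbon-limited

    def test_unreachable_target_errors(self, toy, growth_objective):
        with pytest.raises(ValueError, match="outside achievable range"):
            fit_uptake_to_target(toy, "EX_photon", growth_objective, 5.0,
                                 bracket=(0.0, 50.0))
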