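"""FBA engine: condition setup, LP optima, variability, yields."""

import numpy as np
import pytest

import aromflux as af
from aromflux.fba import ConditionError, SolverError
from aromflux.model import stoichiometric_matrix
from aromflux.vertices import enumerate_vertices, lp_optimum, optimal_face_ranges

from conftest import linear_chain_model


class TestLinearChain:
    def test_bottleneck_objective(self, chain_model):
        # 10 substrate → 10 ATP, biomass needs 2 ATP per unit → 5
        sol = af.solve_fba(chain_model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(5.0, abs=1e-9)

    def test_maintenance_drain_reduces_objective(self):
        model = linear_chain_model(uptake_max=10.0, ngam=2.0)
        sol = af.solve_fba(model)
        assert sol.objective_value == pytest.approx(4.0, abs=1e-9)  # (10-2)/2

    def test_objective_scales_with_uptake(self):
        lo = af.solve_fba(linear_chain_model(uptake_max=5.0)).objective_value
        hi = af.solve_fba(linear_chain_model(uptake_max=10.0)).objective_value
        assert hi == pytest.approx(2.0 * lo, abs=1e-9)

    def test_unique_pathway_has_point_ranges(self, chain_model):
        sol = af.solve_fba(chain_model)
        fr = af.flux_variability(chain_model)
        for rid, (lo, hi) in fr.ranges.items():
            assert lo == pytest.approx(hi, abs=1e-6)
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6

    def test_infeasible_reported_not_silent(self, chain_model):
        model = chain_model.copy()
        model.reaction("BIO").lower_bound = 6.0  # demands more than uptake allows
        sol = af.solve_fba(model)
        assert sol.status == "infeasible"
        assert sol.fluxes == {}
        with pytest.raises(SolverError):
            af.flux_variability(model)


class TestParallelRoutes:
    def _two_routes(self):
        mets = [
            af.Metabolite("a_e", compartment="external"),
            af.Metabolite("a_c"),
            af.Metabolite("b_c"),
        ]
        rxns = [
            af.Reaction("EX_a", {"a_e": -1}, -10.0, 0.0, category="boundary"),
            af.Reaction("T_a", {"a_e": -1, "a_c": 1}),
            af.Reaction("R1", {"a_c": -1, "b_c": 1}),
            af.Reaction("R2", {"a_c": -1, "b_c": 1}),
            af.Reaction("BIO", {"b_c": -1}, category="biomass"),
        ]
        return af.MetabolicModel(mets, rxns, "BIO")

    def test_equivalent_routes_span_zero_to_total(self):
        model = self._two_routes()
        fr = af.flux_variability(model)
        total = af.solve_fba(model).objective_value
        assert total == pytest.approx(10.0, abs=1e-9)
        for rid in ("R1", "R2"):
            lo, hi = fr.ranges[rid]
            assert lo == pytest.approx(0.0, abs=1e-6)
            assert hi == pytest.approx(total, abs=1e-6)


class TestConditions:
    def test_rival_acceptor_closed(self, toy_model, toy_presets):
        aerobic = next(c for c in toy_presets if c.label == "acetate-aerobic")
        bounded = af.apply_condition(toy_model, aerobic)
        no3 = bounded.reaction("EX_no3")
        assert (no3.lower_bound, no3.upper_bound) == (0.0, 0.0)
        assert bounded.reaction("EX_o2").lower_bound == -aerobic.acceptor_uptake_max

    def test_aromatic_anaerobic_bounds(self, toy_model, toy_presets):
        cond = next(c for c in toy_presets if c.label == "aromatic-anaerobic")
        bounded = af.apply_condition(toy_model, cond)
        assert bounded.reaction("EX_bz").lower_bound == -cond.substrate_uptake_max
        o2 = bounded.reaction("EX_o2")
        assert (o2.lower_bound, o2.upper_bound) == (0.0, 0.0)
        ngam = bounded.reaction("NGAM")
        assert (ngam.lower_bound, ngam.upper_bound) == (cond.ngam, cond.ngam)

    def test_no_electron_sink_means_no_growth(self, toy_model, toy_presets):
        cond = next(c for c in toy_presets if c.label == "acetate-anaerobic")
        starved = af.Condition(
            label="acetate-no-acceptor",
            substrate_exchange=cond.substrate_exchange,
            substrate_uptake_max=cond.substrate_uptake_max,
            acceptor="nitrate",
            acceptor_exchange=cond.acceptor_exchange,
            acceptor_uptake_max=0.0,
            ngam=0.0,
            closed_exchanges=("EX_o2",),
        )
        sol = af.solve_fba(af.apply_condition(toy_model, starved))
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_missing_exchange_is_configuration_error(self, toy_model, toy_presets):
        cond = toy_presets[0]
        broken = af.Condition(
            label="x", substrate_exchange="EX_missing", substrate_uptake_max=1.0,
            acceptor="oxygen", acceptor_exchange=cond.acceptor_exchange,
            acceptor_uptake_max=1.0,
        )
        with pytest.raises(ConditionError, match="EX_missing"):
            af.apply_condition(toy_model, broken)

    def test_objective_monotone_in_acceptor_supply(self, toy_model, toy_presets):
        cond = next(c for c in toy_presets if c.label == "acetate-anaerobic")
        previous = -1.0
        for acceptor_max in (0.0, 5.0, 15.0, 30.0):
            variant = af.Condition(
                label=cond.label, substrate_exchange=cond.substrate_exchange,
                substrate_uptake_max=cond.substrate_uptake_max,
                acceptor=cond.acceptor, acceptor_exchange=cond.acceptor_exchange,
                acceptor_uptake_max=acceptor_max, ngam=0.0,
                closed_exchanges=cond.closed_exchanges,
            )
            obj = af.solve_fba(af.apply_condition(toy_model, variant)).objective_value
            assert obj >= previous - 1e-9
            previous = obj


class TestSteadyState:
    def test_residual_below_tolerance(self, toy_solutions):
        for bounded, sol in toy_solutions.values():
            assert af.steady_state_residual(bounded, sol) <= 1e-6

    def test_ranges_bracket_fba_fluxes(self, toy_solutions, toy_ranges):
        for fr in toy_ranges:
            _, sol = toy_solutions[fr.condition_label]
            for rid, (lo, hi) in fr.ranges.items():
                assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_network_matches_vertex_enumeration(self, seed):
        model = af.make_random_network(seed)
        S = stoichiometric_matrix(model).toarray()
        lb = np.array([r.lower_bound for r in model.reactions])
        ub = np.array([r.upper_bound for r in model.reactions])
        c = np.zeros(len(model.reactions))
        c[model.reaction_ids.index(model.objective_id)] = 1.0
        verts = enumerate_vertices(S, lb, ub)
        sol = af.solve_fba(model)
        assert sol.objective_value == pytest.approx(lp_optimum(verts, c), abs=1e-6)
        engine = af.flux_variability(model)
        oracle = optimal_face_ranges(verts, c)
        for j, rid in enumerate(model.reaction_ids):
            assert engine.ranges[rid][0] == pytest.approx(oracle[j, 0], abs=1e-6)
            assert engine.ranges[rid][1] == pytest.approx(oracle[j, 1], abs=1e-6)

    def test_facultative_toy_matches_oracle(self):
        spec = af.ToyNetworkSpec(include_phb=False, include_glyoxylate_shunt=False,
                                 substrates=("acetate",))
        model = af.make_toy_model(spec)
        for cond in af.toy_conditions(substrates=("acetate",)):
            bounded = af.apply_condition(model, cond)
            S = stoichiometric_matrix(bounded).toarray()
            lb = np.array([r.lower_bound for r in bounded.reactions])
            ub = np.array([r.upper_bound for r in bounded.reactions])
            c = np.zeros(len(bounded.reactions))
            c[bounded.reaction_ids.index("BIOMASS")] = 1.0
            verts = enumerate_vertices(S, lb, ub)
            sol = af.solve_fba(bounded)
            assert sol.objective_value == pytest.approx(lp_optimum(verts, c), abs=1e-6)


class TestCobraCrossCheck:
    def test_toy_objective_agrees_with_cobra(self, toy_model, toy_presets):
        cobra = pytest.importorskip("cobra")
        cond = next(c for c in toy_presets if c.label == "acetate-aerobic")
        bounded = af.apply_condition(toy_model, cond)
        cm = cobra.Model("toy")
        cmets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment[0])
                 for m in bounded.metabolites}
        crxns = []
        for r in bounded.reactions:
            cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
            cr.add_metabolites({cmets[mid]: coeff for mid, coeff in r.stoichiometry.items()})
            crxns.append(cr)
        cm.add_reactions(crxns)
        cm.objective = "BIOMASS"
        ours = af.solve_fba(bounded).objective_value
        theirs = cm.optimize().objective_value
        assert ours == pytest.approx(theirs, abs=1e-6)


class TestCarbonYield:
    def test_fully_respired_substrate_gives_zero(self):
        # biomass consumes only the carbon-free energy carrier
        mets = [
            af.Metabolite("s_e", compartment="external", formula={"C": 2}),
            af.Metabolite("s_c", formula={"C": 2}),
            af.Metabolite("co2_e", compartment="external", formula={"C": 1}),
            af.Metabolite("atp", formula={}),
        ]
        rxns = [
            af.Reaction("EX_s", {"s_e": -1}, -10, 0, category="boundary"),
            af.Reaction("T_s", {"s_e": -1, "s_c": 1}),
            af.Reaction("OX", {"s_c": -1, "co2_e": 2, "atp": 4}),
            af.Reaction("EX_co2", {"co2_e": -1}, 0, 1000, category="boundary"),
            af.Reaction("BIO", {"atp": -2}, category="biomass"),
        ]
        model = af.MetabolicModel(mets, rxns, "BIO")
        sol = af.solve_fba(model)
        assert af.biomass_carbon_yield(sol, model) == pytest.approx(0.0, abs=1e-9)

    def test_full_assimilation_gives_hundred(self):
        mets = [
            af.Metabolite("s_e", compartment="external", formula={"C": 2}),
            af.Metabolite("s_c", formula={"C": 2}),
        ]
        rxns = [
            af.Reaction("EX_s", {"s_e": -1}, -10, 0, category="boundary"),
            af.Reaction("T_s", {"s_e": -1, "s_c": 1}),
            af.Reaction("BIO", {"s_c": -1}, category="biomass"),
        ]
        model = af.MetabolicModel(mets, rxns, "BIO")
        sol = af.solve_fba(model)
        assert af.biomass_carbon_yield(sol, model) == pytest.approx(100.0, abs=1e-9)

    def test_toy_yields_bounded_and_aerobic_higher(self, toy_solutions):
        yields = {
            label: af.biomass_carbon_yield(sol, bounded)
            for label, (bounded, sol) in toy_solutions.items()
        }
        for value in yields.values():
            assert 0.0 <= value <= 100.0
        assert yields["acetate-aerobic"] > yields["acetate-anaerobic"]
        assert yields["aromatic-aerobic"] > yields["aromatic-anaerobic"]
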