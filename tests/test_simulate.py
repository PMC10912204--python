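"""FBA/MOMA correctness against independent LP and QP oracles."""

import numpy as np
import pytest

from fluxgrowth import (
    MediumDefinition,
    apply_gene_deletion,
    fba,
    moma,
    set_medium,
    simulate_deletion_panel,
    single_reaction_essentiality,
    stoichiometric_matrix,
    wildtype_reference,
)
from fluxgrowth.model_io import INFINITY_BOUND, MetabolicModel, Metabolite, Reaction, parse_gpr
from fluxgrowth.simulate import solve_projection_qp

from .conftest import make_model
from .oracles import kkt_polished_qp, lp_max_by_vertex_enumeration


def arrays(model):
    S = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return S, lb, ub


class TestSetMedium:
    def make_two_carbon(self):
        return make_model(
            "two_carbon",
            [("glc_e", "e"), ("ac_e", "e"), ("x_c", "c")],
            [
                ("EX_glc", {"glc_e": -1}, 0, 1000, ""),
                ("EX_ac", {"ac_e": -1}, 0, 1000, ""),
                ("T_glc", {"glc_e": -1, "x_c": 1}, 0, 1000, ""),
                ("T_ac", {"ac_e": -1, "x_c": 1}, 0, 1000, ""),
                ("BIOMASS", {"x_c": -1}, 0, 1000, ""),
            ],
            [],
            "BIOMASS",
        )

    def test_glucose_medium_sets_uptake_bound(self):
        model = self.make_two_carbon()
        conditioned = set_medium(model, MediumDefinition("glc", "EX_glc"))
        assert conditioned.reaction("EX_glc").lower_bound == -10.0
        assert conditioned.reaction("EX_ac").lower_bound == 0.0

    def test_switching_carbon_closes_old_opens_new(self):
        model = self.make_two_carbon()
        glc = set_medium(model, MediumDefinition("glc", "EX_glc"))
        ac = set_medium(glc, MediumDefinition("ac", "EX_ac"))
        assert ac.reaction("EX_glc").lower_bound == 0.0
        assert ac.reaction("EX_ac").lower_bound == -10.0

    def test_non_exchange_reaction_errors(self):
        model = self.make_two_carbon()
        with pytest.raises(KeyError, match="T_glc"):
            set_medium(model, MediumDefinition("bad", "T_glc"))

    def test_free_exchanges_fully_open(self):
        model = self.make_two_carbon()
        conditioned = set_medium(
            model, MediumDefinition("glc", "EX_glc", free_exchanges=frozenset({"EX_ac"}))
        )
        assert conditioned.reaction("EX_ac").lower_bound == -INFINITY_BOUND


class TestFBA:
    def test_chain_growth_limited_by_uptake(self, chain_model):
        sol = fba(chain_model)
        assert sol.objective_value == pytest.approx(10.0, abs=1e-8)

    def test_zero_uptake_zero_growth(self, chain_model):
        closed = chain_model.with_bounds({"EX_a": (0.0, 1000.0)})
        assert fba(closed).objective_value == 0.0

    def test_branched_model_matches_vertex_enumeration_oracle(self):
        # biomass consumes 2 b + 1 c; two branches compete for a
        model = make_model(
            "branched",
            [("a", "c"), ("b", "c"), ("c_m", "c")],
            [
                ("EX_a", {"a": -1}, -10, 1000, ""),
                ("R_b", {"a": -1, "b": 1}, 0, 1000, ""),
                ("R_c", {"a": -1, "c_m": 1}, 0, 6, ""),
                ("BIOMASS", {"b": -2, "c_m": -1}, 0, 1000, ""),
            ],
            [],
            "BIOMASS",
        )
        sol = fba(model)
        S, lb, ub = arrays(model)
        c = np.zeros(len(ub))
        c[model.reaction_ids.index("BIOMASS")] = 1.0
        oracle = lp_max_by_vertex_enumeration(S, lb, ub, c)
        assert sol.objective_value == pytest.approx(oracle, abs=1e-8)

    def test_infeasible_model_reports_zero_growth(self):
        model = make_model(
            "forced_infeasible",
            [("a", "c")],
            [
                ("EX_a", {"a": -1}, 0, 0, ""),
                ("SINK", {"a": -1}, 5, 1000, ""),  # demands flux it cannot get
            ],
            [],
            "SINK",
        )
        sol = fba(model)
        assert sol.status == "infeasible" and sol.objective_value == 0.0

    def test_steady_state_and_bounds_residuals(self, chain_model):
        sol = fba(chain_model)
        S, lb, ub = arrays(chain_model)
        v = sol.as_array(chain_model.reaction_ids)
        assert np.linalg.norm(S @ v, np.inf) < 1e-6
        assert (v >= lb - 1e-9).all() and (v <= ub + 1e-9).all()


class TestMOMA:
    def test_identical_mutant_returns_wildtype_flux(self, chain_model):
        wt = wildtype_reference(chain_model)
        sol = moma(chain_model, wt)
        v = sol.as_array(chain_model.reaction_ids)
        w = wt.as_array(chain_model.reaction_ids)
        assert np.linalg.norm(v - w, np.inf) < 1e-9

    def test_deleting_only_internal_reaction_kills_flux(self, chain_model):
        wt = wildtype_reference(chain_model)
        mut = chain_model.with_bounds({"R1": (0.0, 0.0)})
        sol = moma(mut, wt)
        assert sol.objective_value == 0.0
        assert all(abs(x) < 1e-9 for x in sol.fluxes.values())

    def test_parallel_route_rerouting_matches_qp_oracle(self, parallel_model):
        # force all wild-type flux through route 1, then delete it
        forced = parallel_model.with_bounds({"R2": (0.0, 0.0)})
        wt = wildtype_reference(forced)
        assert wt.fluxes["R1"] == pytest.approx(10.0, abs=1e-8)
        mut = parallel_model.with_bounds({"R1": (0.0, 0.0)})
        sol = moma(mut, wt)
        S, lb, ub = arrays(mut)
        w = wt.as_array(mut.reaction_ids)
        oracle = kkt_polished_qp(S, np.zeros(S.shape[0]), w, lb, ub)
        v = sol.as_array(mut.reaction_ids)
        assert np.linalg.norm(v - oracle, np.inf) < 1e-6
        assert sol.fluxes["R2"] > 1.0  # rerouted

    def test_moma_growth_never_exceeds_fba_growth(self, parallel_model):
        forced = parallel_model.with_bounds({"R2": (0.0, 0.0)})
        wt = wildtype_reference(forced)
        mut = parallel_model.with_bounds({"R1": (0.0, 5.0)})
        m = moma(mut, wt)
        f = fba(mut)
        assert f.objective_value >= m.objective_value - 1e-8

    def test_moma_solution_beats_random_feasible_points(self, parallel_model):
        rng = np.random.default_rng(0)
        wt = wildtype_reference(parallel_model.with_bounds({"R2": (0.0, 0.0)}))
        mut = parallel_model.with_bounds({"R1": (0.0, 3.0)})
        sol = moma(mut, wt)
        order = mut.reaction_ids
        w = wt.as_array(order)
        v = sol.as_array(order)
        obj = np.sum((v - w) ** 2)
        # random feasible points of the chain: uptake u, split r1 <= 3
        for _ in range(50):
            u = rng.uniform(0, 10)
            r1 = rng.uniform(0, min(3.0, u))
            point = dict(zip(order, [-u, r1, u - r1, u]))
            feas = np.array([point[r] for r in order])
            assert np.sum((feas - w) ** 2) >= obj - 1e-8

    def test_zero_flux_nonessential_deletion_leaves_solution(self, parallel_model):
        # WT reference sends flux through both routes equally; close R2's
        # bounds in a mutant whose reference flux there is already zero
        forced = parallel_model.with_bounds({"R2": (0.0, 0.0)})
        wt = wildtype_reference(forced)
        assert abs(wt.fluxes["R2"]) < 1e-9
        mut = parallel_model.with_bounds({"R2": (0.0, 0.0)})
        sol = moma(mut, wt)
        for rxn in parallel_model.reaction_ids:
            assert sol.fluxes[rxn] == pytest.approx(wt.fluxes[rxn], abs=1e-9)


class TestRandomNetworksAgainstOracles:
    """Randomly generated stoichiometric toys vs dense LP/QP oracles."""

    @staticmethod
    def random_network(rng):
        # random consistent S with bounded polytope and a designated
        # "biomass" column; n - rank(S) kept small for vertex enumeration
        while True:
            n = int(rng.integers(8, 13))
            m = int(rng.integers(n - 3, n - 1))
            S = rng.integers(-2, 3, size=(m, n)).astype(float)
            if np.linalg.matrix_rank(S) != m:
                continue
            lb = np.where(rng.random(n) < 0.5, -1000.0, 0.0)
            ub = np.full(n, 1000.0)
            for j in rng.choice(n, size=2, replace=False):
                ub[j] = float(abs(rng.normal(0, 3)))
            obj = int(rng.integers(0, n))
            if ub[obj] <= 0:
                continue
            return S, lb, ub, obj

    def test_fba_and_moma_match_oracles_on_random_networks(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 20:
            S, lb, ub, obj = self.random_network(rng)
            n = S.shape[1]
            c = np.zeros(n)
            c[obj] = 1.0
            oracle_obj = lp_max_by_vertex_enumeration(S, lb, ub, c)
            if oracle_obj is None:
                continue
            mets = [(f"m{i}", "c") for i in range(S.shape[0])]
            rxns = []
            for j in range(n):
                stoich = {f"m{i}": S[i, j] for i in range(S.shape[0]) if S[i, j] != 0}
                if not stoich:
                    continue
                rxns.append((f"r{j}", stoich, lb[j], ub[j], ""))
            if len(rxns) != n:
                continue
            model = make_model("rand", mets, rxns, [], f"r{obj}")
            sol = fba(model)
            assert sol.objective_value == pytest.approx(oracle_obj, abs=1e-8)
            # MOMA: project a random target onto the polytope
            w = rng.normal(0, 5, n)
            v = solve_projection_qp(S, np.zeros(S.shape[0]), w, lb, ub)
            ref = kkt_polished_qp(S, np.zeros(S.shape[0]), w, lb, ub)
            assert np.linalg.norm(v - ref, np.inf) < 1e-6
            checked += 1


class TestWildtypeReference:
    def test_chain_matches_fba(self, chain_model):
        ref = wildtype_reference(chain_model)
        sol = fba(chain_model)
        assert ref.objective_value == pytest.approx(sol.objective_value, abs=1e-9)
        assert ref.fluxes["R1"] == pytest.approx(10.0, abs=1e-8)

    def test_parallel_routes_split_equally(self, parallel_model):
        ref = wildtype_reference(parallel_model)
        assert ref.fluxes["R1"] == pytest.approx(5.0, abs=1e-7)
        assert ref.fluxes["R2"] == pytest.approx(5.0, abs=1e-7)
        # and it is the QP-oracle minimum-norm point at optimal growth
        S = stoichiometric_matrix(parallel_model)
        lb = np.array([r.lower_bound for r in parallel_model.reactions])
        ub = np.array([r.upper_bound for r in parallel_model.reactions])
        row = np.zeros(len(ub))
        row[parallel_model.reaction_ids.index("BIOMASS")] = 1.0
        A = np.vstack([S, row])
        b = np.concatenate([np.zeros(S.shape[0]), [ref.objective_value]])
        oracle = kkt_polished_qp(A, b, np.zeros(len(ub)), lb, ub)
        assert np.linalg.norm(ref.as_array(parallel_model.reaction_ids) - oracle, np.inf) < 1e-6

    def test_infeasible_medium(self, chain_model):
        broken = chain_model.with_bounds({"EX_a": (0.0, 0.0), "BIOMASS": (1.0, 1000.0)})
        assert wildtype_reference(broken).status == "infeasible"


class TestDeletionPanel:
    def test_replicates_do_not_change_results(self, toy_study):
        model, media = toy_study["model"], toy_study["media"]
        genes = sorted(model.genes)[:3]
        one = simulate_deletion_panel(model, genes, media[:1], replicates=1)
        three = simulate_deletion_panel(model, genes, media[:1], replicates=3)
        for a, b in zip(one, three):
            assert a.fluxes == pytest.approx(b.fluxes, abs=1e-12)

    def test_panel_shape(self, toy_study):
        model, media = toy_study["model"], toy_study["media"]
        genes = sorted(model.genes)[:4]
        panel = simulate_deletion_panel(model, genes, media[:2])
        assert len(panel) == 8
        assert {(fd.condition_id, fd.strain_id) for fd in panel} == {
            (m.condition_id, g) for m in media[:2] for g in genes
        }

    def test_panel_fluxes_match_direct_qp(self, toy_study):
        model, media = toy_study["model"], toy_study["media"]
        medium = media[0]
        conditioned = set_medium(model, medium)
        wt = wildtype_reference(conditioned, condition_id=medium.condition_id)
        gene = "gM1"
        [fd] = simulate_deletion_panel(model, [gene], [medium], replicates=3)
        mut = apply_gene_deletion(conditioned, {gene})
        S = stoichiometric_matrix(mut)
        lb = np.array([r.lower_bound for r in mut.reactions])
        ub = np.array([r.upper_bound for r in mut.reactions])
        oracle = kkt_polished_qp(
            S, np.zeros(S.shape[0]), wt.as_array(mut.reaction_ids), lb, ub
        )
        assert np.linalg.norm(fd.as_array(mut.reaction_ids) - oracle, np.inf) < 1e-6


class TestEssentiality:
    def brute_force(self, model, medium, threshold=0.05):
        conditioned = set_medium(model, medium)
        wt = fba(conditioned)
        calls = {}
        for rxn in conditioned.reaction_ids:
            ko = conditioned.with_bounds({rxn: (0.0, 0.0)})
            calls[rxn] = fba(ko).objective_value < threshold * wt.objective_value
        return calls

    def test_biomass_reaction_essential(self, toy_study):
        model, media = toy_study["model"], toy_study["media"]
        calls = single_reaction_essentiality(model, media[0], method="fba")
        assert calls["BIOMASS"] is True

    def test_redundant_route_nonessential(self, toy_study):
        model, media = toy_study["model"], toy_study["media"]
        calls = single_reaction_essentiality(model, media[0], method="fba")
        assert calls["CAT_C1"] is False  # bypass keeps the strain alive

    def test_matches_brute_force_and_moma_agrees(self, toy_study):
        model, media = toy_study["model"], toy_study["media"]
        medium = media[0]
        via_fba = single_reaction_essentiality(model, medium, method="fba")
        assert via_fba == self.brute_force(model, medium)
        via_moma = single_reaction_essentiality(model, medium, method="moma")
        assert via_moma == via_fba  # both optimization methods agree

    def test_zero_growth_medium_errors(self, chain_model):
        model = chain_model.with_bounds({"EX_a": (0.0, 1000.0)})
        medium = MediumDefinition("none", "EX_a", carbon_uptake_max=0.0)
        with pytest.raises(ValueError, match="essentiality undefined"):
            single_reaction_essentiality(model, medium)
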