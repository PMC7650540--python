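"""FBA correctness, condition screening, MILP gap-filling and minimal media."""

from __future__ import annotations

import numpy as np
import pytest
from oracle_helpers import brute_force_min_additions

from panmet.gapfill import (
    FBAError,
    GapFillProblem,
    LinearNetwork,
    Media,
    ReactionRecord,
    add_transporters,
    condition_media,
    essential_candidates,
    fba,
    gapfill,
    gapfill_milp,
    map_phenotype_compounds,
    minimal_media,
    screen_conditions,
)
from panmet.synthdata import (
    degrade_models,
    generate_true_network,
    records_to_model,
    simulate_phenotype_array,
)


def chain_model(**kw):
    records = [
        ReactionRecord("EX_glc", {"glc_e": -1.0}, -1000.0, 1000.0),
        ReactionRecord("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, -1000.0, 1000.0),
        ReactionRecord("STEP", {"glc_c": -1.0, "a_c": 1.0}, 0.0, 1000.0),
        ReactionRecord("BIOMASS", {"a_c": -1.0}, 0.0, 1000.0),
    ]
    return records_to_model(records, "chain")


class TestFBA:
    def test_linear_chain_bound_limited(self):
        growth, flux = fba(chain_model(), Media({"glc": 10.0}))
        assert growth == pytest.approx(10.0)
        assert flux["EX_glc"] == pytest.approx(-10.0)

    def test_no_carbon_gives_zero_not_error(self):
        growth, _ = fba(chain_model(), Media({}))
        assert growth == pytest.approx(0.0)

    def test_branched_network_hand_computed_optimum(self):
        # two routes to biomass, one doubling stoichiometry: optimum uses
        # the 1->2 branch only, giving 2x the uptake bound
        records = [
            ReactionRecord("EX_glc", {"glc_e": -1.0}, -1000.0, 1000.0),
            ReactionRecord("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, -1000.0, 1000.0),
            ReactionRecord("R1", {"glc_c": -1.0, "a_c": 1.0}, 0.0, 1000.0),
            ReactionRecord("R2", {"glc_c": -1.0, "a_c": 2.0}, 0.0, 1000.0),
            ReactionRecord("BIOMASS", {"a_c": -1.0}, 0.0, 1000.0),
        ]
        model = records_to_model(records, "branch")
        growth, flux = fba(model, Media({"glc": 5.0}))
        assert growth == pytest.approx(10.0)
        assert flux["R1"] == pytest.approx(0.0, abs=1e-6)

    def test_matches_cobra_glpk_solver(self, small_network):
        """HiGHS-based FBA agrees with COBRApy's GLPK optimizer."""
        for sp, model in small_network.species_models.items():
            ours, _ = fba(model, small_network.base_media)
            probe = model.copy()
            base = small_network.base_media.uptakes
            for rxn in probe.reactions:
                if rxn.id.startswith("EX_"):
                    cpd = rxn.id.removeprefix("EX_")
                    rxn.lower_bound = -base.get(cpd, 0.0)
            assert ours == pytest.approx(probe.slim_optimize(), rel=1e-6)

    def test_mass_balance_within_tolerance(self, small_network):
        model = small_network.species_models["S01"]
        net = LinearNetwork.from_model(model)
        _, flux = net.solve("BIOMASS", small_network.base_media)
        assert np.abs(net.S @ flux).max() <= 1e-6

    def test_unknown_objective_raises(self):
        with pytest.raises(FBAError, match="NOPE"):
            fba(chain_model(), Media({}), objective_id="NOPE")


class TestTransporters:
    def test_fresh_compound_adds_two_reactions(self):
        model = chain_model()
        n = len(model.reactions)
        out = add_transporters(model, ["xyl"])
        assert len(out.reactions) == n + 2
        assert {"EX_xyl", "T_xyl"} <= {r.id for r in out.reactions}

    def test_existing_transporter_untouched_and_idempotent(self):
        model = chain_model()
        once = add_transporters(model, ["glc", "xyl"])
        twice = add_transporters(once, ["glc", "xyl"])
        assert {r.id for r in once.reactions} == {r.id for r in twice.reactions}
        assert len(once.reactions) == len(model.reactions) + 2


class TestScreening:
    def test_base_medium_retained_on_growing_model(self, small_network):
        model = small_network.species_models["S01"]
        retained, discarded = screen_conditions(
            model, small_network.universal_db, [small_network.base_media]
        )
        assert len(retained) == 1 and not discarded

    def test_planted_dead_ends_discarded_exactly(self, small_network):
        net = small_network
        model = net.species_models["S01"]
        conds = [condition_media(net.base_media, cpd) for cpd in net.compound_panel]
        retained, discarded = screen_conditions(model, net.universal_db, conds)
        assert {c.name for c in discarded} == set(net.dead_end_compounds)

    def test_phenotype_mapping_is_dictionary_lookup(self):
        mapped, unmapped = map_phenotype_compounds(
            ["D-Glucose", "Mystery-42", "D-Glucose"], {"D-Glucose": "cpd00027"}
        )
        assert mapped == {"D-Glucose": "cpd00027"}
        assert unmapped == ["Mystery-42"]


class TestEssential:
    def test_bridge_reaction_is_essential(self, small_network):
        net = small_network
        drafts, gaps = degrade_models(net, 0.3, seed=13)
        sp = "S01"
        conds = [
            condition_media(net.base_media, cpd)
            for cpd in sorted(net.species_compounds[sp])
        ]
        retained, _ = screen_conditions(drafts[sp], net.universal_db, conds)
        essential = essential_candidates(drafts[sp], net.universal_db, retained)
        # every planted gap on a needed linear chain is an essential candidate
        assert set(gaps.removed[sp]) <= essential

    def test_essential_subset_of_milp_solution(self, small_network):
        net = small_network
        drafts, _ = degrade_models(net, 0.3, seed=13)
        sp = "S02"
        arr, _ = simulate_phenotype_array(
            net.species_models[sp], net.compound_panel, net.base_media
        )
        conds = [condition_media(net.base_media, c) for c, ok in arr.items() if ok]
        res = gapfill(drafts[sp], net.universal_db, conds)
        assert set(res.essential) <= set(res.added)


class TestMILP:
    def test_no_gaps_empty_addition_set(self, small_network):
        net = small_network
        model = net.species_models["S01"]
        conds = [
            condition_media(net.base_media, cpd)
            for cpd in sorted(net.species_compounds["S01"])
        ]
        res = gapfill(model, net.universal_db, conds)
        assert res.added == []

    def test_addition_sets_match_bruteforce_minimum(self):
        for seed in (1, 2, 3):
            net = generate_true_network(3, db_size=30, shared_fraction=0.4, seed=seed)
            drafts, _ = degrade_models(net, 0.25, seed=seed)
            sp = sorted(net.species_models)[seed % 3]
            arr, _ = simulate_phenotype_array(
                net.species_models[sp], net.compound_panel, net.base_media
            )
            conds = [
                condition_media(net.base_media, c) for c, ok in arr.items() if ok
            ][:4]
            res = gapfill(drafts[sp], net.universal_db, conds)
            k, optima = brute_force_min_additions(
                drafts[sp], net.universal_db, conds
            )
            assert res.objective == k
            assert set(res.added) in optima

    def test_alternative_fixes_tie_broken_deterministically(self):
        records = [
            ReactionRecord("EX_glc", {"glc_e": -1.0}, -1000.0, 1000.0),
            ReactionRecord("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, -1000.0, 1000.0),
            ReactionRecord("BIOMASS", {"b_c": -1.0}, 0.0, 1000.0),
        ]
        model = records_to_model(records, "tie")
        # two equivalent single-reaction fixes; ZZZ carries gene support
        candidates = {
            "AAA_fix": ReactionRecord("AAA_fix", {"glc_c": -1.0, "b_c": 1.0}, 0, 1000),
            "ZZZ_fix": ReactionRecord(
                "ZZZ_fix", {"glc_c": -1.0, "b_c": 1.0}, 0, 1000, gene_support=True
            ),
        }
        conds = [Media({"glc": 10.0}, name="glc")]
        res = gapfill_milp(
            GapFillProblem(model=model, candidates=candidates, conditions=conds)
        )
        k, optima = brute_force_min_additions(model, candidates, conds)
        assert k == 1 and set(res.added) in optima
        assert res.added == ["ZZZ_fix"]  # gene support beats lexicographic order

        no_genes = {
            rid: ReactionRecord(rid, rec.stoichiometry, rec.lower, rec.upper)
            for rid, rec in candidates.items()
        }
        res2 = gapfill_milp(
            GapFillProblem(model=model, candidates=no_genes, conditions=conds)
        )
        assert res2.added == ["AAA_fix"]  # lexicographic when support ties

    def test_adding_condition_never_shrinks_solution(self, small_network):
        net = small_network
        drafts, _ = degrade_models(net, 0.3, seed=13)
        sp = "S03"
        arr, _ = simulate_phenotype_array(
            net.species_models[sp], net.compound_panel, net.base_media
        )
        positives = [c for c, ok in arr.items() if ok]
        sizes = []
        for upto in range(1, len(positives) + 1):
            conds = [condition_media(net.base_media, c) for c in positives[:upto]]
            res = gapfill(drafts[sp], net.universal_db, conds)
            sizes.append(res.objective)
        assert sizes == sorted(sizes)

    def test_witnesses_satisfy_mass_balance_and_threshold(self, small_network):
        net = small_network
        drafts, _ = degrade_models(net, 0.3, seed=13)
        sp = "S01"
        conds = [
            condition_media(net.base_media, cpd)
            for cpd in sorted(net.species_compounds[sp])
        ]
        res = gapfill(drafts[sp], net.universal_db, conds)
        added = [net.universal_db[r] for r in res.added]
        vnet = LinearNetwork.from_model(drafts[sp], added)
        for cond_name, witness in res.witnesses.items():
            flux = witness.to_numpy()
            assert np.abs(vnet.S @ flux).max() <= 1e-6
            assert witness["BIOMASS"] >= 1e-3 - 1e-9


class TestMinimalMedia:
    def test_prototroph_needs_nothing_beyond_base(self):
        model = chain_model()
        need = minimal_media(
            model, {"vitX": 10.0}, base=Media({"glc": 10.0})
        )
        assert need == []

    def test_knockout_creates_requirement_matching_subset_oracle(self):
        import itertools

        records = [
            ReactionRecord("EX_glc", {"glc_e": -1.0}, -1000.0, 1000.0),
            ReactionRecord("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, -1000.0, 1000.0),
            ReactionRecord("EX_biotin", {"biotin_e": -1.0}, -1000.0, 1000.0),
            ReactionRecord(
                "T_biotin", {"biotin_e": -1.0, "biotin_c": 1.0}, -1000.0, 1000.0
            ),
            ReactionRecord("EX_thi", {"thi_e": -1.0}, -1000.0, 1000.0),
            ReactionRecord("T_thi", {"thi_e": -1.0, "thi_c": 1.0}, -1000.0, 1000.0),
            ReactionRecord("GROW", {"glc_c": -1.0, "a_c": 1.0}, 0.0, 1000.0),
            # thiamine can be synthesized, biotin cannot (knocked out)
            ReactionRecord("SYN_thi", {"a_c": -1.0, "thi_c": 1.0}, 0.0, 1000.0),
            ReactionRecord(
                "BIOMASS", {"a_c": -1.0, "biotin_c": -0.01, "thi_c": -0.01}, 0.0, 1000.0
            ),
        ]
        model = records_to_model(records, "auxo")
        pool = {"biotin": 10.0, "thi": 10.0}
        base = Media({"glc": 10.0})
        need = minimal_media(model, pool, base=base)
        assert need == ["biotin"]

        # oracle: smallest pool subsets sustaining growth
        feasible = []
        for k in range(len(pool) + 1):
            for combo in itertools.combinations(sorted(pool), k):
                m = Media({**base.uptakes, **{c: 10.0 for c in combo}})
                growth, _ = fba(model, m)
                if growth >= 1e-3:
                    feasible.append(set(combo))
            if feasible:
                break
        assert set(need) in feasible

    def test_no_growth_on_full_pool_is_error(self):
        model = chain_model()
        with pytest.raises(FBAError):
            minimal_media(model, {"vitX": 10.0}, base=Media({}))
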