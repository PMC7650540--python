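"""SBML round-trips, reaction classification, pan-GEM consolidation and
reaction-set arithmetic."""

from __future__ import annotations

import re

import cobra
import pytest

from panmet.gapfill import ReactionRecord
from panmet.pangem import (
    ModelError,
    PanGEM,
    build_pangem,
    census_model,
    classify_reaction,
    diff_models,
    load_model,
    normalize_reaction_id,
    reaction_sets,
    write_model,
)
from panmet.synthdata import records_to_model


def toy_model(model_id: str, extra: list[ReactionRecord] = ()) -> cobra.Model:
    records = [
        ReactionRecord("EX_glc", {"glc_e": -1.0}, -10.0, 1000.0),
        ReactionRecord("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, -1000.0, 1000.0),
        ReactionRecord("PGI", {"glc_c": -1.0, "f6p_c": 1.0}, 0.0, 1000.0, True),
        ReactionRecord("BIOMASS", {"f6p_c": -1.0}, 0.0, 1000.0),
        *extra,
    ]
    return records_to_model(records, model_id, biomass_id="BIOMASS")


class TestSBMLRoundTrip:
    def test_structural_equality_after_write_read(self, tmp_path):
        model = toy_model("toy")
        path = tmp_path / "toy.xml"
        write_model(model, path)
        back = load_model(path)
        assert {r.id for r in back.reactions} == {r.id for r in model.reactions}
        for rxn in model.reactions:
            other = back.reactions.get_by_id(rxn.id)
            assert other.bounds == rxn.bounds
            assert {m.id: c for m, c in other.metabolites.items()} == {
                m.id: c for m, c in rxn.metabolites.items()
            }
            assert other.gene_reaction_rule == rxn.gene_reaction_rule

    def test_census_counts_preserved(self, tmp_path, small_network):
        model = small_network.species_models["S01"]
        path = tmp_path / "S01.xml"
        write_model(model, path)
        assert census_model(load_model(path)) == census_model(model)
        assert census_model(model)["total"] == len(model.reactions)

    def test_malformed_sbml_raises(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml>this is not valid</sbml>")
        with pytest.raises(ModelError, match="bad.xml"):
            load_model(bad)

    def test_lower_bound_above_upper_rejected(self, tmp_path):
        path = tmp_path / "toy.xml"
        write_model(toy_model("toy"), path)
        text = path.read_text()
        text = text.replace(
            'id="cobra_default_ub" value="1000"',
            'id="cobra_default_ub" value="1000"'
        ).replace(
            "<listOfParameters>",
            '<listOfParameters><parameter sboTerm="SBO:0000626" id="bad_lb" '
            'value="2000" constant="true"/>',
        )
        text = re.sub(
            r'(<reaction id="R_BIOMASS"[^>]*?)fbc:lowerFluxBound="[^"]+"',
            r'\1fbc:lowerFluxBound="bad_lb"',
            text,
        )
        bad = tmp_path / "bad_bounds.xml"
        bad.write_text(text)
        with pytest.raises(ModelError):
            load_model(bad)


class TestClassification:
    def test_cross_compartment_is_transporter(self):
        model = toy_model("t")
        assert classify_reaction(model.reactions.get_by_id("T_glc")) == "transporter"

    def test_single_metabolite_is_exchange(self):
        model = toy_model("t")
        assert classify_reaction(model.reactions.get_by_id("EX_glc")) == "exchange"

    def test_same_compartment_is_metabolic(self):
        model = toy_model("t")
        assert classify_reaction(model.reactions.get_by_id("PGI")) == "metabolic"

    def test_designated_biomass(self):
        model = toy_model("t")
        rxn = model.reactions.get_by_id("BIOMASS")
        assert classify_reaction(rxn, biomass_id="BIOMASS") == "biomass"

    def test_normalize_strips_compartment_suffix(self):
        assert normalize_reaction_id("rxn00148_c") == "rxn00148"
        assert normalize_reaction_id("rxn00148[c]") == "rxn00148"
        assert normalize_reaction_id("rxn00148") == "rxn00148"
        assert normalize_reaction_id("old1", {"old1": "rxn1"}) == "rxn1"


class TestPanGEM:
    def test_single_model_all_core(self):
        model = toy_model("a")
        supra = build_pangem([model], ["a"])
        assert supra.census()["core"] == len(model.reactions)

    def test_two_identical_models_no_exclusives(self):
        supra = build_pangem([toy_model("a"), toy_model("b")], ["a", "b"])
        counts = reaction_sets(supra, {"a": "g1", "b": "g2"}, classification=None)
        assert counts.core == len(supra.table)
        assert all(v == 0 for v in counts.species_exclusive.values())

    def test_order_invariance(self, small_network):
        models = list(small_network.species_models.values())
        species = list(small_network.species_models)
        fwd = build_pangem(models, species)
        rev = build_pangem(models[::-1], species[::-1])
        assert fwd.table.equals(rev.table)

    def test_duplicate_species_rejected(self):
        with pytest.raises(ModelError):
            build_pangem([toy_model("a"), toy_model("a")], ["a", "a"])

    def test_presence_implies_membership(self, small_network):
        supra = build_pangem(
            list(small_network.species_models.values()),
            list(small_network.species_models),
        )
        for sp in supra.species:
            assert supra.reactions_of(sp, classification=None) == \
                small_network.species_reactions[sp]

    def test_core_bounded_by_smallest_model(self, small_network):
        supra = build_pangem(
            list(small_network.species_models.values()),
            list(small_network.species_models),
        )
        smallest = min(
            len(r) for r in small_network.species_reactions.values()
        )
        assert len(supra.core_reactions()) <= smallest


class TestReactionSets:
    def test_counts_equal_bruteforce_set_arithmetic(self):
        extra = {
            "a": [ReactionRecord("XA", {"f6p_c": -1.0, "xa_c": 1.0}, 0, 1000)],
            "b": [
                ReactionRecord("XB", {"f6p_c": -1.0, "xb_c": 1.0}, 0, 1000),
                ReactionRecord("XS", {"f6p_c": -1.0, "xs_c": 1.0}, 0, 1000),
            ],
            "c": [ReactionRecord("XS", {"f6p_c": -1.0, "xs_c": 1.0}, 0, 1000)],
        }
        models = [toy_model(sp, extra[sp]) for sp in "abc"]
        supra = build_pangem(models, ["a", "b", "c"])
        grouping = {"a": "g1", "b": "g2", "c": "g2"}
        counts = reaction_sets(supra, grouping, classification=None)

        sets = {sp: {r.id for r in m.reactions} for sp, m in zip("abc", models)}
        assert counts.core == len(sets["a"] & sets["b"] & sets["c"])
        assert counts.species_exclusive["a"] == len(
            sets["a"] - sets["b"] - sets["c"]
        )
        assert counts.group_exclusive["g2"] == len(
            (sets["b"] | sets["c"]) - sets["a"]
        )
        assert counts.group_exclusive_universal["g2"] == len(
            (sets["b"] & sets["c"]) - sets["a"]
        )

    def test_grouping_must_cover_all_species(self):
        supra = build_pangem([toy_model("a"), toy_model("b")], ["a", "b"])
        with pytest.raises(ModelError):
            reaction_sets(supra, {"a": "g"})


class TestDiff:
    def test_self_diff_empty(self):
        m = toy_model("m")
        assert diff_models(m, m) == (set(), set())

    def test_planted_gaps_recovered_as_diff(self, small_network):
        from panmet.synthdata import degrade_models

        drafts, gaps = degrade_models(small_network, 0.3, seed=13)
        for sp in drafts:
            only_truth, only_draft = diff_models(
                small_network.species_models[sp], drafts[sp]
            )
            assert only_truth == set(gaps.removed[sp])
            assert only_draft == set()
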