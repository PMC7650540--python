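"""Generator ground truth: determinism, planted structure, viability."""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest

from panmet.gapfill import Media, fba
from panmet.synthdata import (
    PanGenomeParams,
    degrade_models,
    generate_annotations,
    generate_pangenome,
    generate_true_network,
    simulate_phenotype_array,
    write_proteome_fasta,
)


def fasta_bytes(pg) -> bytes:
    buf = io.StringIO()
    for sp in sorted(pg.proteomes):
        for gene in sorted(pg.proteomes[sp]):
            buf.write(f">{gene}\n{pg.proteomes[sp][gene]}\n")
    return buf.getvalue().encode()


class TestPangenomeGenerator:
    def test_closed_pangenome_all_families_core(self):
        params = PanGenomeParams(
            n_species=4, core_size=7, shell_families=0, cloud_rate=0.0, seed=3
        )
        pg = generate_pangenome(params)
        counts = pg.truth.groupby("family")["species"].nunique()
        assert (counts == 4).all()
        assert pg.n_families == 7

    def test_same_seed_identical_bytes(self):
        params = PanGenomeParams(n_species=3, core_size=5, cloud_rate=2.0, seed=9)
        assert fasta_bytes(generate_pangenome(params)) == fasta_bytes(
            generate_pangenome(params)
        )

    def test_different_seed_differs(self):
        a = generate_pangenome(PanGenomeParams(core_size=5, seed=1))
        b = generate_pangenome(PanGenomeParams(core_size=5, seed=2))
        assert fasta_bytes(a) != fasta_bytes(b)

    def test_open_pangenome_mean_size_matches_analytic_expectation(self):
        # pan size = core + sum of 5 Poisson(50) cloud draws; mean 350,
        # sd ~ sqrt(250), so the mean over 40 seeds has sd ~ 2.5
        sizes = [
            generate_pangenome(
                PanGenomeParams(
                    n_species=5, core_size=100, shell_families=0, cloud_rate=50.0, seed=s
                )
            ).n_families
            for s in range(40)
        ]
        assert abs(np.mean(sizes) - 350.0) < 8.0

    def test_within_family_identity_exceeds_between(self):
        pg = generate_pangenome(
            PanGenomeParams(n_species=3, core_size=4, seed=5)
        )
        fam = pg.truth.set_index("gene")["family"]
        seqs = {g: s for sp in pg.proteomes for g, s in pg.proteomes[sp].items()}

        def identity(a, b):
            n = min(len(a), len(b))
            return sum(x == y for x, y in zip(a, b)) / n

        genes = list(seqs)
        within, between = [], []
        for i, gi in enumerate(genes):
            for gj in genes[i + 1 :]:
                (within if fam[gi] == fam[gj] else between).append(
                    identity(seqs[gi], seqs[gj])
                )
        assert min(within) > 0.85
        assert max(between) < 0.2

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_pangenome(
                PanGenomeParams(within_family_identity=0.3, between_family_identity=0.5)
            )
        with pytest.raises(ValueError):
            generate_pangenome(PanGenomeParams(cloud_rate=-1.0))


class TestTrueNetwork:
    def test_every_species_grows_on_base_medium(self, small_network):
        for model in small_network.species_models.values():
            growth, _ = fba(model, small_network.base_media)
            assert growth > 1e-3

    def test_shared_fraction_one_gives_identical_models(self):
        net = generate_true_network(3, db_size=30, shared_fraction=1.0, seed=1)
        sets = list(net.species_reactions.values())
        assert sets[0] == sets[1] == sets[2]

    def test_reaction_sets_match_recorded_assignments(self, small_network):
        net = small_network
        for sp, cpds in net.species_compounds.items():
            expected = {net.biomass_id}
            for cpd in cpds:
                expected |= {f"EX_{cpd}", f"T_{cpd}", *net.chain_reactions[cpd]}
            expected |= {
                f"EX_{c}" for c in net.compound_panel if c not in cpds
            }
            assert net.species_reactions[sp] == expected

    def test_species_model_subset_of_universal_db(self, small_network):
        db = set(small_network.universal_db) | {small_network.biomass_id}
        for rxns in small_network.species_reactions.values():
            assert rxns <= db


class TestDegrade:
    def test_zero_gap_fraction_keeps_models_intact(self, small_network):
        drafts, gaps = degrade_models(small_network, 0.0, seed=1)
        for sp, model in drafts.items():
            assert {r.id for r in model.reactions} == small_network.species_reactions[sp]
            assert gaps.removed[sp] == []

    def test_planted_gaps_equal_set_difference(self, small_network):
        drafts, gaps = degrade_models(small_network, 0.3, seed=13)
        for sp, model in drafts.items():
            diff = small_network.species_reactions[sp] - {
                r.id for r in model.reactions
            }
            assert diff == set(gaps.removed[sp])

    def test_protected_reactions_survive(self, small_network):
        drafts, _ = degrade_models(small_network, 0.5, seed=99)
        base = next(iter(small_network.base_media.uptakes))
        for sp, model in drafts.items():
            ids = {r.id for r in model.reactions}
            exchanges = {
                r for r in small_network.species_reactions[sp] if r.startswith("EX_")
            }
            assert small_network.biomass_id in ids
            assert f"T_{base}" in ids
            assert exchanges <= ids


class TestPhenotypeArray:
    def test_compound_without_transporter_is_negative(self, small_network):
        net = small_network
        for sp, model in net.species_models.items():
            calls, _ = simulate_phenotype_array(
                model, net.compound_panel, net.base_media
            )
            for cpd in net.compound_panel:
                if cpd not in net.species_compounds[sp]:
                    assert not calls[cpd]

    def test_calls_match_independent_cobra_solver(self, small_network):
        """Growth calls agree with COBRApy's own GLPK-backed optimizer."""
        net = small_network
        model = net.species_models["S01"]
        calls, _ = simulate_phenotype_array(model, net.compound_panel, net.base_media)
        for cpd, expected in calls.items():
            probe = model.copy()
            for rxn in probe.reactions:
                if rxn.id.startswith("EX_"):
                    rxn.lower_bound = -10.0 if rxn.id == f"EX_{cpd}" else 0.0
            value = probe.slim_optimize(error_value=0.0)
            assert (value >= 1e-3) == expected, cpd

    def test_duplicates_deduplicated(self, small_network):
        net = small_network
        model = net.species_models["S01"]
        once, _ = simulate_phenotype_array(model, net.compound_panel, net.base_media)
        twice, _ = simulate_phenotype_array(
            model, net.compound_panel * 2, net.base_media
        )
        pd.testing.assert_series_equal(once, twice)


class TestAnnotations:
    def test_zero_split_rate_one_name_per_function(self, small_pangenome):
        ann = generate_annotations(
            small_pangenome.truth, n_functions=5, split_rate=0.0, seed=1
        )
        assert ann.split_functions == []
        merged = ann.table.groupby("name")["gene"].count()
        assert len(merged) <= 5

    def test_split_count_recorded(self, small_pangenome):
        ann = generate_annotations(
            small_pangenome.truth, n_functions=10, split_rate=0.4, seed=2
        )
        # every split function's families got distinct names from one group
        names_by_fn = {}
        fam_fn = ann.family_function
        fam_name = dict(
            zip(
                small_pangenome.truth["family"],
                ann.table.set_index("gene").loc[
                    small_pangenome.truth["gene"], "name"
                ],
            )
        )
        for fam, fn in fam_fn.items():
            names_by_fn.setdefault(fn, set()).add(fam_name[fam])
        for fn in ann.split_functions:
            assert len(names_by_fn[fn]) > 1

    def test_seed_determinism(self, small_pangenome):
        a = generate_annotations(small_pangenome.truth, 8, 0.3, seed=4)
        b = generate_annotations(small_pangenome.truth, 8, 0.3, seed=4)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.synonyms == b.synonyms
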