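"""End-to-end synthetic pipeline with a reproducible run manifest.

Stages: synthetic pan-genome -> ortholog clustering + matrix ->
core/pan fits -> functional pivot -> synthetic networks + drafts +
phenotype arrays -> pan-GEM -> multi-condition gap-filling -> pathway
clustergrams.  Every stage writes its outputs under the run directory and
the manifest records parameters and SHA-256 checksums; a rerun with the
same config reproduces the checksums of every deterministic stage.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

import pandas as pd

from . import funcpivot, gapfill, pangem, panfit, pangenome, pathways, synthdata
from .io import RunConfig, sha256_of, write_json, write_reaction_db_tsv

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def majority_cluster_annotations(
    clusters: list[pangenome.OrthologCluster], gene_table: pd.DataFrame
) -> dict[str, funcpivot.Annotation]:
    """Annotate each cluster by the most common (name, EC) of its members."""
    by_gene = {
        row.gene: (row.name_, row.ec)
        for row in gene_table.rename(columns={"name": "name_"}).itertuples(index=False)
    }
    out = {}
    for cl in clusters:
        votes = Counter(by_gene[g] for _, g in cl.members if g in by_gene)
        if not votes:
            out[cl.cluster_id] = funcpivot.Annotation("hypothetical protein")
            continue
        name, ec = votes.most_common(1)[0][0]
        out[cl.cluster_id] = funcpivot.Annotation(
            name, funcpivot.parse_ec_list(ec)
        )
    return out


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage on synthetic data and return the manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def save(name: str, path: Path) -> None:
        outputs[name] = str(path.relative_to(out))

    # -- stage 1: synthetic pan-genome ------------------------------------
    pg = _stage("synth-pangenome")(synthdata.generate_pangenome)(
        synthdata.PanGenomeParams(
            n_species=config.n_species,
            core_size=config.core_size,
            shell_families=config.shell_families,
            p_shell=config.p_shell,
            cloud_rate=config.cloud_rate,
            within_family_identity=config.within_family_identity,
            between_family_identity=config.between_family_identity,
            seed=config.seed,
        )
    )
    fasta_dir = out / "proteomes"
    fasta_dir.mkdir(exist_ok=True)
    for sp, genes in pg.proteomes.items():
        synthdata.write_proteome_fasta(genes, fasta_dir / f"{sp}.faa")
        save(f"fasta_{sp}", fasta_dir / f"{sp}.faa")
    pg.truth.to_csv(out / "family_truth.tsv", sep="\t", index=False)
    save("family_truth", out / "family_truth.tsv")

    # -- stage 2: clustering and matrix -----------------------------------
    cfg = pangenome.ClusteringConfig(
        min_coverage=config.min_coverage, min_identity=config.min_identity
    )
    clusters = _stage("cluster")(pangenome.cluster_orthologs)(pg.proteomes, cfg)
    pangenome.write_clusters_tsv(clusters, out / "clusters.tsv")
    save("clusters", out / "clusters.tsv")
    matrix = pangenome.build_matrix(clusters, sorted(pg.proteomes))
    pangenome.write_matrix_tsv(matrix, out / "matrix.tsv")
    save("matrix", out / "matrix.tsv")
    classification = pangenome.classify_matrix(matrix)
    write_json(classification.as_dict(), out / "classification.json")
    save("classification", out / "classification.json")

    # -- stage 3: accumulation curves and fits ----------------------------
    curve = _stage("panfit")(panfit.sample_curves)(
        matrix, n_permutations=config.n_permutations, seed=config.seed
    )
    curve.as_frame().to_csv(out / "curves.tsv", sep="\t", index=False)
    save("curves", out / "curves.tsv")
    growth_fit = panfit.fit_pan_growth(curve)
    core_fit = panfit.fit_core_decay(curve)
    write_json(
        {"pan_growth": growth_fit.as_dict(), "core_decay": core_fit.as_dict()},
        out / "fits.json",
    )
    save("fits", out / "fits.json")

    # -- stage 4: functional pivot ----------------------------------------
    ann = _stage("annotate")(synthdata.generate_annotations)(
        pg.truth,
        n_functions=config.n_functions,
        split_rate=config.split_rate,
        seed=config.seed,
    )
    ann.table.to_csv(out / "annotations.tsv", sep="\t", index=False)
    save("annotations", out / "annotations.tsv")
    cluster_ann = majority_cluster_annotations(clusters, ann.table)
    syn_table = funcpivot.SynonymTable(ann.synonyms)
    functional = _stage("pivot")(funcpivot.pivot)(matrix, cluster_ann, syn_table)
    functional.matrix.astype(int).to_csv(out / "functional_matrix.tsv", sep="\t")
    save("functional_matrix", out / "functional_matrix.tsv")
    hidden = funcpivot.hidden_core(matrix, functional)
    write_json(
        {"report": functional.report(), "hidden_core": hidden},
        out / "pivot_report.json",
    )
    save("pivot_report", out / "pivot_report.json")

    # -- stage 5: networks, drafts, phenotype arrays ----------------------
    net = _stage("synth-network")(synthdata.generate_true_network)(
        n_species=config.n_species,
        db_size=config.db_size,
        shared_fraction=config.shared_fraction,
        seed=config.seed,
        chain_len=config.chain_len,
        n_dead=config.n_dead,
        growth_threshold=config.epsilon,
    )
    model_dir = out / "models"
    model_dir.mkdir(exist_ok=True)
    for sp, model in net.species_models.items():
        pangem.write_model(model, model_dir / f"{sp}.xml")
        save(f"model_{sp}", model_dir / f"{sp}.xml")
    write_reaction_db_tsv(net.universal_db, out / "universal_db.tsv")
    save("universal_db", out / "universal_db.tsv")

    drafts, gaps = _stage("degrade")(synthdata.degrade_models)(
        net, config.gap_fraction, seed=config.seed
    )
    for sp, model in drafts.items():
        pangem.write_model(model, model_dir / f"{sp}_draft.xml")
        save(f"draft_{sp}", model_dir / f"{sp}_draft.xml")
    write_json(gaps.removed, out / "planted_gaps.json")
    save("planted_gaps", out / "planted_gaps.json")

    arrays = {}
    for sp, model in net.species_models.items():
        calls, unmappable = _stage("array")(synthdata.simulate_phenotype_array)(
            model, net.compound_panel, net.base_media, config.epsilon
        )
        arrays[sp] = calls
    pd.DataFrame(arrays).to_csv(out / "phenotype_arrays.tsv", sep="\t")
    save("phenotype_arrays", out / "phenotype_arrays.tsv")

    # -- stage 6: pan-GEM ---------------------------------------------------
    species = sorted(net.species_models)
    pg_models = [net.species_models[sp] for sp in species]
    supra = _stage("pangem")(pangem.build_pangem)(pg_models, species)
    supra.to_tsv(out / "pangem.tsv")
    save("pangem", out / "pangem.tsv")
    write_json(supra.census(), out / "pangem_census.json")
    save("pangem_census", out / "pangem_census.json")

    # -- stage 7: gap filling ---------------------------------------------
    gap_results = {}
    for sp in species:
        conds = [
            gapfill.condition_media(net.base_media, cpd)
            for cpd, ok in arrays[sp].items()
            if ok
        ]
        res = _stage("gapfill")(gapfill.gapfill)(
            drafts[sp],
            net.universal_db,
            conds,
            epsilon=config.epsilon,
            big_m=config.big_m,
        )
        gap_results[sp] = {
            "added": res.added,
            "planted": gaps.removed[sp],
            "recovered_exactly": res.added == gaps.removed[sp],
            "discarded_conditions": res.discarded,
            "essential": res.essential,
        }
    write_json(gap_results, out / "gapfill_results.json")
    save("gapfill_results", out / "gapfill_results.json")

    # -- stage 8: pathway clustergrams ------------------------------------
    defs = [
        pathways.PathwayDefinition(
            f"{cpd}_utilization", frozenset(rxns + [f"T_{cpd}"])
        )
        for cpd, rxns in net.chain_reactions.items()
    ]
    profile = _stage("pathways")(pathways.score_presence)(supra, defs)
    gram = pathways.cluster_profiles(profile, reference="pan")
    gram.similarity.to_csv(out / "pathway_similarity.tsv", sep="\t")
    save("pathway_similarity", out / "pathway_similarity.tsv")
    gram.heatmap.to_csv(out / "pathway_heatmap.tsv", sep="\t")
    save("pathway_heatmap", out / "pathway_heatmap.tsv")
    (out / "pathway_tree.nwk").write_text(gram.newick + "\n")
    save("pathway_tree", out / "pathway_tree.nwk")

    manifest = {
        "config": config.to_json(),
        "outputs": outputs,
        "checksums": {name: sha256_of(out / rel) for name, rel in outputs.items()},
        "summary": {
            "n_genes": int(len(pg.truth)),
            "n_clusters": int(len(clusters)),
            "classification": classification.as_dict(),
            "pan_growth_rate": growth_fit.new_families_at_N,
            "core_asymptote": core_fit.omega,
            "collapse_ratio": functional.collapse_ratio,
            "hidden_core": hidden,
            "pangem_census": supra.census(),
            "gapfill_exact": all(
                r["recovered_exactly"] for r in gap_results.values()
            ),
            "leaf_order": gram.leaf_order,
        },
    }
    write_json(manifest, out / "manifest.json")
    return manifest
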