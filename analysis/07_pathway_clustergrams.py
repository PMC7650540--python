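"""Score per-compound utilization pathways across species, compute Jaccard
similarities and produce the average-linkage clustergram (pan-reactome and
reference-strain modes)."""

from __future__ import annotations

import json

from _common import parse_args

from panmet.io import write_json
from panmet.pangem import build_pangem, load_model
from panmet.pathways import PathwayDefinition, cluster_profiles, score_presence

args = parse_args(__doc__)
inputs = args.results / "inputs"
out = args.results / "pathways"
out.mkdir(parents=True, exist_ok=True)

paths = sorted(p for p in (inputs / "models").glob("*.xml") if "_draft" not in p.stem)
species = [p.stem for p in paths]
supra = build_pangem([load_model(p) for p in paths], species)

truth = json.loads((inputs / "network_truth.json").read_text())
definitions = [
    PathwayDefinition(f"{cpd}_utilization", frozenset(rxns + [f"T_{cpd}"]))
    for cpd, rxns in truth["chain_reactions"].items()
]
profile = score_presence(supra, definitions)

pan_gram = cluster_profiles(profile, reference="pan")
ref_gram = cluster_profiles(profile, reference=species[0])
pan_gram.similarity.to_csv(out / "species_similarity.tsv", sep="\t")
pan_gram.heatmap.to_csv(out / "heatmap_pan_referenced.tsv", sep="\t")
ref_gram.heatmap.to_csv(out / f"heatmap_{species[0]}_referenced.tsv", sep="\t")
(out / "clustergram.nwk").write_text(pan_gram.newick + "\n")

write_json(
    {
        "pathways": profile.pathways,
        "dropped": profile.dropped,
        "leaf_order": pan_gram.leaf_order,
        "newick": pan_gram.newick,
    },
    out / "clustergram_report.json",
)
print(f"{len(profile.pathways)} pathways scored over {len(species)} species")
print(f"clustergram leaf order: {pan_gram.leaf_order}")
print(f"dendrogram: {pan_gram.newick}")
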