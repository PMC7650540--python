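"""Pathway presence scoring, Jaccard similarity and clustergrams.

Reactions belonging to a pathway (e.g. the biosynthesis or degradation
route of one amino acid) are scored present/absent per species from the
pan-GEM presence flags.  Species are then compared by the Jaccard
similarity of their pathway reaction sets and clustered agglomeratively
(average linkage / UPGMA) on the distance 1 - J; the heat-map table is
emitted in leaf order, referenced either to the pan-reactome (all pathway
reactions seen in any species) or to a chosen reference strain.

Two species that both lack a pathway entirely are treated as maximally
similar for that pathway (empty-vs-empty Jaccard := 1), and such cells
are flagged in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .pangem import PanGEM


class PathwayError(ValueError):
    pass


@dataclass(frozen=True)
class PathwayDefinition:
    """A named pathway and its member reaction ids (pan-GEM namespace)."""

    pathway_id: str
    reactions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.reactions:
            raise PathwayError(f"pathway {self.pathway_id!r} has no reactions")


def read_pathways_tsv(path) -> list[PathwayDefinition]:
    """Two-column TSV (pathway id, reaction id), one reaction per line."""
    frame = pd.read_csv(path, sep="\t")
    return [
        PathwayDefinition(pid, frozenset(group.iloc[:, 1]))
        for pid, group in frame.groupby(frame.columns[0])
    ]


def default_amino_acid_pathways() -> list[PathwayDefinition]:
    """The shipped amino-acid pathway template (ModelSEED-style rxn ids).

    An editable starting point, not a curated resource: real analyses
    should replace it with pathway definitions keyed to the reaction
    namespace of their own reconstructions (``read_pathways_tsv``).
    """
    from importlib.resources import files

    with (files("panmet") / "data" / "amino_acid_pathways.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    return [
        PathwayDefinition(pid, frozenset(group["reaction"]))
        for pid, group in frame.groupby("pathway")
    ]


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a n b| / |a u b|; two empty sets are defined as similarity 1."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)


@dataclass
class PathwayProfile:
    """Per-species pathway reaction sets plus resolution diagnostics."""

    members: dict[str, dict[str, frozenset[str]]]  # species -> pathway -> present
    pathways: list[str]
    species: list[str]
    pan_sets: dict[str, frozenset[str]]  # pathway -> union across species
    dropped: list[str]  # pathways with no resolvable reaction
    unresolved: dict[str, list[str]]  # pathway -> ids absent from the pan-GEM

    def presence_bits(self) -> pd.DataFrame:
        """(species, pathway, reaction) presence bits as a long table."""
        rows = [
            (sp, pw, rxn, rxn in self.members[sp][pw])
            for sp in self.species
            for pw in self.pathways
            for rxn in sorted(self.pan_sets[pw])
        ]
        return pd.DataFrame(rows, columns=["species", "pathway", "reaction", "present"])

    def reference_table(self, reference: str = "pan") -> pd.DataFrame:
        """Species x pathway Jaccard table against a reference set.

        ``reference='pan'`` scores each species' pathway set against the
        pan-reactome set of that pathway; any species id scores against
        that strain's own sets (the two modes agree when the reference
        strain carries the full pan set).
        """
        if reference == "pan":
            ref_sets = self.pan_sets
        elif reference in self.species:
            ref_sets = self.members[reference]
        else:
            raise PathwayError(f"unknown reference {reference!r}")
        data = {
            pw: [jaccard(self.members[sp][pw], ref_sets[pw]) for sp in self.species]
            for pw in self.pathways
        }
        return pd.DataFrame(data, index=self.species)

    def species_similarity(self) -> pd.DataFrame:
        """Symmetric species x species Jaccard over all pathway reactions."""
        pooled = {
            sp: frozenset().union(*self.members[sp].values())
            for sp in self.species
        }
        n = len(self.species)
        sim = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                sim[i, j] = sim[j, i] = jaccard(
                    pooled[self.species[i]], pooled[self.species[j]]
                )
        return pd.DataFrame(sim, index=self.species, columns=self.species)


def score_presence(
    pangem: PanGEM, definitions: Sequence[PathwayDefinition]
) -> PathwayProfile:
    """Score pathway reaction presence per species from pan-GEM flags.

    Pathway member ids missing from the pan-GEM namespace are reported as
    unresolved; a pathway with no resolvable member at all is dropped with
    a warning.
    """
    import warnings

    known = set(pangem.table.index)
    pathways, dropped, unresolved = [], [], {}
    resolved_defs: dict[str, frozenset[str]] = {}
    for pd_ in definitions:
        missing = sorted(pd_.reactions - known)
        keep = pd_.reactions & known
        if missing:
            unresolved[pd_.pathway_id] = missing
        if not keep:
            warnings.warn(
                f"pathway {pd_.pathway_id!r}: no member reaction resolves, dropped",
                stacklevel=2,
            )
            dropped.append(pd_.pathway_id)
            continue
        pathways.append(pd_.pathway_id)
        resolved_defs[pd_.pathway_id] = frozenset(keep)

    members: dict[str, dict[str, frozenset[str]]] = {}
    for sp in pangem.species:
        have = pangem.reactions_of(sp, classification=None)
        members[sp] = {
            pw: frozenset(resolved_defs[pw] & have) for pw in pathways
        }
    pan_sets = {
        pw: frozenset().union(*(members[sp][pw] for sp in pangem.species))
        for pw in pathways
    }
    return PathwayProfile(
        members=members,
        pathways=pathways,
        species=list(pangem.species),
        pan_sets=pan_sets,
        dropped=dropped,
        unresolved=unresolved,
    )


@dataclass
class Clustergram:
    """Average-linkage clustering result plus the ordered heat-map table."""

    linkage: np.ndarray
    leaf_order: list[str]
    newick: str
    heatmap: pd.DataFrame  # rows in leaf order
    similarity: pd.DataFrame


def _newick(linkage: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for k, (a, b, height, _) in enumerate(linkage):
        a, b = int(a), int(b)
        la = heights[a]
        lb = heights[b]
        nodes[n + k] = (
            f"({nodes[a]}:{height - la:.6g},{nodes[b]}:{height - lb:.6g})"
        )
        heights[n + k] = float(height)
    return nodes[n + len(linkage) - 1] + ";"


def cluster_profiles(
    profile: PathwayProfile, reference: str = "pan"
) -> Clustergram:
    """Agglomerative clustering of species on Jaccard distance 1 - J.

    Uses average linkage (UPGMA) on the species-by-species Jaccard
    similarity over pathway reactions; the heat-map table (species x
    pathway similarity to the reference) is returned in leaf order, and the
    dendrogram is also serialized as a Newick string with branch lengths.
    """
    if len(profile.species) < 2:
        raise PathwayError("clustering needs at least 2 species")
    sim = profile.species_similarity()
    dist = 1.0 - sim.to_numpy()
    np.fill_diagonal(dist, 0.0)
    linkage = average(squareform(dist, checks=False))
    order = [profile.species[i] for i in leaves_list(linkage)]
    heat = profile.reference_table(reference).loc[order]
    return Clustergram(
        linkage=linkage,
        leaf_order=order,
        newick=_newick(linkage, profile.species),
        heatmap=heat,
        similarity=sim,
    )
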