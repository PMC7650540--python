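"""Ortholog clustering and the pan-genomic presence/count matrix.

Proteins from several species are grouped into ortholog families by
bidirectional best hit (BDBH): for every ordered species pair the best
scoring global alignment defines a hit, reciprocal hits that pass the
coverage and identity thresholds become edges, and ortholog clusters are
the connected components of that graph.  BDBH is deterministic and can be
checked against a brute-force all-pairs-alignment oracle, which is why it
stands in for Markov-clustering based orthology here; the configuration
records the customary Markov granularity parameter for provenance only.

The pan-genomic matrix has one row per cluster and one column per species,
with member counts as entries; classification splits rows into the core
genome (present in every species), strain-specific rows (exactly one
species) and the shell (the remainder).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices


class InputError(ValueError):
    """Bad or empty inputs (named in the message)."""


@dataclass(frozen=True)
class ClusteringConfig:
    """Thresholds and alignment scoring for BDBH ortholog clustering.

    ``min_identity`` over ``min_coverage`` of the shorter sequence stands in
    for the customary alignment E-value cutoff of 1e-5 used with
    Markov-cluster orthology; ``granularity`` is recorded for provenance
    and has no effect on BDBH.
    """

    min_coverage: float = 0.75
    min_identity: float = 0.40
    granularity: float = 1.5
    substitution_matrix: str = "BLOSUM62"
    open_gap_score: float = -11.0
    extend_gap_score: float = -1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.min_coverage <= 1.0):
            raise ValueError("min_coverage must lie in (0, 1]")
        if not (0.0 <= self.min_identity <= 1.0):
            raise ValueError("min_identity must lie in [0, 1]")

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load(
            self.substitution_matrix
        )
        aligner.open_gap_score = self.open_gap_score
        aligner.extend_gap_score = self.extend_gap_score
        return aligner


@dataclass
class OrthologCluster:
    """One ortholog family: (species, gene) members and a representative."""

    cluster_id: str
    members: frozenset[tuple[str, str]]
    representative: str

    def species(self) -> set[str]:
        return {sp for sp, _ in self.members}


def alignment_stats(
    a: str, b: str, aligner: Align.PairwiseAligner
) -> tuple[float, float, float]:
    """(score, identity, coverage) of one optimal global alignment.

    Identity is matched positions over the shorter sequence length;
    coverage is aligned (both non-gap) positions over the shorter length.
    """
    aln = aligner.align(a, b)[0]
    matches = aligned = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        aligned += ea - sa
        matches += sum(
            1 for x, y in zip(a[sa:ea], b[sb:eb]) if x == y
        )
    shorter = min(len(a), len(b))
    return float(aln.score), matches / shorter, aligned / shorter


def _validated(proteomes: dict[str, dict[str, str]]) -> dict[str, dict[str, str]]:
    if not proteomes:
        raise InputError("no proteomes supplied")
    for sp, genes in proteomes.items():
        if not genes:
            raise InputError(f"empty proteome for species {sp!r}")
        for gene, seq in genes.items():
            if not seq:
                raise InputError(f"empty sequence for gene {gene!r} ({sp})")
    return {sp: dict(sorted(proteomes[sp].items())) for sp in sorted(proteomes)}


def cluster_orthologs(
    proteomes: dict[str, dict[str, str]],
    config: ClusteringConfig | None = None,
) -> list[OrthologCluster]:
    """Partition all genes into ortholog clusters by bidirectional best hit.

    Best hits are chosen by alignment score, with ties broken by higher
    identity and then lexicographic gene id; only reciprocal hits passing
    the identity and coverage thresholds become edges.  Inputs are sorted
    internally, so the clustering is invariant to input order.  Every gene
    appears in exactly one cluster (unmatched genes are singletons).
    """
    config = config or ClusteringConfig()
    proteomes = _validated(proteomes)
    aligner = config.aligner()
    species = list(proteomes)

    # best passing hit per (gene, target species)
    stats_cache: dict[tuple[str, str], tuple[float, float, float]] = {}

    def stats(g1: str, s1: str, g2: str, s2: str):
        key = (g1, g2) if g1 < g2 else (g2, g1)
        if key not in stats_cache:
            a = proteomes[s1][g1] if g1 < g2 else proteomes[s2][g2]
            b = proteomes[s2][g2] if g1 < g2 else proteomes[s1][g1]
            stats_cache[key] = alignment_stats(a, b, aligner)
        return stats_cache[key]

    best: dict[tuple[str, str], str] = {}
    for i, sa in enumerate(species):
        for sb in species[i + 1 :]:
            for ga in proteomes[sa]:
                candidates = []
                for gb in proteomes[sb]:
                    score, ident, cov = stats(ga, sa, gb, sb)
                    if ident >= config.min_identity and cov >= config.min_coverage:
                        candidates.append((score, ident, gb))
                if candidates:
                    best[(ga, sb)] = min(
                        candidates, key=lambda t: (-t[0], -t[1], t[2])
                    )[2]
            for gb in proteomes[sb]:
                candidates = []
                for ga in proteomes[sa]:
                    score, ident, cov = stats(ga, sa, gb, sb)
                    if ident >= config.min_identity and cov >= config.min_coverage:
                        candidates.append((score, ident, ga))
                if candidates:
                    best[(gb, sa)] = min(
                        candidates, key=lambda t: (-t[0], -t[1], t[2])
                    )[2]

    # reciprocal best hits -> union-find components
    gene_species = {
        gene: sp for sp, genes in proteomes.items() for gene in genes
    }
    parent = {g: g for g in gene_species}

    def find(g: str) -> str:
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for (ga, sb), gb in best.items():
        sa = gene_species[ga]
        if best.get((gb, sa)) == ga:
            union(ga, gb)

    groups: dict[str, list[str]] = {}
    for g in sorted(gene_species):
        groups.setdefault(find(g), []).append(g)
    clusters = []
    for idx, root in enumerate(sorted(groups)):
        members = groups[root]
        clusters.append(
            OrthologCluster(
                cluster_id=f"C{idx + 1:05d}",
                members=frozenset((gene_species[g], g) for g in members),
                representative=min(members),
            )
        )
    return clusters


def brute_force_clusters(
    proteomes: dict[str, dict[str, str]],
    config: ClusteringConfig | None = None,
) -> list[frozenset[str]]:
    """All-pairs-alignment connected components at the same thresholds.

    The independent oracle for ``cluster_orthologs`` on small instances:
    every gene pair (any species) passing identity and coverage thresholds
    is an edge; components are returned as frozensets of gene ids.
    """
    config = config or ClusteringConfig()
    proteomes = _validated(proteomes)
    aligner = config.aligner()
    genes = [(sp, g, seq) for sp in proteomes for g, seq in proteomes[sp].items()]
    parent = {g: g for _, g, _ in genes}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            _, gi, si = genes[i]
            _, gj, sj = genes[j]
            _, ident, cov = alignment_stats(si, sj, aligner)
            if ident >= config.min_identity and cov >= config.min_coverage:
                ri, rj = find(gi), find(gj)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[str, set[str]] = {}
    for _, g, _ in genes:
        groups.setdefault(find(g), set()).add(g)
    return [frozenset(v) for _, v in sorted(groups.items())]


def two_stage_cluster(
    proteomes: dict[str, dict[str, str]],
    representatives: dict[str, str] | None = None,
    config: ClusteringConfig | None = None,
) -> list[OrthologCluster]:
    """Optional two-stage driver: intra-species clustering first, then
    inter-species clustering of user-chosen representative strains.

    ``representatives`` maps a species group label to the species id whose
    genes represent the group in stage 2; by default every species
    represents itself (reducing to single-stage clustering).
    """
    if not representatives:
        return cluster_orthologs(proteomes, config)
    chosen = {rep: proteomes[rep] for rep in representatives.values()}
    return cluster_orthologs(chosen, config)


# ---------------------------------------------------------------------------
# The pan-genomic matrix
# ---------------------------------------------------------------------------


def build_matrix(
    clusters: list[OrthologCluster], species_list: list[str]
) -> pd.DataFrame:
    """Clusters x species member-count matrix.

    Entry (c, s) is the number of members of cluster c drawn from species
    s; a binarized view is ``matrix > 0``.  Column sums recount each
    species' clustered genes exactly.
    """
    known = set(species_list)
    counts = {}
    for cl in clusters:
        row = dict.fromkeys(species_list, 0)
        for sp, _ in cl.members:
            if sp not in known:
                raise InputError(f"unknown species id {sp!r} in {cl.cluster_id}")
            row[sp] += 1
        counts[cl.cluster_id] = row
    matrix = pd.DataFrame.from_dict(counts, orient="index", columns=species_list)
    matrix = matrix.loc[sorted(matrix.index)]
    matrix.index.name = "cluster"
    return matrix


@dataclass
class MatrixClassification:
    """Core / shell / strain-specific partition of matrix rows."""

    core: int
    strain_specific: int
    shell: int
    total: int
    percentages: dict[str, int]  # rounded to nearest integer
    degenerate_single_species: bool = False

    def as_dict(self) -> dict:
        return {
            "core": self.core,
            "strain_specific": self.strain_specific,
            "shell": self.shell,
            "total": self.total,
            "percentages": dict(self.percentages),
            "degenerate_single_species": self.degenerate_single_species,
        }


def classify_matrix(matrix: pd.DataFrame) -> MatrixClassification:
    """Partition rows into core / strain-specific / shell with percentages.

    With a single species every row is simultaneously core and
    strain-specific; such rows are counted under core and the degeneracy is
    flagged.
    """
    if matrix.empty:
        raise InputError("empty pan-genome matrix")
    present = matrix.to_numpy() > 0
    n_species = present.shape[1]
    per_row = present.sum(axis=1)
    core = int((per_row == n_species).sum())
    if n_species == 1:
        return MatrixClassification(
            core=core,
            strain_specific=0,
            shell=0,
            total=core,
            percentages={"core": 100, "strain_specific": 0, "shell": 0},
            degenerate_single_species=True,
        )
    strain_specific = int((per_row == 1).sum())
    total = int(present.shape[0])
    shell = total - core - strain_specific
    pct = {
        "core": round(100.0 * core / total),
        "strain_specific": round(100.0 * strain_specific / total),
        "shell": round(100.0 * shell / total),
    }
    return MatrixClassification(
        core=core,
        strain_specific=strain_specific,
        shell=shell,
        total=total,
        percentages=pct,
    )


def write_clusters_tsv(clusters: list[OrthologCluster], path) -> None:
    rows = [
        (cl.cluster_id, sp, gene)
        for cl in clusters
        for sp, gene in sorted(cl.members)
    ]
    pd.DataFrame(rows, columns=["cluster", "species", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
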