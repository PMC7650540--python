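"""Synthetic inputs with known ground truth for every pipeline stage.

Generates (a) per-species proteomes with planted core/shell/cloud ortholog
families under an open pan-genome model, (b) toy metabolic networks (a
"true" network per species plus a superset universal reaction database),
(c) draft models with planted gaps, (d) phenotype-array growth calls
computed on the true network, and (e) functional annotation tables with
controlled synonym noise.

Sequences are synthetic amino-acid strings produced by mutating a family
ancestor at a per-site substitution rate chosen to hit the identity
targets; there is no codon model, because downstream clustering only needs
controlled pairwise identity.  Toy networks are layered
uptake -> conversion -> biomass chains with stoichiometries in {1, 2};
biomass is a single sink reaction, which is all that flux balance analysis
and the gap-filling MILP need to be exercised.

All randomness flows from one explicit integer seed; no global random
state is touched, and a fixed seed gives byte-identical artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd

from .gapfill import Media, ReactionRecord, fba

AA_ALPHABET = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")


class GenerationError(RuntimeError):
    """Raised when a synthetic instance cannot be constructed."""


# ---------------------------------------------------------------------------
# Pan-genome sequence generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanGenomeParams:
    """Parameters of the planted core/shell/cloud pan-genome model.

    ``core_size`` families occur once in every species; each of
    ``shell_families`` occurs in a species independently with probability
    ``p_shell``; every species additionally carries Poisson(``cloud_rate``)
    strain-specific (cloud) families, which makes the pan-genome open with
    an expected ``cloud_rate`` new families per added genome.
    """

    n_species: int = 5
    core_size: int = 100
    shell_families: int = 0
    p_shell: float = 0.5
    cloud_rate: float = 0.0
    within_family_identity: float = 0.9
    between_family_identity: float = 0.2
    seq_length: tuple[int, int] = (140, 220)
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.core_size < 0 or self.shell_families < 0:
            raise ValueError("family counts must be non-negative")
        if self.shell_families and not (0.0 < self.p_shell < 1.0):
            raise ValueError("p_shell must lie in (0, 1)")
        if self.cloud_rate < 0:
            raise ValueError("cloud_rate must be non-negative")
        if not (0.0 < self.within_family_identity <= 1.0):
            raise ValueError("within_family_identity must lie in (0, 1]")
        if not (0.0 <= self.between_family_identity < 1.0):
            raise ValueError("between_family_identity must lie in [0, 1)")
        if self.within_family_identity <= self.between_family_identity:
            raise ValueError(
                "within_family_identity must exceed between_family_identity"
            )


@dataclass
class SyntheticPanGenome:
    """Proteomes plus the hidden family label of every gene."""

    proteomes: dict[str, dict[str, str]]  # species -> gene_id -> sequence
    truth: pd.DataFrame  # columns: gene, species, family
    params: PanGenomeParams

    @property
    def n_families(self) -> int:
        return self.truth["family"].nunique()

    def family_of(self) -> dict[str, str]:
        return dict(zip(self.truth["gene"], self.truth["family"]))


def _mutate(ancestor: np.ndarray, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``rate`` (always to a new AA)."""
    seq = ancestor.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    for i in hits:
        choices = AA_ALPHABET[AA_ALPHABET != seq[i]]
        seq[i] = rng.choice(choices)
    return seq.tobytes().decode()


def generate_pangenome(params: PanGenomeParams) -> SyntheticPanGenome:
    """Generate per-species proteomes with planted ortholog families.

    Each family descends from an independent random ancestor; within-family
    copies are mutated so that expected pairwise identity stays at or above
    ``within_family_identity``, while unrelated ancestors share only the
    background identity (~5 %), far below ``between_family_identity``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    # Per-copy substitution rate: two copies mutated at rate r from a shared
    # ancestor have expected identity ~(1-r)^2; the 0.8 margin keeps sampled
    # pairwise identities above the declared floor.
    rate = (1.0 - math.sqrt(params.within_family_identity)) * 0.8

    species = [f"S{i + 1:02d}" for i in range(params.n_species)]
    presence: list[tuple[str, list[str]]] = []  # family -> species carrying it

    for i in range(params.core_size):
        presence.append((f"F{len(presence):05d}", list(species)))
    for _ in range(params.shell_families):
        carriers = [s for s in species if rng.random() < params.p_shell]
        if not carriers:  # a never-observed family is not part of the pan-genome
            carriers = [species[int(rng.integers(params.n_species))]]
        presence.append((f"F{len(presence):05d}", carriers))
    for sp in species:
        for _ in range(int(rng.poisson(params.cloud_rate))):
            presence.append((f"F{len(presence):05d}", [sp]))

    lo, hi = params.seq_length
    proteomes: dict[str, dict[str, str]] = {sp: {} for sp in species}
    rows = []
    counters = dict.fromkeys(species, 0)
    for family, carriers in presence:
        ancestor = rng.choice(AA_ALPHABET, size=int(rng.integers(lo, hi + 1)))
        for sp in carriers:
            counters[sp] += 1
            gene = f"{sp}_g{counters[sp]:05d}"
            proteomes[sp][gene] = _mutate(ancestor, rate, rng)
            rows.append((gene, sp, family))

    truth = pd.DataFrame(rows, columns=["gene", "species", "family"])
    return SyntheticPanGenome(proteomes=proteomes, truth=truth, params=params)


def write_proteome_fasta(proteome: dict[str, str], path) -> None:
    """Write one species' proteome as FASTA (deterministic byte layout)."""
    with open(path, "w") as fh:
        for gene in sorted(proteome):
            fh.write(f">{gene}\n{proteome[gene]}\n")


# ---------------------------------------------------------------------------
# Toy metabolic networks
# ---------------------------------------------------------------------------

BIOMASS_ID = "BIOMASS"


@dataclass
class TrueNetwork:
    """A planted genus: per-species true models inside a universal database.

    ``universal_db`` is the superset reaction table (the ModelSEED stand-in);
    every species model is a subset of it plus the biomass sink.  The panel
    lists carbon-source compounds whose exchange reactions exist in the
    database; ``dead_end_compounds`` have an exchange but no conversion
    route anywhere in the database, so no model can ever grow on them.
    """

    universal_db: dict[str, ReactionRecord]
    species_models: dict[str, cobra.Model]
    species_reactions: dict[str, set[str]]
    compound_panel: list[str]
    dead_end_compounds: list[str]
    chain_reactions: dict[str, list[str]]  # compound -> ordered chain rxn ids
    species_compounds: dict[str, set[str]]  # compounds with a full chain
    base_media: Media
    biomass_id: str = BIOMASS_ID


def _chain_records(
    compound: str, chain_len: int, rng: np.random.Generator
) -> list[ReactionRecord]:
    """Exchange + transporter + conversion chain down to the hub metabolite."""
    records = [
        ReactionRecord(f"EX_{compound}", {f"{compound}_e": -1.0}, -1000.0, 1000.0),
        ReactionRecord(
            f"T_{compound}",
            {f"{compound}_e": -1.0, f"{compound}_c": 1.0},
            -1000.0,
            1000.0,
        ),
    ]
    prev = f"{compound}_c"
    for j in range(chain_len):
        nxt = "hub_c" if j == chain_len - 1 else f"{compound}_m{j + 1}_c"
        coeff = float(rng.integers(1, 3))  # product stoichiometry in {1, 2}
        records.append(
            ReactionRecord(
                f"R_{compound}_{j + 1}",
                {prev: -1.0, nxt: coeff},
                0.0,
                1000.0,
                gene_support=True,
            )
        )
        prev = nxt
    return records


def generate_true_network(
    n_species: int,
    db_size: int = 30,
    shared_fraction: float = 0.5,
    seed: int = 0,
    chain_len: int = 3,
    n_dead: int = 1,
    n_decoys: int = 3,
    growth_threshold: float = 1e-3,
) -> TrueNetwork:
    """Plant per-species true networks inside a superset universal database.

    ``db_size`` sets the approximate universal-database size; each panel
    compound costs ``chain_len + 2`` reactions (exchange, transporter,
    chain).  Compound ``c1`` is the shared base carbon source present in
    every species; every other live compound is either shared by all
    species (probability ``shared_fraction``) or assigned to a random
    non-empty subset.  Decoy reactions produce dead-end metabolites and can
    never carry steady-state flux.  Every species model is verified to grow
    on the base medium at build time.
    """
    per_compound = chain_len + 2
    n_compounds = max(2, db_size // per_compound)
    if n_compounds < 1 + n_dead:
        raise GenerationError(
            f"db_size={db_size} too small for chain_len={chain_len} "
            f"and {n_dead} dead-end compounds"
        )
    rng = np.random.default_rng(seed)
    species = [f"S{i + 1:02d}" for i in range(n_species)]
    compounds = [f"c{i + 1}" for i in range(n_compounds)]
    live = compounds[: n_compounds - n_dead]
    dead = compounds[n_compounds - n_dead :]

    db: dict[str, ReactionRecord] = {}
    chains: dict[str, list[str]] = {}
    for cpd in live:
        recs = _chain_records(cpd, chain_len, rng)
        for r in recs:
            db[r.id] = r
        chains[cpd] = [r.id for r in recs if r.id.startswith("R_")]
    for cpd in dead:  # exchange only: unfillable growth conditions
        r = ReactionRecord(f"EX_{cpd}", {f"{cpd}_e": -1.0}, -1000.0, 1000.0)
        db[r.id] = r
    for j in range(n_decoys):
        db[f"DEC_{j + 1}"] = ReactionRecord(
            f"DEC_{j + 1}", {"hub_c": -1.0, f"dead{j + 1}_c": 1.0}, 0.0, 1000.0
        )

    base = live[0]
    species_compounds: dict[str, set[str]] = {sp: {base} for sp in species}
    for cpd in live[1:]:
        if rng.random() < shared_fraction:
            carriers = list(species)
        else:
            carriers = [s for s in species if rng.random() < 0.5]
            if not carriers:
                carriers = [species[int(rng.integers(n_species))]]
        for sp in carriers:
            species_compounds[sp].add(cpd)

    biomass = ReactionRecord(BIOMASS_ID, {"hub_c": -1.0}, 0.0, 1000.0)
    base_media = Media({base: 10.0}, name="base")

    models: dict[str, cobra.Model] = {}
    species_reactions: dict[str, set[str]] = {}
    for sp in species:
        recs = [biomass]
        for cpd in sorted(species_compounds[sp]):
            recs.extend(db[r] for r in (f"EX_{cpd}", f"T_{cpd}"))
            recs.extend(db[r] for r in chains[cpd])
        # every panel compound is probed in the phenotype array, so each
        # model carries all exchanges even where the pathway is missing
        for cpd in compounds:
            if cpd not in species_compounds[sp]:
                recs.append(db[f"EX_{cpd}"])
        model = records_to_model(recs, model_id=sp, biomass_id=BIOMASS_ID)
        growth, _ = fba(model, base_media, BIOMASS_ID)
        if growth < growth_threshold:
            raise GenerationError(f"species {sp} does not grow on base medium")
        models[sp] = model
        species_reactions[sp] = {r.id for r in recs}

    return TrueNetwork(
        universal_db=db,
        species_models=models,
        species_reactions=species_reactions,
        compound_panel=list(compounds),
        dead_end_compounds=list(dead),
        chain_reactions=chains,
        species_compounds=species_compounds,
        base_media=base_media,
    )


def records_to_model(
    records: list[ReactionRecord], model_id: str, biomass_id: str = BIOMASS_ID
) -> cobra.Model:
    """Materialize reaction records as a COBRApy model (SBML-writable)."""
    model = cobra.Model(model_id)
    mets: dict[str, cobra.Metabolite] = {}
    reactions = []
    for rec in records:
        rxn = cobra.Reaction(rec.id, lower_bound=rec.lower, upper_bound=rec.upper)
        stoich = {}
        for met_id, coeff in rec.stoichiometry.items():
            if met_id not in mets:
                mets[met_id] = cobra.Metabolite(met_id, compartment=met_id.rsplit("_", 1)[-1])
            stoich[mets[met_id]] = coeff
        reactions.append((rxn, stoich, rec.gene_support))
    model.add_reactions([r for r, _, _ in reactions])
    for i, (rxn, stoich, gene_support) in enumerate(reactions):
        rxn.add_metabolites(stoich)
        if gene_support:
            rxn.gene_reaction_rule = f"{model_id}_gene_{i:04d}"
    model.objective = biomass_id
    return model


# ---------------------------------------------------------------------------
# Planted gaps
# ---------------------------------------------------------------------------


@dataclass
class PlantedGaps:
    """Record of the reactions removed from each true model."""

    removed: dict[str, list[str]]  # species -> removed reaction ids
    gap_fraction: float
    protected: dict[str, set[str]]


def degrade_models(
    network: TrueNetwork, gap_fraction: float, seed: int
) -> tuple[dict[str, cobra.Model], PlantedGaps]:
    """Remove a fraction of unprotected reactions from every true model.

    Protected and never removed: the biomass sink, every exchange reaction,
    and the transporters of the base-medium carbon source.  Everything else
    (conversion chains, accessory transporters) may be deleted, mimicking a
    draft reconstruction with missing steps.
    """
    if not (0.0 <= gap_fraction < 1.0):
        raise ValueError("gap_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    base_cpd = next(iter(network.base_media.uptakes))
    drafts: dict[str, cobra.Model] = {}
    removed: dict[str, list[str]] = {}
    protected_by_sp: dict[str, set[str]] = {}
    for sp, model in network.species_models.items():
        protected = {network.biomass_id, f"T_{base_cpd}"}
        protected |= {r.id for r in model.reactions if r.id.startswith("EX_")}
        protected_by_sp[sp] = protected
        removable = sorted(r.id for r in model.reactions if r.id not in protected)
        k = int(math.floor(gap_fraction * len(removable)))
        gaps = sorted(rng.choice(removable, size=k, replace=False).tolist())
        draft = model.copy()
        draft.remove_reactions([draft.reactions.get_by_id(g) for g in gaps])
        drafts[sp] = draft
        removed[sp] = gaps
    return drafts, PlantedGaps(
        removed=removed, gap_fraction=gap_fraction, protected=protected_by_sp
    )


# ---------------------------------------------------------------------------
# Phenotype arrays
# ---------------------------------------------------------------------------


def simulate_phenotype_array(
    model: cobra.Model,
    compound_panel: list[str],
    base_media: Media,
    growth_threshold: float = 1e-3,
    biomass_id: str = BIOMASS_ID,
) -> tuple[pd.Series, list[str]]:
    """Growth call per panel compound as the sole carbon source (true model).

    A compound grows if the FBA biomass optimum, with that compound's uptake
    replacing the base carbon source, reaches ``growth_threshold``.  Panel
    entries without an exchange reaction in the model are reported as
    unmappable and excluded; duplicates are deduplicated.
    """
    carbon = next(iter(base_media.uptakes))
    rate = base_media.uptakes[carbon]
    calls: dict[str, bool] = {}
    unmappable: list[str] = []
    for cpd in dict.fromkeys(compound_panel):  # dedupe, keep order
        if f"EX_{cpd}" not in [r.id for r in model.reactions]:
            unmappable.append(cpd)
            continue
        uptakes = {k: v for k, v in base_media.uptakes.items() if k != carbon}
        uptakes[cpd] = rate
        growth, _ = fba(model, Media(uptakes, name=cpd), biomass_id)
        calls[cpd] = bool(growth >= growth_threshold)
    return pd.Series(calls, name="growth", dtype=bool), unmappable


# ---------------------------------------------------------------------------
# Annotations with synonym noise
# ---------------------------------------------------------------------------


@dataclass
class SyntheticAnnotations:
    """Gene annotations plus the ground-truth function key per gene."""

    table: pd.DataFrame  # columns: gene, name, ec
    synonyms: list[list[str]]  # groups of synonymous names
    family_function: dict[str, str]  # family -> true function id
    split_functions: list[str]  # functions whose families got distinct names
    expected_merges: int  # rows the functional pivot should collapse


def generate_annotations(
    truth: pd.DataFrame,
    n_functions: int,
    split_rate: float = 0.0,
    ec_fraction: float = 0.5,
    seed: int = 0,
) -> SyntheticAnnotations:
    """Annotate genes with names/ECs, planting synonym splits across families.

    Families are mapped onto ``n_functions`` functions (several families may
    share one function — the differential-clustering situation).  A fraction
    ``split_rate`` of multi-family functions have each family given a
    distinct-but-synonymous name, recorded in the synonym dictionary; an
    ``ec_fraction`` of functions also carry an EC number.  The ground-truth
    function of every gene and the number of rows a functional pivot should
    merge are recorded.
    """
    if not (0.0 <= split_rate < 1.0):
        raise ValueError("split_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    families = sorted(truth["family"].unique())
    functions = [f"fun{j:04d}" for j in range(n_functions)]
    family_function = {
        fam: functions[i % n_functions] for i, fam in enumerate(families)
    }

    fn_families: dict[str, list[str]] = {}
    for fam, fn in family_function.items():
        fn_families.setdefault(fn, []).append(fam)

    has_ec = {fn: rng.random() < ec_fraction for fn in functions}
    multi = [fn for fn in functions if len(fn_families.get(fn, [])) > 1]
    split = sorted(fn for fn in multi if rng.random() < split_rate)

    names: dict[str, str] = {}
    synonyms: list[list[str]] = []
    for fn in functions:
        if fn in split:
            group = [f"{fn} name{k}" for k in range(len(fn_families[fn]))]
            synonyms.append(group)
            for fam, nm in zip(fn_families[fn], group):
                names[fam] = nm
        else:
            for fam in fn_families.get(fn, []):
                names[fam] = f"{fn} enzyme"

    ecs = {
        fn: f"{1 + i % 6}.{1 + i % 9}.{1 + i % 9}.{1 + i}"
        for i, fn in enumerate(functions)
        if has_ec[fn]
    }
    rows = [
        (
            gene,
            names[fam],
            ecs.get(family_function[fam], ""),
        )
        for gene, fam in zip(truth["gene"], truth["family"])
    ]
    table = pd.DataFrame(rows, columns=["gene", "name", "ec"])

    # every family of a function collapses onto one functional row
    expected_merges = sum(len(v) - 1 for v in fn_families.values() if len(v) > 1)
    return SyntheticAnnotations(
        table=table,
        synonyms=synonyms,
        family_function=family_function,
        split_functions=split,
        expected_merges=expected_merges,
    )
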