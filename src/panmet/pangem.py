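"""Per-species model loading and genus-level pan-GEM consolidation.

The pan-GEM is the union of the reactions of several genome-scale models:
one row per (normalized) reaction id, with per-species presence flags and
gene-association strings, plus a classification of every reaction as
metabolic, transporter, exchange or biomass.  Reaction identity is the
database id after stripping compartment suffixes (and an optional alias
table); stoichiometric-equivalence matching is deliberately not attempted,
because consolidation assumes models built against one curated reaction
database.

SBML I/O goes through COBRApy/libsbml.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import cobra
import pandas as pd

from .gapfill import biomass_reaction_id, compartment_of


class ModelError(ValueError):
    pass


_COMPARTMENT_SUFFIX_RE = re.compile(r"(?:\[[a-zA-Z0-9]+\]|_[a-z])$")


def load_model(path) -> cobra.Model:
    """Read an SBML model and validate its structural invariants.

    Bounds must satisfy lower <= upper on every reaction; a missing
    biomass reaction is tolerated with a warning (the model then cannot be
    used for growth simulation until an objective is set).
    """
    import warnings

    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises various parse errors
        raise ModelError(f"malformed SBML in {path}: {exc}") from exc
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelError(
                f"{path}: reaction {rxn.id} has lower bound "
                f"{rxn.lower_bound} > upper bound {rxn.upper_bound}"
            )
    try:
        biomass_reaction_id(model)
    except Exception:
        warnings.warn(f"{path}: no unique biomass reaction found", stacklevel=2)
    return model


def write_model(model: cobra.Model, path) -> None:
    cobra.io.write_sbml_model(model, str(path))


def normalize_reaction_id(
    rxn_id: str, aliases: Mapping[str, str] | None = None
) -> str:
    """Database id with trailing compartment suffix stripped and aliases
    applied (e.g. mapping legacy ids onto ModelSEED ``rxn`` ids)."""
    base = _COMPARTMENT_SUFFIX_RE.sub("", rxn_id)
    if not base:  # id was nothing but a suffix; keep it
        base = rxn_id
    if aliases:
        base = aliases.get(base, base)
    return base


def classify_reaction(rxn: cobra.Reaction, biomass_id: str | None = None) -> str:
    """metabolic | transporter | exchange | biomass.

    Exchange: a single-metabolite boundary reaction.  Transporter: the
    participants span at least two compartments.  Biomass: the designated
    biomass id.  Everything else is metabolic (including reactions whose
    compartments cannot be parsed, which are logged as such by callers).
    """
    if biomass_id is not None and rxn.id == biomass_id:
        return "biomass"
    mets = list(rxn.metabolites)
    if len(mets) == 1:
        return "exchange"
    comps = {m.compartment or compartment_of(m.id) for m in mets}
    if len(comps) >= 2:
        return "transporter"
    return "metabolic"


@dataclass
class PanGEM:
    """Union reaction table with per-species presence and GPR columns."""

    table: pd.DataFrame  # index = normalized id; classification + per-species cols
    species: list[str]
    biomass_ids: dict[str, str]

    def presence(self) -> pd.DataFrame:
        return self.table[[f"presence_{sp}" for sp in self.species]].rename(
            columns=lambda c: c.removeprefix("presence_")
        )

    def core_reactions(self, classification: str | None = None) -> set[str]:
        mask = self.presence().all(axis=1)
        if classification is not None:
            mask &= self.table["classification"] == classification
        return set(self.table.index[mask])

    def census(self) -> dict[str, int]:
        counts = self.table["classification"].value_counts().to_dict()
        counts["total"] = int(self.table.shape[0])
        counts["core"] = len(self.core_reactions())
        counts["core_metabolic"] = len(self.core_reactions("metabolic"))
        return counts

    def reactions_of(self, species: str, classification: str | None = None) -> set[str]:
        mask = self.table[f"presence_{species}"]
        if classification is not None:
            mask &= self.table["classification"] == classification
        return set(self.table.index[mask])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def census_model(model: cobra.Model) -> dict[str, int]:
    """Reaction census of one model (total / metabolic / transporter /
    exchange / biomass / gene-associated counts)."""
    try:
        biomass = biomass_reaction_id(model)
    except Exception:
        biomass = None
    kinds = pd.Series([classify_reaction(r, biomass) for r in model.reactions])
    counts = kinds.value_counts().to_dict()
    counts["total"] = len(model.reactions)
    counts["gene_associated"] = sum(1 for r in model.reactions if r.genes)
    return counts


def build_pangem(
    models: Sequence[cobra.Model],
    species_ids: Sequence[str],
    aliases: Mapping[str, str] | None = None,
) -> PanGEM:
    """Consolidate per-species models into a single supra-model table.

    One row per normalized reaction id; per-species boolean presence and
    verbatim gene-association strings; classification decided by the first
    model carrying the reaction (models built on one database agree).
    The result is invariant to the order of the input models.
    """
    if len(models) != len(species_ids):
        raise ModelError("models and species_ids differ in length")
    if len(set(species_ids)) != len(species_ids):
        raise ModelError("duplicate species id")
    order = sorted(range(len(models)), key=lambda i: species_ids[i])
    models = [models[i] for i in order]
    species = [species_ids[i] for i in order]

    biomass_ids = {}
    for sp, model in zip(species, models):
        try:
            biomass_ids[sp] = biomass_reaction_id(model)
        except Exception:
            biomass_ids[sp] = ""

    rows: dict[str, dict] = {}
    for sp, model in zip(species, models):
        biomass = biomass_ids.get(sp) or None
        for rxn in model.reactions:
            rid = normalize_reaction_id(rxn.id, aliases)
            row = rows.setdefault(
                rid,
                {"classification": classify_reaction(rxn, biomass)},
            )
            row[f"presence_{sp}"] = True
            gpr = rxn.gene_reaction_rule or ""
            if gpr:
                row[f"genes_{sp}"] = gpr

    table = pd.DataFrame.from_dict(rows, orient="index")
    for sp in species:
        pcol, gcol = f"presence_{sp}", f"genes_{sp}"
        if pcol not in table:
            table[pcol] = False
        if gcol not in table:
            table[gcol] = ""
        table[pcol] = table[pcol].map(lambda v: v is True).astype(bool)
        table[gcol] = table[gcol].map(lambda v: v if isinstance(v, str) else "")
    cols = ["classification"]
    cols += [f"presence_{sp}" for sp in species]
    cols += [f"genes_{sp}" for sp in species]
    table = table[cols].loc[sorted(table.index)]
    table.index.name = "reaction"
    return PanGEM(table=table, species=list(species), biomass_ids=biomass_ids)


@dataclass
class ReactionSetCounts:
    """Set-arithmetic summary over a species grouping."""

    core: int
    group_exclusive: dict[str, int]  # in >=1 member, in 0 non-members
    group_exclusive_universal: dict[str, int]  # additionally in all members
    species_exclusive: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "core": self.core,
            "group_exclusive": dict(self.group_exclusive),
            "group_exclusive_universal": dict(self.group_exclusive_universal),
            "species_exclusive": dict(self.species_exclusive),
        }


def reaction_sets(
    pangem: PanGEM,
    grouping: Mapping[str, str],
    classification: str | None = "metabolic",
) -> ReactionSetCounts:
    """Core / group-exclusive / species-exclusive reaction counts.

    ``grouping`` maps every species to a group label (e.g. dairy vs
    commensal).  Group-exclusive reactions occur in at least one group
    member and no non-member; the universal variant additionally requires
    every member.  Counts default to metabolic reactions only, the
    denominator used for such comparisons; pass ``classification=None``
    for all reactions.
    """
    missing = set(pangem.species) - set(grouping)
    if missing:
        raise ModelError(f"grouping misses species: {sorted(missing)}")
    sets = {sp: pangem.reactions_of(sp, classification) for sp in pangem.species}
    core = set.intersection(*sets.values()) if sets else set()

    groups: dict[str, list[str]] = {}
    for sp in pangem.species:
        groups.setdefault(grouping[sp], []).append(sp)

    group_exclusive, group_universal = {}, {}
    for label, members in sorted(groups.items()):
        inside = set.union(*(sets[sp] for sp in members))
        outside_species = [sp for sp in pangem.species if sp not in members]
        outside = (
            set.union(*(sets[sp] for sp in outside_species))
            if outside_species
            else set()
        )
        exclusive = inside - outside
        universal = set.intersection(*(sets[sp] for sp in members)) - outside
        group_exclusive[label] = len(exclusive)
        group_universal[label] = len(universal)

    species_exclusive = {}
    for sp in pangem.species:
        others = set.union(
            *(sets[o] for o in pangem.species if o != sp)
        ) if len(pangem.species) > 1 else set()
        species_exclusive[sp] = len(sets[sp] - others)

    return ReactionSetCounts(
        core=len(core),
        group_exclusive=group_exclusive,
        group_exclusive_universal=group_universal,
        species_exclusive=species_exclusive,
    )


def diff_models(
    a: cobra.Model,
    b: cobra.Model,
    aliases: Mapping[str, str] | None = None,
    classification: str | None = None,
) -> tuple[set[str], set[str]]:
    """(reactions only in a, reactions only in b) by normalized id."""

    def ids(model: cobra.Model) -> set[str]:
        try:
            biomass = biomass_reaction_id(model)
        except Exception:
            biomass = None
        out = set()
        for rxn in model.reactions:
            if classification is not None and classify_reaction(rxn, biomass) != classification:
                continue
            out.add(normalize_reaction_id(rxn.id, aliases))
        return out

    ia, ib = ids(a), ids(b)
    return ia - ib, ib - ia
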