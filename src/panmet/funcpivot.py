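"""Functional pivot of the ortholog matrix and hidden-core detection.

Ortholog clustering splits true homologues across clusters when sequence
divergence is uneven, so the cluster-level matrix understates shared
functionality.  The pivot collapses clusters that encode the same function
in a two-step process: step 1 merges clusters sharing an (identical) EC
number; step 2 merges clusters whose names appear in the same synonym
group of an enzymatic-name dictionary.  Remaining names merge only when
verbatim-identical after normalization — except hypothetical/putative
proteins, which are never merged across clusters.

The "hidden core" is the set of functions present in every species even
though no single contributing cluster is: functionality the ortholog
matrix alone obscures by differential clustering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class AnnotationError(ValueError):
    pass


_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\w+|-)$")
_HYPOTHETICAL_RE = re.compile(r"\b(hypothetical|putative|uncharacteri[sz]ed)\b")


def normalize_name(name: str) -> str:
    """Case/whitespace/punctuation-insensitive canonical form of a name."""
    return re.sub(r"[^a-z0-9]+", " ", name.lower()).strip()


def parse_ec_list(ec: str | list[str] | tuple[str, ...] | None) -> tuple[str, ...]:
    """Parse an EC annotation into valid EC strings, dropping unparseable
    entries (partial ECs like ``2.8.3.-`` are kept verbatim)."""
    if ec is None:
        return ()
    items = ec if isinstance(ec, (list, tuple)) else re.split(r"[;,\s]+", str(ec))
    valid = []
    for item in items:
        item = item.strip().removeprefix("EC").strip(" :")
        if item and _EC_RE.match(item):
            valid.append(item)
    return tuple(sorted(set(valid)))


@dataclass(frozen=True)
class Annotation:
    """A (name, EC list) functional annotation of one cluster."""

    name: str
    ecs: tuple[str, ...] = ()


@dataclass(frozen=True)
class FunctionKey:
    """Canonical identity of a function; equality defines the pivot merge.

    ``rule`` records how the key was derived: ``ec`` (identical EC set),
    ``synonym`` (names in one synonym group), or ``verbatim`` (normalized
    name; suffixed with the cluster id for hypothetical/putative entries so
    they never merge).  Canonicalization is idempotent: keys canonicalize
    to themselves.
    """

    canonical: str
    ecs: tuple[str, ...]
    rule: str


class SynonymTable:
    """Groups of synonymous enzymatic names with O(1) lookup."""

    def __init__(self, groups: list[list[str]]):
        self.groups = [sorted(normalize_name(n) for n in g) for g in groups]
        self._index: dict[str, int] = {}
        for i, group in enumerate(self.groups):
            for name in group:
                if name in self._index and self._index[name] != i:
                    raise AnnotationError(f"name {name!r} in two synonym groups")
                self._index[name] = i

    def group_of(self, name: str) -> int | None:
        return self._index.get(normalize_name(name))

    def canonical_of(self, name: str) -> str | None:
        i = self.group_of(name)
        return self.groups[i][0] if i is not None else None

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SynonymTable":
        """From a two-column table (group id, name)."""
        groups = frame.groupby(frame.columns[0])[frame.columns[1]].apply(list)
        return cls(list(groups))


def canonicalize(
    annotation: Annotation,
    synonym_table: SynonymTable | None = None,
    cluster_id: str | None = None,
) -> FunctionKey:
    """Derive the merge key of an annotation.

    EC identity takes precedence over synonym-name identity over verbatim
    name identity; unparseable EC strings silently fall back to name
    matching.  Hypothetical/putative names yield per-cluster keys that
    never merge.
    """
    norm = normalize_name(annotation.name)
    if _HYPOTHETICAL_RE.search(norm):
        tag = f"{norm}|{cluster_id}" if cluster_id is not None else norm
        return FunctionKey(canonical=tag, ecs=(), rule="verbatim")
    ecs = parse_ec_list(list(annotation.ecs))
    if not ecs and annotation.name.strip().upper().startswith("EC "):
        # keys of the form "EC 2.7.2.1" re-canonicalize to themselves
        ecs = parse_ec_list(annotation.name.strip()[3:])
    if ecs:
        return FunctionKey(canonical="EC " + ";".join(ecs), ecs=ecs, rule="ec")
    if synonym_table is not None:
        canon = synonym_table.canonical_of(annotation.name)
        if canon is not None:
            return FunctionKey(canonical=canon, ecs=(), rule="synonym")
    return FunctionKey(canonical=norm, ecs=(), rule="verbatim")


@dataclass
class FunctionalMatrix:
    """Functions x species presence matrix with a cluster back-map."""

    matrix: pd.DataFrame  # bool, index = canonical function, cols = species
    back_map: dict[str, list[str]]  # canonical -> contributing cluster ids
    keys: dict[str, FunctionKey]
    collapse_ratio: float  # rows after / rows before
    n_merged: int

    def report(self) -> dict:
        rules = pd.Series({k: v.rule for k, v in self.keys.items()})
        return {
            "rows_before": int(self.matrix.shape[0] + self.n_merged),
            "rows_after": int(self.matrix.shape[0]),
            "collapse_ratio": self.collapse_ratio,
            "n_merged": self.n_merged,
            "rule_counts": rules.value_counts().to_dict(),
        }


def pivot(
    matrix: pd.DataFrame,
    cluster_annotations: dict[str, Annotation],
    synonym_table: SynonymTable | None = None,
) -> FunctionalMatrix:
    """Collapse the cluster matrix into a functional matrix.

    Each function row is the elementwise OR of its contributing cluster
    rows, so a species has a function iff it has at least one contributing
    cluster.  Every cluster must be annotated (use a "hypothetical
    protein" annotation for unknowns).
    """
    missing = [c for c in matrix.index if c not in cluster_annotations]
    if missing:
        raise AnnotationError(
            f"{len(missing)} cluster(s) lack annotations: {missing[:10]}"
        )
    presence = matrix > 0
    key_by_cluster = {
        c: canonicalize(cluster_annotations[c], synonym_table, cluster_id=c)
        for c in matrix.index
    }
    back_map: dict[str, list[str]] = {}
    keys: dict[str, FunctionKey] = {}
    for c in matrix.index:
        key = key_by_cluster[c]
        back_map.setdefault(key.canonical, []).append(c)
        keys[key.canonical] = key

    rows = {
        canon: presence.loc[clusters].any(axis=0)
        for canon, clusters in back_map.items()
    }
    fmatrix = pd.DataFrame(rows).T.astype(bool)
    fmatrix = fmatrix.loc[sorted(fmatrix.index)]
    fmatrix.index.name = "function"
    n_before, n_after = matrix.shape[0], fmatrix.shape[0]
    return FunctionalMatrix(
        matrix=fmatrix,
        back_map={k: sorted(v) for k, v in back_map.items()},
        keys=keys,
        collapse_ratio=n_after / n_before,
        n_merged=n_before - n_after,
    )


def hidden_core(
    matrix: pd.DataFrame, functional: FunctionalMatrix
) -> list[str]:
    """Functions core at the functional level but not as any single cluster.

    Exactly the functionality that differential clustering obscures: the
    OR of the contributing clusters covers every species while each
    individual cluster misses at least one.
    """
    presence = matrix > 0
    out = []
    for canon, clusters in functional.back_map.items():
        if not functional.matrix.loc[canon].all():
            continue
        if not presence.loc[clusters].all(axis=1).any():
            out.append(canon)
    return sorted(out)
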