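"""Configuration, serialization helpers and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Every parameter that affects pipeline output, in one round-trippable
    record.  Unknown keys in a serialized config are rejected rather than
    silently ignored."""

    seed: int = 0
    # synthetic pan-genome
    n_species: int = 4
    core_size: int = 8
    shell_families: int = 4
    p_shell: float = 0.5
    cloud_rate: float = 2.0
    within_family_identity: float = 0.9
    between_family_identity: float = 0.2
    # clustering
    min_coverage: float = 0.75
    min_identity: float = 0.40
    # accumulation curves
    n_permutations: int = 100
    # annotations
    n_functions: int = 10
    split_rate: float = 0.2
    # synthetic network
    db_size: int = 30
    shared_fraction: float = 0.5
    chain_len: int = 3
    n_dead: int = 1
    gap_fraction: float = 0.2
    # gap filling
    epsilon: float = 1e-3
    big_m: float = 1000.0
    log_level: str = "WARNING"

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce) + "\n")


def _coerce(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_annotations_tsv(path) -> pd.DataFrame:
    """Gene annotation TSV: columns gene, name, ec (ec may be empty)."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene", "name", "ec"}
    if not required <= set(frame.columns):
        raise ConfigError(f"annotation table needs columns {sorted(required)}")
    return frame


def write_reaction_db_tsv(db, path) -> None:
    """Universal reaction database as TSV (id, equation, bounds, gene flag)."""
    rows = []
    for rid in sorted(db):
        rec = db[rid]
        eq = " + ".join(
            f"{-c:g} {m}" for m, c in sorted(rec.stoichiometry.items()) if c < 0
        )
        eq += " --> " if rec.lower >= 0 else " <=> "
        eq += " + ".join(
            f"{c:g} {m}" for m, c in sorted(rec.stoichiometry.items()) if c > 0
        )
        rows.append((rid, eq, rec.lower, rec.upper, int(rec.gene_support)))
    pd.DataFrame(
        rows, columns=["id", "equation", "lower", "upper", "gene_support"]
    ).to_csv(path, sep="\t", index=False)


def read_reaction_db_tsv(path):
    """Inverse of :func:`write_reaction_db_tsv`."""
    from .gapfill import ReactionRecord

    frame = pd.read_csv(path, sep="\t")
    db = {}
    for row in frame.itertuples(index=False):
        stoich: dict[str, float] = {}
        lhs, rhs = row.equation.replace("<=>", "-->").split("-->")
        for side, sign in ((lhs, -1.0), (rhs, 1.0)):
            for term in side.split("+"):
                term = term.strip()
                if not term:
                    continue
                coeff, met = term.split()
                stoich[met] = stoich.get(met, 0.0) + sign * float(coeff)
        db[row.id] = ReactionRecord(
            row.id,
            stoich,
            float(row.lower),
            float(row.upper),
            bool(row.gene_support),
        )
    return db
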