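"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's MILP path: feasibility of a
candidate subset is decided by plain LPs with all other candidates
disabled, and the minimum addition set is found by exhaustive subset
enumeration in order of increasing size.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import cobra

from panmet.gapfill import LinearNetwork, Media, ReactionRecord, biomass_reaction_id


def subset_is_feasible(
    net: LinearNetwork,
    biomass_id: str,
    all_candidates: Sequence[str],
    chosen: set[str],
    conditions: Sequence[Media],
    epsilon: float,
) -> bool:
    disabled = [c for c in all_candidates if c not in chosen]
    for cond in conditions:
        growth, _ = net.solve(biomass_id, cond, disabled=disabled)
        if growth < epsilon:
            return False
    return True


def brute_force_min_additions(
    model: cobra.Model,
    candidates: Mapping[str, ReactionRecord],
    conditions: Sequence[Media],
    epsilon: float = 1e-3,
    max_size: int | None = None,
) -> tuple[int, list[set[str]]]:
    """(minimum addition-set size, every optimal subset of that size)."""
    present = {r.id for r in model.reactions}
    extra = [rec for rid, rec in sorted(candidates.items()) if rid not in present]
    ids = [rec.id for rec in extra]
    net = LinearNetwork.from_model(model, extra)
    biomass = biomass_reaction_id(model)
    limit = len(ids) if max_size is None else min(max_size, len(ids))
    for k in range(limit + 1):
        optima = [
            set(combo)
            for combo in itertools.combinations(ids, k)
            if subset_is_feasible(net, biomass, ids, set(combo), conditions, epsilon)
        ]
        if optima:
            return k, optima
    raise AssertionError("no feasible subset found up to max_size")
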