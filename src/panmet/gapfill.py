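"""Flux balance analysis, condition screening and MILP gap-filling.

The central object is a draft genome-scale model that fails to grow on
some experimentally supported conditions (phenotype-array positives).  The
gap filler selects the minimal set of reactions from a universal database
whose addition lets the model reach a biomass flux of at least ``epsilon``
on every retained condition *simultaneously*, via a mixed-integer linear
program: one binary indicator per candidate reaction, one full flux vector
per condition, and indicator-linked bounds coupling them.

FBA LPs are solved with HiGHS (scipy) on a stoichiometric matrix extracted
from the COBRApy model; the MILP is built on optlang's GLPK interface.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
from scipy.optimize import linprog

DEFAULT_EPSILON = 1e-3
DEFAULT_BIG_M = 1000.0
MASS_BALANCE_TOL = 1e-6

_EXCHANGE_RE = re.compile(r"^EX_(.+)$")
_COMPARTMENT_RE = re.compile(r"(?:\[([a-zA-Z0-9]+)\]|_([a-zA-Z0-9]+))$")


class FBAError(RuntimeError):
    """LP solver failure with model diagnostics attached."""


class GapFillError(RuntimeError):
    """MILP infeasibility or verification failure."""


@dataclass(frozen=True)
class ReactionRecord:
    """One universal-database reaction: id, stoichiometry and flux bounds."""

    id: str
    stoichiometry: Mapping[str, float]
    lower: float = -1000.0
    upper: float = 1000.0
    gene_support: bool = False

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"{self.id}: lower bound exceeds upper bound")

    @property
    def reversible(self) -> bool:
        return self.lower < 0 < self.upper


@dataclass(frozen=True)
class Media:
    """Maximum uptake rate per exchange compound; absent compounds are closed."""

    uptakes: Mapping[str, float]
    name: str = "medium"

    def __post_init__(self) -> None:
        for cpd, rate in self.uptakes.items():
            if rate < 0:
                raise ValueError(f"negative uptake rate for {cpd}")


def compound_of_exchange(rxn_id: str) -> str | None:
    m = _EXCHANGE_RE.match(rxn_id)
    return m.group(1) if m else None


def compartment_of(met_id: str, fallback: str | None = None) -> str:
    """Parse the compartment tag from a metabolite id (``x_c`` or ``x[c]``)."""
    m = _COMPARTMENT_RE.search(met_id)
    if m:
        return m.group(1) or m.group(2)
    return fallback if fallback is not None else "c"


# ---------------------------------------------------------------------------
# Stoichiometric extraction and plain FBA
# ---------------------------------------------------------------------------


@dataclass
class LinearNetwork:
    """Dense stoichiometric view of a model (plus optional extra reactions)."""

    rxn_ids: list[str]
    met_ids: list[str]
    S: np.ndarray  # metabolites x reactions
    lb: np.ndarray
    ub: np.ndarray
    exchange_compound: dict[int, str]  # column -> exchange compound id

    @classmethod
    def from_model(
        cls, model: cobra.Model, extra: Sequence[ReactionRecord] = ()
    ) -> "LinearNetwork":
        rxn_ids: list[str] = []
        met_index: dict[str, int] = {}
        entries: list[tuple[int, int, float]] = []
        lb: list[float] = []
        ub: list[float] = []
        seen = set()

        def add(rid: str, stoich: Mapping[str, float], lo: float, hi: float):
            if rid in seen:
                raise ValueError(f"duplicate reaction id {rid!r}")
            seen.add(rid)
            j = len(rxn_ids)
            rxn_ids.append(rid)
            lb.append(lo)
            ub.append(hi)
            for met, coeff in stoich.items():
                i = met_index.setdefault(met, len(met_index))
                entries.append((i, j, coeff))

        for rxn in model.reactions:
            add(
                rxn.id,
                {m.id: c for m, c in rxn.metabolites.items()},
                rxn.lower_bound,
                rxn.upper_bound,
            )
        for rec in extra:
            add(rec.id, rec.stoichiometry, rec.lower, rec.upper)

        S = np.zeros((len(met_index), len(rxn_ids)))
        for i, j, coeff in entries:
            S[i, j] += coeff
        net = cls(
            rxn_ids=rxn_ids,
            met_ids=list(met_index),
            S=S,
            lb=np.array(lb),
            ub=np.array(ub),
            exchange_compound={},
        )
        for j, (rid, col) in enumerate(zip(rxn_ids, S.T)):
            cpd = compound_of_exchange(rid)
            if cpd is not None and np.count_nonzero(col) == 1:
                net.exchange_compound[j] = cpd
        return net

    def index_of(self, rxn_id: str) -> int:
        return self.rxn_ids.index(rxn_id)

    def bounds_for(
        self, media: Media | None, disabled: Iterable[str] = ()
    ) -> tuple[np.ndarray, np.ndarray]:
        """Media-applied bounds: uptake of every exchange is capped by the
        medium (closed when the compound is absent); secretion stays open."""
        lb, ub = self.lb.copy(), self.ub.copy()
        if media is not None:
            for j, cpd in self.exchange_compound.items():
                lb[j] = max(lb[j], -float(media.uptakes.get(cpd, 0.0)))
        off = set(disabled)
        if off:
            for j, rid in enumerate(self.rxn_ids):
                if rid in off:
                    lb[j] = ub[j] = 0.0
        return lb, ub

    def solve(
        self,
        objective_id: str,
        media: Media | None = None,
        disabled: Iterable[str] = (),
    ) -> tuple[float, np.ndarray]:
        """Maximize one reaction's flux subject to S v = 0 and bounds."""
        try:
            obj = self.index_of(objective_id)
        except ValueError:
            raise FBAError(f"objective reaction {objective_id!r} not in model")
        lb, ub = self.bounds_for(media, disabled)
        c = np.zeros(len(self.rxn_ids))
        c[obj] = -1.0
        res = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=list(zip(lb, ub)),
            method="highs",
        )
        if not res.success:
            raise FBAError(
                f"LP failed ({res.message}) on medium "
                f"{getattr(media, 'name', None)!r}: {len(self.rxn_ids)} reactions, "
                f"{len(self.met_ids)} metabolites"
            )
        flux = res.x
        if np.abs(self.S @ flux).max() > MASS_BALANCE_TOL * 10:
            raise FBAError("mass balance residual exceeds tolerance")
        return float(flux[obj]), flux


def fba(
    model: cobra.Model,
    media: Media | None = None,
    objective_id: str | None = None,
    extra: Sequence[ReactionRecord] = (),
) -> tuple[float, pd.Series]:
    """Flux balance analysis: maximal objective flux and a flux witness.

    Uptake through every exchange reaction is limited to the medium's rate
    for that compound (zero when absent); a zero optimum is returned as a
    plain result, not an error.
    """
    if objective_id is None:
        objective_id = biomass_reaction_id(model)
    net = LinearNetwork.from_model(model, extra)
    value, flux = net.solve(objective_id, media)
    return value, pd.Series(flux, index=net.rxn_ids, name="flux")


def biomass_reaction_id(model: cobra.Model) -> str:
    """The designated biomass reaction: the linear objective's reaction."""
    objs = [r.id for r in model.reactions if r.objective_coefficient]
    if len(objs) == 1:
        return objs[0]
    named = [r.id for r in model.reactions if "biomass" in r.id.lower()]
    if len(named) == 1:
        return named[0]
    raise FBAError(f"cannot identify a unique biomass reaction in {model.id!r}")


# ---------------------------------------------------------------------------
# Phenotype-array plumbing
# ---------------------------------------------------------------------------


def map_phenotype_compounds(
    array_compounds: Iterable[str], mapping: Mapping[str, str]
) -> tuple[dict[str, str], list[str]]:
    """Dictionary lookup from assay compound names to database ids.

    Returns (mapped name -> id, unmapped names); no fuzzy matching is
    attempted — unmapped names are reported for manual review.
    """
    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    for name in dict.fromkeys(array_compounds):
        if name in mapping:
            mapped[name] = mapping[name]
        else:
            unmapped.append(name)
    return mapped, unmapped


def add_transporters(model: cobra.Model, compounds: Iterable[str]) -> cobra.Model:
    """Ensure an exchange and a reversible uniport (e <-> c) per compound.

    Idempotent: existing reactions are left untouched; the input model is
    not mutated.
    """
    model = model.copy()
    existing = {r.id for r in model.reactions}
    mets = {m.id: m for m in model.metabolites}

    def met(met_id: str, comp: str) -> cobra.Metabolite:
        if met_id not in mets:
            m = cobra.Metabolite(met_id, compartment=comp)
            mets[met_id] = m
        return mets[met_id]

    new = []
    for cpd in dict.fromkeys(compounds):
        if f"EX_{cpd}" not in existing:
            rxn = cobra.Reaction(f"EX_{cpd}", lower_bound=-1000.0, upper_bound=1000.0)
            new.append((rxn, {met(f"{cpd}_e", "e"): -1.0}))
            existing.add(rxn.id)
        if f"T_{cpd}" not in existing:
            rxn = cobra.Reaction(f"T_{cpd}", lower_bound=-1000.0, upper_bound=1000.0)
            new.append((rxn, {met(f"{cpd}_e", "e"): -1.0, met(f"{cpd}_c", "c"): 1.0}))
            existing.add(rxn.id)
    model.add_reactions([r for r, _ in new])
    for rxn, stoich in new:
        rxn.add_metabolites(stoich)
    return model


def condition_media(
    base: Media, compound: str, carbon: str | None = None
) -> Media:
    """A phenotype-array condition: the base medium with its carbon source
    swapped for ``compound`` at the same uptake rate."""
    if carbon is None:
        carbon = next(iter(base.uptakes))
    uptakes = {k: v for k, v in base.uptakes.items() if k != carbon}
    uptakes[compound] = base.uptakes[carbon]
    return Media(uptakes, name=compound)


def screen_conditions(
    model: cobra.Model,
    universal_db: Mapping[str, ReactionRecord],
    conditions: Sequence[Media],
    epsilon: float = DEFAULT_EPSILON,
    biomass_id: str | None = None,
) -> tuple[list[Media], list[Media]]:
    """Retain conditions where the model plus the *entire* database grows.

    A condition that cannot reach the growth threshold even with every
    database reaction available can never be gap-filled and is discarded.
    """
    if biomass_id is None:
        biomass_id = biomass_reaction_id(model)
    present = {r.id for r in model.reactions}
    extra = [rec for rid, rec in sorted(universal_db.items()) if rid not in present]
    net = LinearNetwork.from_model(model, extra)
    retained, discarded = [], []
    for cond in conditions:
        growth, _ = net.solve(biomass_id, cond)
        (retained if growth >= epsilon else discarded).append(cond)
    return retained, discarded


def essential_candidates(
    model: cobra.Model,
    candidates: Mapping[str, ReactionRecord],
    conditions: Sequence[Media],
    epsilon: float = DEFAULT_EPSILON,
    biomass_id: str | None = None,
) -> set[str]:
    """Candidates without which some condition is infeasible even with the
    whole database: they must be added unconditionally."""
    if biomass_id is None:
        biomass_id = biomass_reaction_id(model)
    present = {r.id for r in model.reactions}
    extra = [rec for rid, rec in sorted(candidates.items()) if rid not in present]
    net = LinearNetwork.from_model(model, extra)
    essential: set[str] = set()
    for cond in conditions:
        for rec in extra:
            if rec.id in essential:
                continue
            growth, _ = net.solve(biomass_id, cond, disabled=[rec.id])
            if growth < epsilon:
                essential.add(rec.id)
    return essential


# ---------------------------------------------------------------------------
# The multi-condition minimal-addition MILP
# ---------------------------------------------------------------------------


@dataclass
class GapFillProblem:
    """Host model + candidate reactions + growth conditions for the MILP."""

    model: cobra.Model
    candidates: Mapping[str, ReactionRecord]
    conditions: Sequence[Media]
    epsilon: float = DEFAULT_EPSILON
    big_m: float = DEFAULT_BIG_M
    biomass_id: str | None = None

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.biomass_id is None:
            self.biomass_id = biomass_reaction_id(self.model)
        bound = max(
            (abs(b) for r in self.model.reactions for b in (r.lower_bound, r.upper_bound)),
            default=0.0,
        )
        if self.big_m < bound:
            raise ValueError("big_m must dominate every flux bound")


@dataclass
class GapFillResult:
    """Minimal addition set with per-condition flux witnesses."""

    added: list[str]
    objective: int
    witnesses: dict[str, pd.Series]  # condition name -> flux vector
    discarded: list[str] = field(default_factory=list)
    essential: list[str] = field(default_factory=list)
    optimal: bool = True


def gapfill_milp(problem: GapFillProblem) -> GapFillResult:
    """Minimal set of database reactions enabling growth on all conditions.

    Minimizes the number of added candidates subject to, for every
    condition c: steady-state mass balance S v^c = 0, media-limited bounds,
    biomass flux >= epsilon, and indicator-linked candidate bounds
    lb_r * y_r <= v^c_r <= ub_r * y_r (one binary per candidate, covering
    both directions of reversible reactions).  Among equal-cardinality
    optima, gene-supported candidates and then lexicographically smaller
    ids are preferred, via fractional objective weights too small to ever
    trade against cardinality.  The returned additions are re-verified by
    plain FBA on every condition.
    """
    from optlang.glpk_interface import Constraint, Model, Objective, Variable

    present = {r.id for r in problem.model.reactions}
    cands = [
        rec for rid, rec in sorted(problem.candidates.items()) if rid not in present
    ]
    M = problem.big_m
    cand_records = [
        ReactionRecord(
            rec.id,
            rec.stoichiometry,
            max(rec.lower, -M),
            min(rec.upper, M),
            rec.gene_support,
        )
        for rec in cands
    ]
    net = LinearNetwork.from_model(problem.model, cand_records)
    cand_idx = {rec.id: net.index_of(rec.id) for rec in cand_records}
    bio = net.index_of(problem.biomass_id)

    n = max(len(cand_records), 1)
    y = {
        rec.id: Variable(f"y__{rec.id}", type="binary") for rec in cand_records
    }
    milp = Model(name="gapfill")
    variables, constraints = list(y.values()), []

    for cond in problem.conditions:
        lb, ub = net.bounds_for(cond)
        v = [
            Variable(f"v__{cond.name}__{j}", lb=lb[j], ub=ub[j])
            for j in range(len(net.rxn_ids))
        ]
        variables.extend(v)
        for i in range(net.S.shape[0]):
            row = net.S[i]
            nz = np.flatnonzero(row)
            expr = sum(row[j] * v[j] for j in nz)
            constraints.append(Constraint(expr, lb=0, ub=0))
        for rec in cand_records:
            j = cand_idx[rec.id]
            constraints.append(Constraint(v[j] - ub[j] * y[rec.id], ub=0))
            constraints.append(Constraint(v[j] - lb[j] * y[rec.id], lb=0))
        constraints.append(Constraint(v[bio] * 1.0, lb=problem.epsilon))

    # cardinality first; tie-breaks live strictly below one unit in total
    weights = {}
    for rank, rec in enumerate(cand_records):
        frac = (0.25 * (0.0 if rec.gene_support else 1.0) + 1e-3 * rank / n) / (n + 1)
        weights[rec.id] = 1.0 + frac
    milp.add(variables)
    milp.add(constraints)
    milp.objective = Objective(
        sum(weights[rid] * var for rid, var in y.items()), direction="min"
    )
    # The LP relaxation sets y = epsilon / M (1e-6 at defaults); GLPK's stock
    # integrality tolerance of 1e-5 would round that to zero and accept an
    # infeasible "solution", so the tolerance must sit well below epsilon / M.
    # GLPK's MIP presolver mis-reduces indicator rows at this coefficient
    # range as well, hence it is disabled (the outer simplex still runs).
    import swiglpk as _glp

    milp.configuration._iocp.tol_int = 1e-9
    milp.configuration._iocp.presolve = _glp.GLP_OFF
    status = milp.optimize()
    if status != "optimal":
        raise GapFillError(f"MILP terminated with status {status!r}")

    added = sorted(rid for rid, var in y.items() if var.primal > 0.5)

    # independent re-verification: plain FBA with only the added reactions
    witnesses: dict[str, pd.Series] = {}
    added_recs = [problem.candidates[rid] for rid in added]
    vnet = LinearNetwork.from_model(problem.model, added_recs)
    for cond in problem.conditions:
        growth, flux = vnet.solve(problem.biomass_id, cond)
        if growth < problem.epsilon - 1e-9:
            raise GapFillError(
                f"verification failed on condition {cond.name!r}: "
                f"growth {growth:.3g} < epsilon {problem.epsilon:.3g}"
            )
        witnesses[cond.name] = pd.Series(flux, index=vnet.rxn_ids, name=cond.name)
    return GapFillResult(added=added, objective=len(added), witnesses=witnesses)


def gapfill(
    model: cobra.Model,
    universal_db: Mapping[str, ReactionRecord],
    conditions: Sequence[Media],
    epsilon: float = DEFAULT_EPSILON,
    big_m: float = DEFAULT_BIG_M,
) -> GapFillResult:
    """Screen conditions, then solve the multi-condition MILP end to end."""
    retained, discarded = screen_conditions(model, universal_db, conditions, epsilon)
    essential = essential_candidates(model, universal_db, retained, epsilon)
    result = gapfill_milp(
        GapFillProblem(
            model=model,
            candidates=universal_db,
            conditions=retained,
            epsilon=epsilon,
            big_m=big_m,
        )
    )
    result.discarded = [c.name for c in discarded]
    result.essential = sorted(essential)
    return result


# ---------------------------------------------------------------------------
# Minimal media
# ---------------------------------------------------------------------------


def minimal_media(
    model: cobra.Model,
    nutrient_pool: Mapping[str, float],
    base: Media | None = None,
    epsilon: float = DEFAULT_EPSILON,
    biomass_id: str | None = None,
) -> list[str]:
    """An irreducible nutrient subset (beyond the fixed base) sustaining growth.

    Nutrients are closed one at a time in sorted order and left closed
    whenever growth survives; because closing uptakes only shrinks the
    feasible region, every nutrient kept open is individually necessary,
    which a final single-removal FBA pass re-verifies.
    """
    if biomass_id is None:
        biomass_id = biomass_reaction_id(model)
    base_uptakes = dict(base.uptakes) if base else {}
    net = LinearNetwork.from_model(model)

    def medium(open_nutrients: Mapping[str, float]) -> Media:
        return Media({**base_uptakes, **open_nutrients}, name="pool")

    open_n = dict(nutrient_pool)
    growth, _ = net.solve(biomass_id, medium(open_n))
    if growth < epsilon:
        raise FBAError("model does not grow even on the full nutrient pool")
    for cpd in sorted(nutrient_pool):
        trial = {k: v for k, v in open_n.items() if k != cpd}
        growth, _ = net.solve(biomass_id, medium(trial))
        if growth >= epsilon:
            open_n = trial
    for cpd in open_n:  # irreducibility certificate
        trial = {k: v for k, v in open_n.items() if k != cpd}
        growth, _ = net.solve(biomass_id, medium(trial))
        if growth >= epsilon:
            raise FBAError(f"minimal medium not irreducible at {cpd!r}")
    return sorted(open_n)
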