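# Methods

This note documents the models, defaults and numerical choices behind
`panmet`, and what the synthetic benchmarks do and do not demonstrate.

## Ortholog clustering and the pan-genomic matrix

Orthology is approximated by **bidirectional best hit** (BDBH): for every
ordered species pair, each gene's best-scoring global alignment
(BLOSUM62, gap open −11, extend −1) defines a hit; reciprocal hits that
reach ≥ `min_identity` (default 0.40) over ≥ `min_coverage` (default
0.75) of the shorter sequence become edges, and clusters are connected
components. Identity and coverage are both normalized by the shorter
sequence, so a short fragment aligning fully inside a longer protein
counts as covered. Ties in best-hit selection are broken by higher
identity, then lexicographic gene id, making the clustering deterministic
and invariant to input order (inputs are sorted internally).

Markov-cluster orthology (granularity 1.5, E-value 1e-5 in the usual
tooling) is deliberately **not** reimplemented: BDBH admits an exact
brute-force oracle — all-pairs alignment plus connected components — that
the test suite runs on every synthetic instance, and the identity-over-
coverage cutoff plays the role of the E-value threshold at these
sequence lengths. The configuration still records a `granularity` field
for provenance; it has no effect. A two-stage driver (intra-species
first, then user-chosen representative strains) is exposed for data sets
with several strains per species, mirroring common practice of picking
one representative per species to avoid intra-species similarity bias.

Matrix classification: core = rows present in every column,
strain-specific = rows present in exactly one, shell = the rest;
percentages are rounded to the nearest integer independently (so they
can sum to 99–101). A single-species matrix makes every row both core
and strain-specific; such rows are counted as core and the result is
flagged degenerate.

## Accumulation curves and size fits

Curves sample random genome orderings (default `n_permutations` = 100;
when n! ≤ the requested count, all orderings are enumerated exactly
once). Within each permutation pan size (union) is non-decreasing and
core size (intersection) non-increasing by construction — asserted as a
property test.

Two standard closed forms are fitted to across-permutation **medians**
(robust to sampling noise):

* pan growth, Tettelin-style: new families contributed by the Nth genome
  ≈ κ·N^(−γ); the pan-genome is called *open* when γ < 1 with a positive
  rate, and the rate evaluated at the last genome is the reported
  "new families per additional genome";
* core decay, Willenbrock-style: core(N) = A·exp(−N/τ) + ω with
  asymptote ω ≥ 0 constrained not to exceed the observed core at maximal
  N.

Both fits are **separable least squares on a fixed grid**: the nonlinear
parameter (γ on [0, 6] in 0.01 steps; τ log-spaced over [1e-2, 1e3]) is
scanned and the linear parameters profiled out in closed form. This is
deterministic and cannot fail to converge on short, flat or degenerate
curves, where generic Levenberg–Marquardt/TRF starts routinely diverge
(a flat-then-step median curve makes the exponential model parameters
run away). Degenerate inputs short-circuit: zero increments give a
closed verdict with rate 0; a flat core curve reports ω = the observed
size with τ unidentifiable rather than fitting noise.

## Functional pivot

Two merge steps, in fixed order: (1) clusters with identical, parseable
EC sets merge; (2) clusters whose (normalized) names fall in the same
synonym group merge; remaining clusters merge only on verbatim-identical
normalized names. Partial EC strings ("2.8.3.-") merge only with the
identical partial string, to avoid over-merging enzyme families.
Hypothetical/putative/uncharacterized names get per-cluster keys and are
never merged — curating them adds little functional signal and risks
false merges. Function rows are the elementwise OR of their cluster
rows, so a species has a function iff it has at least one contributing
cluster; the pivot is idempotent and can only reduce the row count.

The **hidden core** is the set of functions whose OR-row is all-present
while no single contributing cluster is: exactly the functionality that
differential clustering hides from a cluster-level core count.

## Pan-GEM consolidation

Reaction identity is the database id after stripping a trailing
compartment tag (`_c`, `[c]`, …) and applying an optional alias table;
stoichiometric-equivalence matching is not attempted, because
consolidation assumes models curated against one reaction database.
Classification: exchange = single-metabolite boundary reaction;
transporter = participants span ≥ 2 compartments; biomass = the
designated objective; everything else metabolic. Gene-association
strings are stored verbatim per species. Consolidation is order-
invariant and SBML round-trips (COBRApy/libsbml) preserve the census.

Set arithmetic over a species grouping reports group-exclusive
(≥ 1 member, 0 non-members), group-exclusive-and-universal (all
members, 0 non-members) and species-exclusive counts, against an
explicit classification filter (default: metabolic reactions), so
percentages are always relative to a named denominator.

## FBA, screening and the gap-filling MILP

FBA maximizes the biomass flux subject to S·v = 0 and bounds, with
uptake through every exchange capped by the medium (absent compounds are
closed; secretion stays open). LPs are solved with HiGHS on a dense
stoichiometric matrix extracted from the COBRApy model; the test suite
cross-checks against COBRApy's own GLPK path, keeping two independent
solver routes. A zero optimum is a result, not an error; returned fluxes
must satisfy mass balance within 1e-6.

Gap-filling follows the phenotype-array protocol: transporters are added
for array-positive compounds (idempotently: an exchange plus a
reversible e↔c uniport each); conditions that cannot reach the growth
threshold ε even with the *entire* universal database are discarded;
candidates whose removal makes some condition infeasible even with the
rest of the database are reported as essential; then one MILP minimizes
the number of added candidates subject to, per retained condition, mass
balance, media bounds, biomass ≥ ε, and indicator coupling
lb_r·y_r ≤ v^c_r ≤ ub_r·y_r (a single binary covers both directions of
a reversible candidate). Pure cardinality is the objective; among
equal-size optima, gene-supported candidates and then lexicographically
smaller ids win, implemented as fractional weight perturbations whose
total stays below one unit so they can never trade against cardinality.
Defaults: ε = 1e-3 flux units, M = 1000 (bounds are clipped to ±M).

Two GLPK specifics matter at this ε/M ratio and are set explicitly: the
integrality tolerance is lowered to 1e-9, because the LP relaxation
puts y = ε/M = 1e-6 on a candidate and the stock 1e-5 tolerance would
round that to an "integral" — and infeasible — solution; and GLPK's MIP
presolver is disabled, since it mis-reduces indicator rows in the same
regime. LP feasibility stays at solver defaults (~1e-7–1e-9); every
MILP solution is re-verified by plain FBA per condition before being
returned, so a solver artifact cannot silently pass.

Minimal media closes pool nutrients one at a time in sorted order,
keeping a nutrient closed whenever growth survives. Closing uptakes only
shrinks the feasible region, so the surviving set is irreducible; a
final single-removal FBA pass certifies it. Phenotype-assay compound
names map to database ids by exact dictionary lookup with an explicit
unmapped report — no fuzzy chemistry matching.

## Pathways and clustergrams

Pathway presence is scored from pan-GEM flags; unresolvable reaction ids
are reported and fully unresolvable pathways dropped with a warning.
Species are compared by Jaccard similarity of their pathway reaction
sets and clustered with average linkage (UPGMA) on 1 − J; the metric is
standard for such comparisons, the linkage is this package's choice.
Empty-vs-empty Jaccard is defined as 1 (two species both lacking a
pathway are maximally similar for clustering purposes). Heat-map tables
are emitted in leaf order, referenced either to the pan-reactome or to a
reference strain; the two modes coincide whenever the reference carries
a pathway's full pan set. A small editable amino-acid pathway TSV ships
as a template; real analyses should key it to their own reconstruction
namespace.

## Synthetic data: what it emulates, what it does not

The proteome generator plants core families (one copy per species),
shell families (per-species presence probability `p_shell`) and
strain-specific cloud families (Poisson(`cloud_rate`) per genome, making
the pan-genome open with that expected rate). Sequences are amino-acid
strings mutated from a per-family ancestor at a per-site rate chosen so
expected within-family identity stays above the declared floor (default
0.9), while unrelated families sit at background identity (~5 %, below
the declared 0.2 ceiling). There is no codon model, no indels, no rate
heterogeneity and no homoplasy — clustering only needs a controlled
identity gap, and a wide gap makes oracle equivalence exact. Passing
these tests shows the clustering machinery is correct, not that the
thresholds are optimal for real proteomes with domain shuffling or
fragmented gene calls.

Toy networks are layered uptake → conversion → biomass chains (one chain
per carbon source, stoichiometric coefficients in {1, 2}, biomass a
single sink). The universal database is the union of all chains plus
dead-end decoy reactions (which can never carry steady-state flux) and
dead-end panel compounds (exchange but no route — these must be
discarded by screening). Draft degradation removes a fraction of
unprotected reactions (biomass, all exchanges and base-medium
transporters are protected). These networks exercise every FBA/MILP code
path — multiple conditions, alternative optima, infeasible conditions,
essential bridges — but have none of the loops, cofactor coupling or
thermodynamic subtleties of genome-scale reconstructions; MILP
minimality is verified exactly by subset enumeration at this scale,
which is the point.

Default study conditions (the `RunConfig` defaults and the acceptance
benchmarks): 4–6 species; planted core 100 and cloud rate 50 for the
recovery benchmarks (median fitted rate within 15 %, asymptote within 10
families over 20 seeds); gap-fill instances with ≤ 30 candidate
reactions and ≤ 4 conditions, 50 random instances for the minimality
check. These sizes make exhaustive oracles exact and keep the whole
suite under a couple of minutes on one CPU while still covering every
branch of the formulation.

## Known limitations

* BDBH merges families through chains of reciprocal best hits; at narrow
  identity gaps it can over- or under-merge relative to Markov
  clustering. The oracle equivalence holds at the planted gap, not at
  arbitrary divergence.
* The Heaps/core-decay forms are the two standard summaries; finite
  supragenome models and Bayesian treatments are out of scope, and
  uncertainty is reported only as permutation spread.
* Gap-filling is pure cardinality (optionally weighted); no
  likelihood-weighted or thermodynamics-aware variant.
* Pan-GEM consolidation trusts database ids; models built against
  different databases must be aliased first.
* The pipeline treats curation as data: it diffs and reports manual
  changes but never re-enacts them.
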