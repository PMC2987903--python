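# Methods

## Scope and model assumptions

The package predicts environments (media) that induce commensal or
mutualistic growth between two microbial species, using steady-state
constraint-based models. The assumptions are those of flux balance
analysis: mass balance at steady state (S·v = 0), capacity bounds on every
reaction, and growth expressed as flux through a biomass reaction. No
regulation, kinetics or thermodynamic (ΔG) constraints are modeled; in
particular the benefit a hydrogen producer derives from a partner lowering
H₂ partial pressure is outside this framework, and the fitness cost of
provisioning a partner is not modeled, so commensalism and parasitism are
not distinguished.

## Joint two-species models

Members keep their own cytosolic (`CYT1`, `CYT2`) and extracellular (`EX1`,
`EX2`) compartments and are embedded under a shared environment `ENV`.
Three reaction layers connect a metabolite to a species: *exchange*
(`X[ENV] <=> ∅`, positive flux = secretion out of the whole system, lower
bound −availability = uptake capacity), *shuttle* (`X[ENV] <=> X[EXk]`,
positive flux = net flow into species *k*), and the species' own
*transport* reactions. The shuttle layer exists so that a species' net
uptake/secretion of a metabolite is a single flux even when many
transporters move it; the exchange searches gate shuttles, not
transporters. Member blocks are copied verbatim (ids namespaced `S1:`/
`S2:`); a member's former exchange reactions become shuttles with
sign-flipped bounds, so structural irreversibility (uptake-only or
secretion-only metabolites) is preserved. Metabolites transportable by only
one species still receive ENV entries, so one species can dump a by-product
even if the partner cannot use it.

Metabolite correspondence across members is either given explicitly or
derived by exact id match (with an override table for manual curation);
extracellular ids ending in `_e` drop the suffix in `ENV`.

## Media

A medium is a map metabolite → maximal uptake rate (mM·gDW⁻¹·h⁻¹) and acts
purely as a bounds overlay: exchange lower bound −availability for present
metabolites, 0 otherwise; secretion is never restricted. The default
availability for searched nutrients is 10; transporter and secretion caps
default to 1000 (effectively unconstrained). Uptake bounds for limited
nutrients are configurable — the appropriate values are organism- and
protocol-specific and no universal default exists.

## Growth thresholds

Two thresholds are deliberately distinct. Boolean growth tests
(classification) use `eps` = 1e−6 on the maximized biomass flux: "can this
species grow at all". MILP searches impose a growth *floor*
`v_min` = 0.1 on each species' biomass flux: "find media/exchanges
sustaining non-trivial growth of both". A medium passing the floor always
passes the boolean test.

## Interaction classification

Four FBA problems per medium: each species' biomass maximized inside the
joint model (the partner's network may run without growing), and each
member model alone with the medium translated into its own namespace
(dropping metabolites it cannot transport). The class is a pure function of
the four booleans: both joint tests must pass, else *no growth*; then both
solo passes → *neutralism*, exactly one → *commensalism* with the growing
species as provider, neither → *mutualism*. Testing joint growth per
species (rather than maximizing the summed biomass) prevents one member's
growth from masking the other's failure.

## SMM — minimal media

Binary θᵢ per candidate exchange reaction; uptake gated by
`v_EX_i ≥ −L·θᵢ` (secretion never gated); minimize Σθᵢ subject to the
growth floor(s) — both members for a joint model. Minimality (removal of
any member kills growth) follows from optimality and is re-checkable with
`verify_minimal` (one LP per member). Free co-factors (minerals, water) can
be allowlisted out of the count, and candidates whose formula spans several
non-hydrogen elements (amino-acid-like dual sources) can be discouraged by
a soft objective penalty — a penalty rather than a hard exclusion because
such nutrients are only to be *avoided if possible*.

## SEM — exchanged metabolites

Candidates are metabolites transportable by both species
(TM⁽¹⁾ ∩ TM⁽²⁾) and absent from the medium: medium metabolites are shared,
not cross-fed, and are never counted. For each candidate, both species'
shuttle fluxes are gated symmetrically (`|v_S| ≤ L·θᵢ`) and the
environmental exchange of non-medium metabolites is closed to uptake, so
any uptake of a candidate must come from the partner; Σθ is minimized.
The published formulation's coupling constraint is not reproduced legibly
in the source material; the symmetric big-M gating implements its stated
meaning (θᵢ = 1 iff metabolite *i* is transported between the species).
One consequence is that secreting a waste product that is not in the medium
also costs a θ even without partner uptake; the generator's instances have
no obligatory waste, and on real models such metabolites are better placed
in the medium or allowlist.

Directions are read after the cardinality optimum: with the indicator
pattern frozen and non-selected candidates closed, an LP minimizes the
summed absolute shuttle flux of the selected metabolites (standard flux
splitting), stripping zero-benefit bidirectional loops; provider = negative
shuttle flux, recipient = positive, anything else is labeled
bidirectional.

Alternate optima: from each solution, each member is excluded in turn
(lexicographic order) and the MILP re-solved, depth-first, keeping
solutions within a configurable cardinality slack (default 0) of the
optimum, deduplicated, capped at `max_solutions` (default 50). This
enumeration is not guaranteed exhaustive.

Heuristic: step 1 minimizes by LP the summed absolute shuttle fluxes over
all non-medium metabolites (both species) under the growth floors; step 2
runs the exact search restricted to the metabolites active in step 1, with
all other candidates closed. The result is removal-minimal but its
cardinality may exceed the global optimum; restriction can only preserve or
worsen it.

## SIM — media search

Per element A ∈ {C, N, P, S} (membership from elemental formulas;
formula-less metabolites are excluded from stripping and pools with a
logged warning): strip every A-containing metabolite from the medium, then
scan the pool in lexicographic order for single metabolites restoring joint
dual growth (floors on both members), removing each hit from the pool; when
no single suffices, a minimal multi-metabolite set is found by the SMM MILP
restricted to the pool (the stripped medium held fixed and free), and the
search bifurcates on removal of each member of that set. The pool is all
ENV metabolites minus the *stripped* medium, so the element's original
source re-enters the pool and is recovered; this is what makes the media
set independent of which seed source the search starts from, and that
independence is asserted exactly (set equality) on the synthetic instances.
Pool ordering is lexicographic for reproducibility of the bifurcation
pattern.

Candidate media are the Cartesian product of per-element replacement sets
added to the element-stripped base (union semantics: a metabolite replacing
two elements counts once, and when chosen all its elements count as
covered). Every candidate is then classified; candidates failing joint
growth are reported as *no growth* rather than silently dropped, so class
counts partition the growing media exactly. An element with no source in
the seed medium has nothing to substitute and passes the composition
through unchanged.

## Clustering and accuracy

The usage matrix M has M_ij = 1 iff metabolite *j* occurs in medium *i*.
Columns (or rows) are clustered by average-linkage hierarchical clustering
under the Jaccard distance d(u,v) = 1 − |u∧v|/|u∨v|; two all-zero columns
get distance 0 (identical support), logged. For the two-class accuracy the
media rows are clustered the same way, the tree is cut into two groups, and
each group takes the label assignment that maximizes (TP+TN)/(P+N) — an
upper-bound mapping, chosen because no canonical cluster-to-class rule
exists for an unsupervised cut; the reported accuracy is therefore the best
achievable two-cluster separation. Enrichment is the hypergeometric tail
probability of observing at least TP positives in the positive cluster.

## Perturbation robustness

Environmental perturbation: one uniformly chosen carbon-containing medium
metabolite is swapped for a uniformly chosen different carbon-containing
pool metabolite, rejection-sampled until the joint model still grows
(bounded retries; exhaustion is a status, and in transition tallies counts
as an unchanged environment). Network perturbations: k cumulative insults
per application — random deletion (both bounds zeroed) of an internal or
transport reaction (never biomass, exchange or shuttle reactions), random
addition of a reaction from a user pool referencing only existing
metabolites (default bounds ±1000; the source material does not state
bounds for added reactions), or one deletion plus one addition. Transition
probabilities are Monte-Carlo estimates: each sampled medium is classified,
perturbed independently `reps` times from a fresh copy, reclassified, and
the class→class tallies row-normalized. *No growth* is an explicit fifth
class, since a deletion can abolish joint growth. All stochastic operations
consume a single seeded `numpy` generator; CLI runs record seed and
configuration in a provenance JSON.

## Synthetic test pairs

The generator emulates, at oracle-testable scale, species pairs with known
interaction structure. Each species assimilates `n_sources_per_element`
carbon and nitrogen sources into two biomass precursors (biomass = 1 A + 1
B), with a linear pathway of up to `n_core_mets` intermediates for the
first source; two decoy metabolites are transportable but never
assimilated. A dependency plan removes one species' assimilation route for
one element and wires a one-way carrier metabolite from the partner
(provider: synthesis + export-only transport and secretion-only exchange;
recipient: import-only); *mutual* plants one dependency in each direction,
so the minimal exchange set has exactly two members with known directions.
One-way carrier wiring keeps carriers from doubling as plain environmental
nutrients, so the viable element sources are exactly the planted ones.
`alt_carriers` adds interchangeable carbon carriers to make the minimal
exchange set degenerate. All transporters and exchanges exist in both
species, so the candidate exchange sets of the two members coincide and
stay ≤ 12 metabolites, within reach of exhaustive subset oracles.
Randomness (seeded): pathway lengths, the designed medium's source choice.
Every emitted instance is certified by direct LP classification of its
designed medium before return, with a bounded derived-seed retry.

What the generator does not emulate: genome-scale network topology,
by-product secretion under growth (no obligatory waste), cofactor coupling
in transport, multi-element nutrients. Passing tests on these instances
validate the algorithms' correctness contracts (optimality, minimality,
classification logic), not predictive fidelity on real reconstructions.

## Numerical choices

HiGHS (via `scipy.optimize.linprog`/`milp`) solves all LPs and MILPs,
single-threaded and deterministic. Big-M L = 1000 is validated at build
time against the largest finite bound — an undersized L silently corrupts
gating, so it is an error. Indicator integrality is checked to 1e−6;
steady-state residuals of accepted solutions are ≤ 1e−6; shuttle-sign
reads use a 1e−7 tolerance. Individual flux values in degenerate optima are
solver-dependent and are never part of the API contract; only objective
values, cardinalities and memberships are.

## Problem sizes in the shipped analyses

The test-suite acceptance checks use 200 random instances for the
MILP-vs-oracle comparisons, 50 instances per dependency plan for
planted-class recovery (with a 10-per-plan media-enumeration mirror), 1000
Monte-Carlo repetitions for the transition-matrix comparison against exact
deletion enumeration, and 100 label permutations for the clustering null.
`scripts/acceptance.py` defaults to 80 oracle instances and 20 per plan,
adjustable from the command line; both complete in minutes on one CPU.

## Known limitations

Pairwise only (the joint construction generalizes to more species, but the
searches here are two-species); enumeration of alternate optima is
heuristic, not exhaustive; elemental bookkeeping covers C, N, P, S (not
trace metals); the SEM gating charges a θ for one-sided waste secretion of
non-medium metabolites; k-means partitioning of media classes and
figure-only quantities from the robustness analyses are out of scope.
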