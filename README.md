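# symbiomedia

Predicting growth media that *induce* symbiotic interactions between pairs
of microbial species, using constraint-based models of metabolism.

Most engineering of microbial mutualisms modifies the organisms (auxotroph
construction, pathway knockouts). This package takes the complementary
route: given two stoichiometric metabolic models, it searches the space of
nutrient compositions for media under which the pair can grow jointly but
one or both species cannot grow alone — environments that force
commensalism (one species feeds the other) or mutualism (obligate
bidirectional cross-feeding). It is aimed at computational microbial
ecologists and synthetic-ecology experimentalists who want candidate media
and candidate exchanged metabolites for a given species pair.

## The model

Each species is a stoichiometric model: a matrix **S** (metabolites ×
reactions), flux bounds **LB** ≤ *v* ≤ **UB**, and a biomass objective *c*.
Flux balance analysis (FBA) solves

```
max  c·v    subject to   S v = 0,   LB ≤ v ≤ UB
```

Two species are merged under a shared environmental compartment `ENV`.
For each metabolite *X<sub>i</sub>* the joint model carries

* an **exchange** reaction  `X_i[ENV] <=> ∅`   (environmental availability;
  the medium sets its lower bound to −availability),
* one **shuttle** reaction per species  `X_i[ENV] <=> X_i[EXk]`
  (the species' *net* uptake or secretion, regardless of how many
  transporters it has),
* the species' own **transport** and internal reactions, copied verbatim.

On top of this joint model:

* **SMM** (minimal media): binary θ<sub>i</sub> gates uptake through
  exchange *i* (`v_EX_i ≥ −L·θ_i`); minimize Σθ subject to both species'
  biomass fluxes ≥ v<sub>min</sub> (0.1 by default). The result is minimal:
  removing any member abolishes growth.
* **SEM** (exchanged metabolites): θ<sub>i</sub> gates *both* species'
  shuttles of metabolites absent from the medium (`|v_S| ≤ L·θ_i`), with
  external uptake of those metabolites closed — any uptake must come from
  the partner. Minimizing Σθ yields the fewest cross-fed metabolites;
  alternate optima are enumerated by exclusion, and a scalable two-step
  heuristic (L1-minimal shuttle flux, then the exact search restricted to
  the active metabolites) handles large models.
* **SIM** (interaction-inducing media): starting from a seed medium, for
  each element (C, N, P, S) the element's sources are stripped and all
  single metabolites (or minimal sets) restoring joint growth are found
  recursively; the per-element replacements are combined into candidate
  media; each medium is classified by four FBA growth tests (each species
  in the joint model, each species alone) into **neutralism**,
  **commensalism** (either direction), **mutualism**, or no growth.
* Downstream analyses: a binary media × metabolite usage matrix with
  average-linkage Jaccard clustering, a two-class clustering accuracy with
  hypergeometric enrichment, and Monte-Carlo transition-probability
  matrices between interaction classes under random reaction deletions /
  additions or random carbon-source swaps.

All LPs and MILPs are solved with HiGHS through `scipy.optimize`.

## Worked example

The built-in toy pair: both organisms transport metabolites X, Y, Z and
build biomass from one unit of each; organism 1 can only synthesize Y
(X→Y), organism 2 only Z (X→Z).

```python
from symbiomedia import (
    Medium, MilpConfig, make_toy_pair, build_joint, classify_interaction,
    find_minimal_medium, find_min_exchange_set, solve_fba,
)

m1, m2, met_map = make_toy_pair()
joint = build_joint(m1, m2, met_map)
config = MilpConfig()

for availability in ({"X": 10}, {"X": 10, "Z": 10}, {"X": 10, "Y": 10, "Z": 10}):
    record = classify_interaction(joint, Medium(availability), config)
    print(sorted(availability), "->", record.interaction_class)

mm = find_minimal_medium(joint, {"X": 10, "Y": 10, "Z": 10}, config)
print("minimal joint medium:", sorted(mm.medium.metabolite_ids))

ex = find_min_exchange_set(joint, Medium({"X": 10}), config)
print("exchanged on {X}:", ex.members)

growth = solve_fba(joint.model, Medium({"X": 10}),
                   objective={b: 1.0 for b in joint.biomass_ids})
print("total joint biomass flux on {X}: %.4f" % growth.objective_value)
```

prints

```
['X'] -> mutualism
['X', 'Z'] -> commensal_1_provider
['X', 'Y', 'Z'] -> neutralism
minimal joint medium: ['X']
exchanged on {X}: {'Y': '1->2', 'Z': '2->1'}
total joint biomass flux on {X}: 3.3333
```

On X alone neither organism grows by itself, but the pair does (mutualism):
organism 1 feeds Y to organism 2 (`1->2`) and receives Z (`2->1`). Adding Z
lets organism 1 grow alone, so it becomes the commensal provider; the full
medium supports both individually (neutralism). The minimal joint medium is
X alone, and 10 units of X sustain a summed biomass flux of 10/3 — each unit
of biomass costs three units of X across the consortium.

The same operations are available from the shell:

```
symbiomedia fixtures --toy --out-dir toy/
symbiomedia classify toy/toy1.tsv toy/toy2.tsv --medium X=10   # -> mutualism
symbiomedia sem toy/toy1.tsv toy/toy2.tsv --medium X=10 --out exchanges.tsv
symbiomedia sim toy/toy1.tsv toy/toy2.tsv --seed-medium mm.tsv --out media.tsv
```

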