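# Methods

## Scope and representation

`commfba` operates on steady-state constraint-based metabolic networks.
A model holds compartments, metabolites (with optional elemental formulas),
reactions with flux bounds and boolean gene–protein–reaction (GPR) rules,
and one or more biomass reactions. Conventions, fixed once and used
everywhere:

* Compartment ids: `c<i>` for the cytosol of species *i* (*i* ≥ 1), `e0`
  for the single shared extracellular compartment, `c0` for the merged
  cytosol of mixed-bag models. Metabolite ids carry the compartment as a
  suffix (`glc_c1`). This makes species attribution unambiguous after
  merging.
* Exchange reactions are written in export orientation (`x_e0 → ∅`);
  uptake is negative flux. A medium maps each compound to
  (max_uptake, max_excretion) ≥ 0, applied as exchange bounds
  (−uptake, +excretion); compounds absent from the medium have uptake
  closed and excretion left open. Media application is idempotent and
  never touches non-exchange reactions.
* Default bounds when unspecified: reversible (−100, 100), irreversible
  (0, 100) mmol·gDW⁻¹·h⁻¹. The finite box keeps every LP bounded.
* Zero stoichiometric coefficients are dropped at construction so that
  reaction identity can be hashed canonically.

## Community merging

Two reactions are *the same biochemistry* iff their canonical
stoichiometries match: sort metabolite ids, then orient the reaction so the
lexicographically smallest participant has a negative coefficient
(transforming bounds accordingly). Reaction-id equality is deliberately not
used — members from different reconstruction pipelines rarely share ids.

*Mixed-bag*: all cytosolic content is re-homed to `c0`; canonical
duplicates collapse to a single reaction whose GPR is the OR of the
members' rules (either species' enzyme suffices in a pooled cytosol) and
whose bounds are the union interval. Member biomass equations are combined
by summing coefficients per metabolite and dividing by the number of
members *N*.

*Compartmentalized*: species *i*'s cytosol becomes `c<i>`; extracellular
metabolites merge by compound identity into `e0` and duplicate exchange
reactions collapse (species transporters stay per-compartment — only the
boundary with the environment is shared). Each member keeps its biomass
reaction, which additionally produces a pseudo-metabolite
`biomass_sp<i>`; the community biomass consumes 1/N of each and is the
default objective, so community growth requires every member to grow.
Equal 1/N weighting mirrors the mixed-bag rescaling rule; an
abundance-weighted variant would only change those coefficients.
Per-reaction provenance (`member`, original id, per-member exchange
bounds) is retained in reaction metadata, which makes member extraction an
exact inverse of the merge.

## LP/MILP backend

All optimization runs through scipy's HiGHS interface. Variables are
ordered by sorted reaction id and metabolite rows by sorted metabolite id,
so repeated solves are bit-reproducible; HiGHS runs single-threaded with
zero MIP gap (every reported gapfill is a proven optimum; instances here
are desk-scale). LP feasibility tolerance is 1e-9; flux solutions are
checked against S·v = 0 at that tolerance in the tests. COBRApy (GLPK) is
used in the test suite as an independent solver stack for FBA/pFBA
cross-checks, and never as the implementation.

pFBA minimizes Σ|v| via the standard split v = p − q at the fixed optimal
objective (held to within 1e-9). Against explicit vertex enumeration of
the split-variable polytope on small instances, both the objective and the
flux support match.

## Gapfilling

The gapfiller solves: minimize Σ cost·z over binary indicators subject to
S·v = 0, media bounds, v_objective ≥ ε, and 0 ≤ v_candidate ≤ M·z with
M = 100 (the global flux box). Choices that matter:

* ε = 0.01 flux units, deliberately three orders of magnitude above the
  1e-6 growth-call threshold, so gapfill solutions cannot rest on
  numerically marginal trickle fluxes.
* Reversible database reactions are offered as two directed candidates at
  cost 1 each (adding both costs 2); costs must be positive.
* Transporter templates: for every transportable compound in the database,
  a reversible uniport between each cytosol and `e0`, emitted as two
  directed candidates. Cross-feeding repairs are impossible without them.
* Ties between equal-cost optima are broken deterministically in favour of
  the lexicographically smallest sorted (compartment, database id,
  direction) tuple, implemented as an infinitesimal (1e-7-scale) rank
  perturbation of the candidate costs — far below the smallest real cost
  difference, so the true optimum is never displaced.
* Candidates identical (canonically) to an existing model reaction are not
  instantiated.

Community gapfilling is the same MILP with the database instantiated once
per species compartment and the community biomass as objective; only the
community biomass is constrained (the 1/N coupling forces the members).
Iterative gapfilling integrates each round's additions (cost already paid)
before the next medium.

A brute-force oracle enumerates candidate subsets in increasing
cardinality, prunes supersets of feasible solutions, and returns all
minimum-cost minimal subsets. It is guarded to ≤ 15 instantiated
candidates (or an explicit `max_size` cap with a bounded subset count) and
certifies the MILP's optimality on a 25-instance benchmark.

## Interaction extraction

Interactions are read from a pFBA solution of the community biomass: for
each extracellular compound, each species' net transport flux into `e0` is
summed over the reactions attributable to that species; a compound is an
interaction when one species' net secretion and another's net uptake both
exceed 1e-6 (an order of magnitude above solver noise), with transfer flux
min(secretion, uptake) — so consumption covered by the medium is never
attributed to cross-feeding. pFBA rather than plain FBA because FBA flux
is degenerate; the parsimonious solution is deterministic and avoids
spurious futile exchanges. An optional flux-variability mode re-minimizes
each producer's net secretion at the optimal objective and labels
transfers `obligatory` (persist in every optimum) or `possible`.

## Expression integration

* Threshold: the 10th percentile (linear interpolation between order
  statistics, numpy's default) of the expression of universal-role
  housekeeping genes present in the profile; at least two are required.
  Genes exactly at the threshold are "on" (a convention fixed for
  determinism); genes absent from the profile are unknown.
* Reaction activity: three-valued GPR evaluation (OR: any subunit on;
  AND: all on; decisive unknowns propagate). Empty-GPR reactions
  (gapfilled, exchange, biomass, spontaneous) are excluded from the
  confusion matrix but counted in the per-pathway gapfilled-active tally.
* Transcriptomic flux fitting: a MILP maximizing the number of satisfied
  calls — an active reaction is satisfied when |v| ≥ δ (δ = 1e-3, above
  solver tolerance and configurable), an inactive one when v = 0 —
  subject to mass balance, bounds, and biomass ≥ ε. Direction binaries
  prevent the split variables from faking |v| ≥ δ with cancelling
  forward/backward flux. A second stage minimizes Σ|v| at the fixed
  maximum agreement.
* Consistency report: percentages of the four categories over classified
  reactions (they sum to 100 by construction);
  accuracy_active = (+F+E)/((+F+E)+(−F+E)),
  accuracy_inactive = (−F−E)/((−F−E)+(+F−E)),
  accuracy_overall = (+F+E)+(−F−E). Degenerate denominators are reported
  as not applicable. The same arithmetic applied to published category
  rows reproduces the published accuracies within the rounding of the
  printed inputs.
* Community expression uses one merged gene table; genes resolve to
  species through the member gene sets, which the merges preserve.

## The synthetic consortium

The fixture generator emulates a thermophilic phototroph–heterotroph mat
community at desk scale. The phototroph (~15 internal/transport reactions)
runs photon-driven water splitting, CO₂ fixation, nitrate reduction,
amino-acid and (3-step) vitamin biosynthesis, and natively leaks sugar and
ammonia. The heterotroph (~12 reactions) respires sugar with O₂ and
ammonia but — by default — lacks nitrate assimilation and the entire
vitamin pathway, and has no vitamin importer: the draft grows nowhere, as
unrefined drafts typically do, and even after repair it cannot grow
autotrophically on its own. Chemistry uses real elemental formulas at a
CH₂O level of abstraction so every enzymatic and transport reaction is
elementally balanced (checked in tests); photons and the abstract energy
token are massless, biomass reactions are precursor drains and exempt. An
explicit energy-dissipation reaction absorbs surplus energy, since the
fixed production ratios of photosynthesis and respiration would otherwise
deadlock the network.

The vitamin pathway is deliberately three steps so the community-level
repair (exporter + importer, cost 2) is strictly cheaper than in-species
biosynthesis (cost 3) — the parsimony decision is exercised, not tied.
The candidate database (10 enzymatic templates + 5 transportable
compounds, ≤ 15 cytosolic candidates per compartment) contains the deleted
pathways, a full autotrophy alternative, and three never-useful
distractors, keeping the brute-force oracle exhaustive in seconds.

Synthetic expression profiles designate a flux-consistent active gene set
(genes of reactions carrying pFBA flux), draw active genes from a
log-normal band around 400, inactive around 2, and universal housekeeping
genes around 150, with the band SD (`noise`, log scale) controlling
overlap; at the default noise = 1.0 the percentile rule recovers ~95% of
the designated calls, and at noise = 0 recovery is exact.

What the fixtures do *not* emulate: genome-scale redundancy (isozymes,
alternative carbon sources), realistic biomass compositions, enzyme
kinetics, regulation, or noise structure of real RNA-seq (library size,
overdispersion). Passing tests therefore certify the algorithms — merging
rules, MILP optimality, the delegation economics, threshold arithmetic —
not the biological fidelity of any genome-scale reconstruction.

## Problem sizes and runtime

All benchmarks are sized for interactive use: toy models of 15–25
reactions, communities of ~36, gapfilling MILPs with ≤ 40 binaries,
brute-force enumeration capped at a few thousand LPs, vertex enumeration
on ≤ 6-reaction instances, and 20-seed expression replicates. The whole
test suite runs in well under a minute; the acceptance script in ~20 s on
one CPU.

## Known limitations

* Exchange collapsing in compartmentalized mode assumes compound identity
  is encoded in metabolite id prefixes; models with conflicting id schemes
  need harmonizing first.
* Interaction attribution requires every non-exchange reaction touching
  `e0` to involve exactly one species' cytosol; reactions spanning two
  cytosols (not produced by the merges) would be ignored.
* The brute-force oracle's all-minimal-solutions guarantee assumes uniform
  candidate costs when it stops at the first feasible cardinality; with
  heterogeneous costs it enumerates up to `max_size` only.
* Mixed-bag models cannot support interaction extraction (no species
  boundaries) — that is intrinsic to the representation, not a defect.
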