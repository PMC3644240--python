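# Methods

This note documents the models and procedures implemented in `metcentric`,
the conventions and tolerances they use, and the design choices made where
more than one reasonable convention exists.

## Stoichiometric models and scenarios

A model is a stoichiometric matrix **S** (m metabolites × n reactions) with
flux bounds **lb** ≤ **v** ≤ **ub** in mmol gDW⁻¹ h⁻¹ and a biomass
objective reaction.  The sign convention is the standard one: *sᵢⱼ* > 0
when metabolite *i* is a product of reaction *j*, < 0 when it is a
substrate.  SBML species flagged `boundaryCondition` are treated as
unconstrained sources/sinks and contribute no mass-balance row.  Bounds are
read from the fbc plugin when present, else from COBRA-style
`LOWER_BOUND`/`UPPER_BOUND` kinetic-law parameters (the dialect of the
published *E. coli* reconstructions), else defaulted to [−1000, 1000] for
reversible and [0, 1000] for irreversible reactions.  Exchange reactions
are recognised structurally (single-metabolite stoichiometry), with an
id-prefix fallback, because SBML dialects differ in naming.

Growth conditions live in *scenarios*: per-reaction bound overrides, linear
flux couplings *a·vᵢ − b·vⱼ* = 0 (appended as extra equality rows — this is
how, e.g., a 1:1 ratio between two isoenzymes is imposed), and the
objective.  Uptake limits are exchange lower bounds (uptake is negative
exchange flux: "uptake ≤ U" ⇒ lb = −U); forced secretion is a positive
exchange lower bound.  Maintenance energy follows the usual convention:
growth-associated maintenance is part of the biomass stoichiometry,
non-growth-associated maintenance is an ATP-hydrolysis reaction with a
positive lower bound.

## Linear programming

FBA maximises (or minimises) the objective flux subject to **Sv** = 0,
coupling rows, and bounds.  LPs are solved with HiGHS dual simplex through
`scipy.optimize.linprog` at feasibility/optimality tolerance 10⁻⁹, so
solutions are basic (vertex) solutions and deterministic for a fixed solver
configuration; output metadata records solver and tolerance so degenerate
quantities remain comparable across runs.  FBA optima are generally
degenerate in genome-scale models; FVA (per-reaction min/max subject to
objective ≥ γ·optimum, 0 < γ ≤ 1) quantifies that degeneracy.  The FVA
constraint system is assembled once and reused across all 2n subproblems;
warm-started basis reuse would speed this further but does not change
results, which are identical to the naive two-LPs-per-reaction definition.

## Split-ratio analysis

Partial fluxes ρᵢⱼ = sᵢⱼ·vⱼ, grouped by sign into producing (Pᵢ) and
consuming (Cᵢ) sets; flux sum Φᵢ = Σ_{j∈Pᵢ} ρᵢⱼ; split ratios ρᵢⱼ/Φᵢ.  At
steady state the two sides balance, which the implementation asserts
(relative tolerance 10⁻⁶) rather than assumes — a user-supplied flux vector
that is not at steady state is rejected, not silently summed.  The activity
cutoff below which partial fluxes, metabolites, and reactions are treated
as inactive defaults to 10⁻¹² mmol gDW⁻¹ h⁻¹ and is configurable.
Rendered balance sheets report percentages at two decimals; full precision
is kept internally.  Metabolites occurring in several compartments are
distinct nodes.

Cycle discounting takes an explicit producer set and consumer set (cycles
are identified by the analyst, typically from a condensed branch-point
graph; no automatic cycle detection is attempted): the cycle flux *c* (sum
over the cycle producers) is removed from the producing side and subtracted
from the cycle consumers in proportion to their partial fluxes, after
checking that the cycle does not absorb more than it feeds.  Proportional
attribution makes discounting two disjoint cycles commutative.  Pathway net
balances restrict partial fluxes to a reaction set and divide by a
reference flux magnitude (e.g. glucose uptake), yielding per-substrate
yields such as "net 2 ATP per glucose".

## Branch point analysis

The bipartite reaction graph contains every reaction with |vⱼ| above
threshold and every metabolite with Φᵢ above threshold; edges exist where
|ρᵢⱼ| is above threshold, are directed along the net flux (reaction →
metabolite when producing), and carry the split ratio at their metabolite
endpoint.  Condensation around user-selected hubs proceeds in five steps:
(1) remove excluded nodes; (2) split each "disconnect" node into one
instance per incident edge; (3) bridge transitory nodes — exactly two
countable incident edges to two distinct neighbours, where edges to
instances do not count — into dashed edges, iterating to a fixed point;
(4) prune nodes farther than the distance limit from the nearest hub,
counting every edge (dashed included) as one hop on the bridged graph;
(5) if disconnected, keep only the largest component.

Conventions chosen here, where more than one reading is possible:

- *Transitory* is an edge-count criterion, not a neighbour-count one: a
  node with three parallel edges to two neighbours is a branch point.
  Counting distinct neighbours instead would collapse the 2-cycles that
  bridging legitimately produces from metabolic cycles and destroy exactly
  the topology the analysis is meant to reveal.
- Steps 3–5 are repeated until the graph stops changing: distance pruning
  can leave fresh two-edge nodes at the cut boundary, and the condensed
  result should contain only hubs, instances, and true branch points.
  This also makes the reduction idempotent.
- Distance is measured on the post-bridging graph with dashed edges as one
  hop, and as the minimum over hubs.
- A bridge whose two replaced edges both point into (or out of) the
  bridged node — e.g. a reaction consuming two metabolites after its
  product was excluded — has no flux direction; it is oriented by node-id
  order and flagged undirected (rendered without an arrowhead).
- Ties for the largest component are broken by total flux sum, then by
  smallest node id, for determinism.
- Dashed edges carry one ratio label per metabolite endpoint (two labels
  when both endpoints are metabolites).

DOT export renders metabolite nodes green with Φᵢ at three significant
digits, reaction nodes yellow, bridges dashed, and hub nodes with a heavy
outline.

## Metabolite flux minimisation

Fluxes are split into non-negative components v = v⁺ − v⁻ with the
corresponding columns of the equality system duplicated and negated; bounds
map to v⁺ ∈ [max(lb, 0), ub] and v⁻ ∈ [max(−ub, 0), −lb], and variables
constrained to zero are dropped with their columns.  For metabolite *i* the
LP minimises Σⱼ sᵢⱼ⁺·vⱼ (sᵢⱼ⁺ = max(sᵢⱼ, 0) over the split columns) under
steady state, bounds, and *v*_Biomass ≥ ζ·*v*_Biomass,opt.  The default
ζ = 1 is implemented with a relative slack of 10⁻⁹ on the optimum to absorb
LP round-off.  Essentiality uses a separate tolerance: minimum flux sum
> 10⁻⁹ ⇒ essential.  Futile v⁺/v⁻ pairs in reactions touching the target
metabolite strictly increase the objective and are therefore absent at the
optimum.  The scan defaults to the metabolites carrying flux in a reference
FBA solution (periplasmic and extracellular species included); the full
metabolite set is available behind a flag.  One split system is built once
and reused across all per-metabolite LPs, which differ only in the
objective vector.

The equivalent knockout formulation — clip every reaction that could
consume the metabolite to its non-consuming direction and re-solve FBA — is
implemented as an independent oracle; a knockout that leaves no feasible
flux state reports a biomass optimum of zero.  The test suite asserts the
equivalence (minimum flux sum = 0 ⇔ knockout optimum unchanged) on every
metabolite of every fixture.

Carbon counts come from Hill-notation formulas (only the explicit `C`
token; pseudo-elements such as `R`/`X` count zero carbons with a warning)
or from explicit per-metabolite overrides, which is how conventions like
counting only the two transferred carbons of acetyl-CoA are expressed.
Metabolites without a formula or override are reported separately as
carbon-unknown rather than silently ranked at zero.

## Synthetic fixtures

Fixtures are generated programmatically, never stored, so that sizes and
ratios can be property-tested.  They are topological stand-ins, not
realistic biochemistry: `chain` (fully determined linear path), `diamond`
(one branch point with capacity-forced split ratios), `cycle`
(transamination-style loop with side fluxes, for cycle-discount
arithmetic), `bypass` (two stoichiometrically equivalent routes, giving
nonessential intermediates and [0, total] variability ranges), and
`mini_core` (a ~13-reaction central-carbon toy with ATP, CO₂, forced
acetate-like secretion, a maintenance drain, and a biomass reaction).

`mini_core`'s default conditions — uptake ≤ 10, forced secretion ≥ 1,
maintenance ≥ 1 mmol gDW⁻¹ h⁻¹ — are scaled-down analogues of a
carbon-limited aerobic growth condition with overflow secretion; its
optimum (2·uptake − acetate)/1.2 follows by hand from the steady-state
balances (the lumped TCA-completing reaction carries zero flux at the
optimum because ATP is in surplus and the reaction wastes carbon).  These
fixtures exercise every code path but deliberately omit features of real
genome-scale models — thousands of reactions, extensive degeneracy,
compartmentalisation, cofactor coupling — so green tests certify the
algorithms' correctness, not predictive accuracy on any real organism.

## Numerical summary

| quantity | default | where |
|---|---|---|
| LP feasibility/optimality tolerance | 10⁻⁹ | `lp.SOLVER_TOL` |
| activity cutoff | 10⁻¹² mmol gDW⁻¹ h⁻¹ | `lp.ACTIVITY_THRESHOLD` |
| steady-state balance tolerance (relative) | 10⁻⁶ | `splitratio.BALANCE_TOL` |
| biomass-constraint slack (relative) | 10⁻⁹ | `metmin.BIOMASS_SLACK` |
| essentiality threshold | 10⁻⁹ mmol gDW⁻¹ h⁻¹ | `metmin.ESSENTIALITY_TOL` |
| FVA suboptimality fraction γ | 1.0 | `run_fva` |
| flux-minimisation biomass fraction ζ | 1.0 | `minimize_metabolite_flux` |

## Known limitations

- No MILP, loopless-FBA, thermodynamic constraints, or quadratic
  objectives; no SBML writing of fbc metadata; no automatic pathway
  labelling (annotations are supplied as files) and no automatic currency-
  metabolite detection for the disconnect list.
- FBA degeneracy means per-reaction fluxes and the split ratios derived
  from them can differ between equally optimal solutions; only LP optima
  (the biomass objective, FVA bounds, minimum flux sums) are
  solver-independent.  The optional total-flux secondary objective is off
  by default and intended only to stabilise degenerate outputs.
- Problem sizes in the test suite and the acceptance script are small
  (≤ 13 reactions) by design: they are chosen so every expected value has
  an analytic or enumerative derivation.
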