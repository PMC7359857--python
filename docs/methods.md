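# Methods

## Network construction

KGML pathway documents are parsed with lxml. Gene and compound entries
become nodes identified by the first token(s) of their graphics label
(HGNC-style symbols); KEGG identifiers are kept as aliases. An entry whose
graphics label lists several comma-separated symbols is expanded to one
node per symbol, with every relation touching the entry duplicated to every
member — the analysis counts genes, not KEGG entries. Group entries become
single complex-kind nodes named by joining their members' symbols; relations
into a group attach to the complex node. Real KEGG graphics labels list
aliases of an entry's *first* gene, so faithful expansion of multi-gene
entries from raw KGML alone is approximate; resolving each KEGG id to its
own symbol would require a KEGG lookup table, which this package does not
bundle.

Relation subtypes map one-to-one onto the edge-kind enum; unlisted subtypes
("state change", "missing interaction", …) map to `unknown`. The default
weight scheme is activation/expression/phosphorylation/binding-association
= +2, inhibition/repression/dephosphorylation/ubiquitination/dissociation
= −1, self-inhibition = −1, and indirect/unknown = 0. Expression and
repression are weighted by analogy with activation and inhibition;
"indirect effect" keeps its own label but weight 0, because an indirect
link's sign and timing are not interpretable one-edge-per-step.

Merging pathways unions nodes by id and collapses duplicate
(source, target, kind) edges with a union of pathway provenance; the same
node pair may keep edges of several kinds (a pair annotated as activating
in one pathway and inhibiting in another keeps both edges). Merging is
associative and order-insensitive. A node id used for a gene in one pathway
and a compound in another is an error rather than a silent merge. After
merging, `add_self_inhibition` gives every node — genes, compounds and
complexes alike — exactly one degradation self-loop; compounds and ligands
must decay too, since degradation is the mechanism by which a boosted
signal fades over steps.

Serialization: GraphML carries all node and edge attributes and round-trips
a network exactly; SIF keeps only `source<TAB>kind<TAB>target` triples, so
reading a SIF file re-derives weights from the default scheme and assumes
gene-kind nodes.

## Baseline discretization

Replicate expression values are averaged arithmetically per gene and
rescaled linearly onto the integer grayscale:

    level = round(9 · (x − min) / (max − min)),   half away from zero.

The scale is global across all genes (a single min and max), which makes
levels invariant under positive affine transforms of the raw intensities
and monotone in the input. A degenerate table (all means equal) maps to all
zeros with a warning. An optional `log2(x+1)` pre-transform is available
for raw array intensities and is off by default; the simulator's published
description does not fix a binning rule, so this linear global rule is the
package's documented choice. Complexes and compounds start at level 0, as
do genes missing from the expression table (logged); knockdown overrides
use the same 0 = "not detectable" convention.

## Update rule

The dynamics are synchronous and deterministic. In the default *indicator*
kernel a source contributes its full edge weight whenever its level is
above the activity threshold (default 0); the degradation loop contributes
−1 exactly when the node's own level is positive. The next level is the
current level plus the summed influence, clamped below at 0 and above at
max(9, current level): values pushed above 9 by initial overrides decay
naturally (a ligand at 20 reaches 0 at step 20) but can never grow, and no
node that starts within [0, 9] ever leaves it. A *level-scaled* kernel
(influence ∝ level/9, fractional deltas rounded half away from zero) is
provided for sensitivity analysis only; all quantitative checks use the
indicator kernel. Step indexing: step t is the state after t updates, step
0 the initial state. Runs always return the full trajectory — reaching a
fixed point does not stop a run early; steady-state detection is a separate
query (the earliest step from which nothing changes through the end).

The update equation itself is this package's design choice: the qualitative
mechanics it must reproduce are signal propagation at one edge per step,
signal decay through degradation, and prolonged source activity for
overridden high initial values. Published step-level results from other
implementations of this style of simulator may depend on kernel details
(threshold semantics, level scaling) that differ from this default.

## Scenarios and comparison

The packaged design has three runs of 100 steps: control
{IGF1: 20, INS: 20}; IGF1R-KD {IGF1R: 0, IGF1: 0, INS: 20}; INSR-KD
{INSR: 0, INS: 0, IGF1: 20}. The surviving ligand keeps the control boost
in each knockdown, so the knockdown run differs from the control only in
the silenced branch; this is configurable through scenario JSON files.

A gene is changed iff its trajectory differs from the reference at any
step, step 0 included — overridden nodes count, and so does a gene that
deviates transiently and returns to the reference level. Levels are
integers and equality is exact. `last_agreement_step` returns a distinct
`DIVERGED_AT_START` sentinel (not an integer) for nodes that already differ
at step 0, avoiding overloaded integer semantics. Venn partitions require
the two comparisons to share a reference run and satisfy
|only_a| + |both| = |changed_a| by construction.

## Graph analyses

Signal distance is a multi-source breadth-first shortest path honoring edge
direction, ignoring edge sign and weight (a path through inhibitions still
carries signal) and excluding degradation loops; the distance is the
minimum over sources and the witness path breaks ties by lexicographic
node order. An unreachable target is an explicit result, not an exception.
Under the indicator kernel a perturbation cannot alter a node before the
step equal to its signal distance, which the tests assert jointly with the
engine. The reduced network is the induced subnetwork on focal genes plus
their direct predecessors and successors, self-loops preserved.

## Synthetic data

`random_network` draws an Erdős–Rényi-style digraph: every ordered pair
gets an edge with the specified density, with the kind sampled from a
categorical distribution (defaults: 55% activation, 25% inhibition, 10%
phosphorylation, 5% dephosphorylation, 5% ubiquitination — activating
influence deliberately dominant, as in curated signaling pathways).
`random_baseline` draws replicate intensities from a lognormal
(mu = 6, sigma = 1, three replicates by default), matching the positivity,
right skew and replicate structure of array data. One integer seed feeds a
single generator stream per artifact. The generators emulate the *shape* of
real inputs (directedness, signed kinds, nonnegative replicated baselines),
not the topology of curated pathways or the intensity distribution of any
particular dataset — passing tests show the machinery is correct, not that
any biological conclusion transfers.

The miniature fixture (22 nodes, 44 edges including degradation loops) is a
hand-built condensation of the INS/IGF1 system: ligand→receptor edges, a
shared HRAS→AKT3→MTOR core feeding a TP53→ATM→CHEK2 checkpoint chain seven
edges from the ligands, an IGF1R-only JAK1/STAT3 branch, an INSR-only
SH2B2/CBLC branch, and a constitutively active RAS-GAP brake (NF1, held
active by a mutual-activation pair) inhibiting HRAS. The brake matters:
under the indicator kernel a knockdown propagates only where it alters some
node's *activity window*, and without the brake HRAS would saturate at
level 9 under either single receptor and the shared core would be blind to
the loss of one input. With it, HRAS plateaus lower and decays earlier in a
knockdown, so shared-core genes change under both knockdowns while each
receptor-specific branch changes only under its own — the qualitative
signature the fixture exists to reproduce. Baseline means span 50–940
intensity units with 3% replicate jitter from a fixed generator seed; a
full 100-step run takes well under a second.

## Numerical and boundary choices

- Rounding is always half away from zero (discretization and the
  level-scaled kernel).
- Steady-state detection returns None when the final two states differ
  (e.g. an oscillation), 0 for a constant trajectory.
- `first_return_to_level` requires the node to have visited, left, and
  regained the level, in that order; anything else is None.
- Duplicate merged edges with inconsistent stored weights keep the first
  weight with a warning; weights are normally re-derived from the scheme.
- Empty seed sets, unknown override targets, gene/compound id collisions,
  and malformed KGML are hard errors naming the offender.

## Problem sizes

The test suite and the acceptance script run on the miniature fixture
(22 nodes, 100 steps), on sweeps of 100 seeded random networks of 3–10
nodes for 50 steps against a brute-force per-node oracle, on 20 seeded
10-node networks for reachability checks, and on 1000 random set pairs for
the Venn algebra; the whole suite completes in a few seconds.

## Known limitations

- The update kernel is qualitative: integer levels, indicator activation,
  unit degradation. It is not an ODE surrogate and fits no parameters.
- Changed/unchanged status is sensitive to the activity-window argument
  above; networks whose knockdowns never alter any activity window will
  report fewer changed genes than a level-sensitive kernel would.
- Multi-gene KGML entry expansion from raw KGML is approximate (see
  Network construction).
- Counts computed on networks rebuilt from current KEGG releases will not
  match counts from a frozen historical merge of the same pathways.
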