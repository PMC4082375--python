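# Methods

## The model and its assumptions

A history graph represents aligned genomes plus ancestry: vertices are
oriented DNA segments (optionally labeled with a multibase allele over
A/C/G/T), bidirected adjacencies pair segment sides into threads
(chromosomes or fragments, linear or circular), and directed branches
record homology.  Validity requires the thread property (each side in at
most one adjacency), at most one parent per vertex, and acyclicity of
the event graph obtained by contracting all adjacencies.  The model
assumes the alignment is given and correct; substitutions are scored as
whole-label inequality between branch endpoints (with single-base labels
this is single-base substitution counting), and all rearrangements are
scored as DCJ operations.  Unbalanced events enter only through the
replication/loss structure of the graph; there is no attempt to model
rates, times, or probabilistic weighting — this is a pure parsimony
framework with a user-selectable monotone cost `c(s, r) = ws·s + wr·r`
(default weights 1, 1).

## Lifting, ambiguity and the four bounds

Every labeled vertex projects its label to its most recent labeled
proper ancestor; every attached side projects its adjacency to the most
recent attached ancestor of each endpoint (virtual free roots absorb
projections that leave the top of a tree).  A lifted label is trivial if
it equals the receiving label (or is the only label received by a free
root); a lifted adjacency is trivial if no unattached junction side
(an MRCA of attached, indirectly related sides) interrupts either
projection path and the receiving sides are adjacent themselves (or both
free roots).  A self-lift — both endpoints projecting to the same side —
counts as two incidences on that side, so that the incidence sum always
equals twice the number of lifted edges; the upper-bound rearrangement
cost counts lifted *edges* (incidences halved), which is what makes the
bounds provably coincide on unambiguous graphs.

Substitution ambiguity `u_s` counts non-trivial lifted labels in excess
of one per vertex; rearrangement ambiguity `u_r` counts non-trivial
incidences in excess of one per side.  Zero total ambiguity defines an
AVG.  The bounds: `lbsc` sums distinct non-trivial lifted labels (minus
one per free root that has any); `ubsc` sums all of them (minus the
deepest identical class per such free root); `lbrc` sums
⌈|V_M|/2⌉ − 1 over modules (components of real plus lifted
adjacencies over sides, free-root sides included); `ubrc` subtracts from
the non-trivial lifted edge count the number of modules whose every
side carries exactly one non-trivial incidence.

## Degenerate rearrangement cycles

Within one epoch, root-layer and leaf-layer adjacencies form alternating
cycles and paths once leaf sides are identified with their parents.  A
cycle with k adjacencies per layer costs k − 1 DCJs.  Degenerate
(linear) components arise when material appears or disappears
mid-history; their cost is the size of the smallest cycle completing
them: `max(a, b) − 1` when the two layer counts differ (only branches
need closing), but `a` when `a == b`, because such a path has one loose
end in each layer and closing it demands a whole extra pattern
repetition.  The distinction matters: scoring mixed-end paths at
`max − 1` would let a constructed scenario undercut the proven lower
bound.  On complete epochs (where homologous sides are uniformly
attached) only cycles occur, and the formula is validated against an
exact breadth-first-search DCJ oracle on random small epochs.

## The operator algebra and G-boundedness

Reduction operations delete an adjacency, an isolated vertex or a label,
or contract a branch with a free child or free parent; extensions are
their inverses.  Whether an element of an extension is *seed-reducible*
is decided by membership in a *fix* — a tracked embedded copy of the
seed graph — rather than by searching reduction sequences, a problem of
unknown (possibly NP-hard) complexity.  One fix corresponds to one
equivalence class of reduction sequences; this is a documented
limitation, not an approximation of the bounds themselves.

Labels and adjacencies are classified by a fixed decision order
(junction, bridge, then the non-minimal taxonomy: leaf, complex,
redundant, complicating, unnecessary bridge, removable bridge).  The
bridge-side clause that one endpoint of the lifted partner must remain a
junction after deletion is evaluated by tentative single deletion; no
cascade is considered at classification time (cascades are handled by
the unbridged-graph fixpoint, which deletes reducible bridge adjacencies
and re-classifies until stable).  A graph is G-bounded when it extends
the fix, contains no reducible non-minimal element, and its unbridged
graph has no reducible ping adjacency (a hanging-sided adjacency whose
endpoint's most recent attached ancestor touches another hanging-sided
adjacency).  Classification is recomputed from scratch after every edit;
at the desk scale this package targets (tens of vertices per graph)
full recomputation is cheaper than cache invalidation is risky.

## Extension to an AVG

`extend_to_avg` repeats four moves, each strictly reducing a progress
measure (total ambiguity, then unattached junction side count) and none
raising either upper bound: label an ambiguous free root's root with a
deepest-class lifted label; interpolate a bridge label above a
non-trivially lifting descendant of a substitution-ambiguous vertex;
attach an unattached junction side (to a fresh vertex, or to a new child
of its attached ancestor's partner); and create a bridge adjacency below
a rearrangement-ambiguous side.  Argmax ties are broken
lexicographically in deterministic mode or drawn uniformly when an RNG
is supplied.

## Realisation of an AVG as a simple history

`realise_avg` converts an AVG into an explicit layered scenario with
substitution cost `lbsc` and rearrangement cost `lbrc`:

1. every attached root receives a fresh unattached parent, so module
   paths end in pairable root sides;
2. obliged unattached root sides (those whose free-root sides sit in
   modules) are paired within their modules — preferring ends already
   joined by a lifted edge, evening odd modules with childless fresh
   partners that later retire at no cost;
3. labels propagate up then down (unlabeled trees receive a constant);
4. the graph is stretched layer by layer (threads take the longest-path
   layer of the event graph; branches become chains of label-copying
   vertices).  A vertex with several children splits in a whole-layer
   replication epoch in which every attached contemporary receives the
   same number of children and surplus copies are disposable clones;
   all other transitions are rearrangement epochs.  Chain sides re-pair
   toward the partner of their lineage's terminal side exactly when that
   destination is *mutual*; otherwise they mirror the parental pattern,
   lineages with no destination of their own keep ghost continuations
   alive while a partner needs them, and sides displaced by a new pair
   re-join each other, completing the corresponding DCJ.

Attachment status is provably constant along every lineage of a valid
simple history, which is why obligations propagate and why splits must
be whole-epoch events.  The free tie-breaks of the construction (module
end pairing, copy matching, displaced re-pairing) are genuinely open;
the first pass breaks them deterministically and, if the rearrangement
cost exceeds the target bound, further passes redraw them at random and
the best valid realisation is kept.  Substitution cost is exact in
every pass; across the populations exercised by the test suite the
first or an early pass attains the rearrangement bound as well.  Any
pass output is a valid simple history extending the input, so the
procedure is sound even where the search budget were to run out.

## Simulation protocol

`simulate_history` evolves a single linear chromosome of 5 single-base
segments through 4 epochs, each uniformly a 2-way whole-genome
replication or a rearrangement epoch applying 1 + Poisson(0.5) DCJ
rematches of existing bonds; every branch substitutes with probability
0.05 (at most one child per vertex in replication epochs, so the epoch
stays legal).  Histories are retained only if they contain at least one
substitution, at least one rearrangement and at least two replication
epochs.  The per-branch substitution probability is the one free rate
the protocol description leaves open; 0.05 puts the per-history
substitution count in the low single digits reported for the original
experiment.  The epoch count, genome size, 2-way replication and 10%
degradation follow the stated protocol; the rearrangements-per-epoch
distribution is an explicit knob (`SimParams.rearrangement_mean`).

`reduce_to_leaves` strips ancestral labels and adjacencies and contracts
internal parent branches, leaving leaf threads plus bare homology trees;
`degrade` removes each leaf vertex, label and adjacency with the nominal
probability (dependents first, so only legal reductions are applied).
Because removing a vertex also removes its label and bonds, the
effective removal rate of labels and adjacencies sits slightly above the
nominal 10%; the vertex removal rate is exactly nominal.  Every
reduction is logged as a replayable op record, so the seed graph is a
reduction of the history by construction.

What the generator does not emulate: realistic substitution/rearrangement
rate ratios, chromosome gain and loss beyond what replication epochs
express, unbalanced indel processes, and alignment error (homology is
always correct by construction).  Passing tests therefore demonstrate
the combinatorial machinery on structurally realistic but
rate-unrealistic inputs; they say nothing about statistical performance
on real alignments.

## Sampling the G-bounded poset

`sample_avgs` restarts random walks from the seed graph, each step
drawing uniformly from the applicable attachment moves (candidates from
the four constructive families above, filtered by a full G-boundedness
check of the result) until the walk reaches an AVG.  A walk is pruned as
soon as `c(lbsc, lbrc)` of the current graph exceeds the incumbent —
initially `c(ubsc, ubrc)` of the seed, afterwards the best AVG cost
found.  The closed-form size caps are asserted at every step; with a
seed of n adjacencies and m labeled vertices the walk budget
2·(max(0,10n−8) + max(0,2m−2,20n−16,20n+2m−18) + m) + 20 moves is far
above anything observed.  Endpoints are verified to be G-bounded AVGs.
Walk logs replay bit-identically because candidate enumeration is
sorted and fresh vertex ids come from a deterministic counter.

## Numerical and scale choices

All computations are exact integer combinatorics; there are no
tolerances.  Test problem sizes: 100 simulated history/seed pairs, 200
sampled AVG endpoints (10 per seed over 20 seeds), 1000 random
reduction-monotonicity pairs, 100 random DCJ-oracle epochs, and a
2000-start search rerun over 10 instances at the 5-segment protocol.
These sizes keep the whole suite in the minutes range on one CPU while
exercising every stated property; the original study's 20 × 20,000-start
tables are instance-specific and stochastic and are reproduced
qualitatively (ordering properties of the summary columns), not row by
row.

## Known limitations

* Fix-based reducibility explores one equivalence class of reduction
  sequences per seed; alternative embeddings of the seed are not
  enumerated.
* The realisation's bound-attainment is constructive-plus-search, not
  proven exhaustively for adversarial AVGs; its validity (a cost-sound
  simple history) is unconditional.
* Graph equality is by vertex id; no isomorphism testing is offered.
* The interchange format does not map segments onto reference
  coordinates (no FASTA/VCF/GFA export).
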