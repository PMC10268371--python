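# Methods

This note records the models implemented in `pktaxa`, the conventions
chosen where the underlying definitions leave room, and what the
synthetic test data does and does not establish.

## Structure model and formats

A secondary structure is an arc diagram: positions 1..n on a single
backbone, with base pairs stored as arcs (i, j), i < j.  Invariants
enforced at construction: each position in at most one pair, all
indices in range, and j ≥ i + 2 (an arc joins non-consecutive
positions).  No minimum hairpin-loop size beyond that is imposed — the
benchmark formats impose none.  Two arcs (i, j) and (k, l) with i < k
*cross* iff i < k < j < l; a structure is pseudoknot-free iff it has
no crossing.

BPSEQ and CT parsing share a back end that validates consecutive
positions, symmetric partnering, and the one-partner-per-position
rule.  Header handling mirrors the two dialects the rRNA databases
ship: headered mode skips leading lines that are not records
(comments, `>` accessions, CT count lines); header-free mode accepts
records only.  Dot-bracket-letter notation uses one matching stack per
bracket family, families `()`, `[]`, `{}`, `<>`, then `A/a`..`Z/z`.
The writer assigns families greedily, first-fit in left-endpoint
order, so a pseudoknot-free structure uses only round brackets and a
single crossing uses exactly two families.  Unknown bases map to `N`;
the sequence is optional since every comparison method here ignores
it.  Multi-strand complexes are out of scope; callers can concatenate
components onto one backbone (`concatenate`, default gap 3 nt) before
comparison.

## Genus

The genus of a structure is the minimum number of handles a sphere
needs for the arc diagram to be drawable without crossings.  It is
computed combinatorially from the fatgraph: rank the 2n arc endpoints
in backbone order, close the backbone into a circle, and trace the
boundary components of the thickened diagram as the cycles of the
permutation α∘τ, where τ swaps the endpoints of every arc and α is the
one-step backbone rotation.  With r boundary components,
g = (n − r + 1) / 2.  The walk asserts that every ribbon side is
consumed exactly once.  The computation runs on the full diagram, not
its shadow; stacking arcs provably leaves g unchanged (asserted as a
test by doubling every arc).  Genus is additive over concatenation on
disjoint intervals, and g = 0 exactly for pseudoknot-free diagrams.
The empty structure has g = 0 by convention (one boundary loop).

## Pseudoknot order

A *region* is a maximal stack of consecutively nested pairs
(i, j), (i+1, j−1), … with no unpaired nucleotide inside the run; the
pairs of a structure partition uniquely into regions.  Two regions
conflict when any pair of one crosses any pair of the other.  Orders
are assigned by layering the region conflict graph: layer 0 is a
maximum-cardinality crossing-free subset of regions, layer 1 a
maximum crossing-free subset of the remainder, and so on; the
structure's order is the deepest layer index.  Pseudoknot-free
structures have order 0, two mutually crossing regions order 1, an
m-clique of pairwise-crossing regions order m − 1.

Two readings of the order circulate — "minimum number of regions to
delete for a pseudoknot-free remainder" and the iterative layer
assignment — and they can diverge on conflict graphs such as odd
cycles.  This package implements the layering, which matches the
iterative description and the dot-bracket-letter encoding use; the
divergence is a known limitation of the concept, not of the
implementation.

Exact layering uses branch-and-bound maximum independent sets,
refused above 20 regions (configurable via
`topology.EXACT_REGION_CAP`); among maximum sets the lexicographically
smallest index tuple is taken, which prefers the leftmost-spanning
region.  The fallback heuristic is first-fit in region index order:
it yields the lexicographically smallest *maximal* independent set and
therefore coincides with the exact choice whenever that set is also
maximum, but it can over-layer when it is not — the oracle-equivalence
suite checks agreement on small seeded structures, and no polynomial
heuristic can guarantee it universally.  Auto mode uses exact up to
the cap.

## ASPRA distance

The structural RNA tree abstracts a structure over three operators.
Recursively select the arc with the rightmost paired nucleotide and
classify its relation to the remaining arcs: crossing (with the count
of crossed arcs carried in the label) wins over nesting (all remaining
arcs strictly inside the selected arc) wins over concatenation.  The
left child is the tree of the remaining structure, the right child the
selected arc as a leaf; a single arc is a leaf, a structure with no
arcs maps to an empty-tree sentinel.  Leaves are in bijection with
arcs, so a structure with p arcs yields 2p − 1 nodes.  Mixed
relations (the selected arc nests some remaining arcs but not all)
classify as concatenation; since the selected arc has the rightmost
endpoint, containment can only run one way.

The distance is the minimum-cost alignment of two such trees under an
ordered-forest alignment dynamic program (the classical tree-alignment
recurrences: match the two rightmost roots, or delete/insert a root
and align its child forest against a suffix of the other forest, with
splits at tree boundaries).  The default scoring is unit-cost:
replacement free for equal labels and 1 otherwise — crossing labels
with different counts count as unequal — and 1 per insertion or
deletion; all costs are configurable through `ScoringScheme`.  The DP
is validated against exhaustive enumeration of all alignments on small
trees.  With a symmetric scheme the distance is symmetric,
non-negative, and zero on identical trees.  No attempt is made to
reproduce the numeric outputs of any particular tree-alignment tool;
the cost constants are a package choice.

## RAG-2D features

The dual graph has one vertex per stem and one edge per maximal
single-stranded segment of **more than one** unpaired nucleotide
strictly inside the backbone, joining the stems of its two flanking
paired positions (a self-loop when both flanks are the same stem, as
in a hairpin loop).  5'/3' dangling ends contribute nothing.  A stem
is a maximal helix, with helices separated by at most one unpaired
nucleotide per strand (and no intervening paired base) merged into one
vertex — consistent with the edge threshold; the merge gap is
configurable, and single-pair stems are admitted.

The Laplacian is L = D − A with a self-loop contributing 2 to both its
adjacency and degree entry, so rows always sum to zero and λ₁ = 0 with
the constant eigenvector (self-loops therefore do not affect the
spectrum).  For a connected graph on n ≥ 2 vertices the Fiedler value
λ₂ is positive; the unit-norm Fiedler vector is sorted ascending,
scaled by (n − 1)/(vₙ − v₁), and the points (i, ṽᵢ) are fitted by
least squares, keeping the slope s and the mean squared residual e.
The scaling denominator is the spread vₙ − v₁: a per-component
denominator vₙ − vᵢ would be singular at i = n, and the spread form is
the only reading defined for every component.  Sign ambiguity of the
eigenvector is resolved by choosing the sign whose sorted vector is
lexicographically smallest (first component the most negative).  When
λ₂ is degenerate the eigensolver's basis choice can leak into (s, e);
the features are well defined only up to that choice, so permutation
invariance is guaranteed (and tested) for graphs with a simple Fiedler
value.  Single-vertex graphs get sentinel features (0, 0) with a
logged warning; disconnected graphs are an error.  The molecule
distance is the Euclidean distance between (s, e) points.

## Clustering

Agglomerative clustering runs directly on a validated dissimilarity
matrix (symmetric within 1e−9 — symmetrised by averaging — finite,
non-negative, zero diagonal).  Linkages: single (min), complete (max),
average (pair-count-weighted mean, i.e. UPGMA).  Ward is deliberately
excluded: it presumes Euclidean inputs, which comparison methods
generally do not produce.  Merging is a naive O(n³) loop — adequate at
benchmark scale (n of a few hundred) — and fully deterministic: equal
merge distances are broken by the smallest pair of cluster creation
indices, and partition labels are assigned by sorted creation index.
The partition at k is the state after n − k merges; single-linkage
partitions equal the components left after deleting the k − 1 largest
edges of a minimum spanning tree, which the tests verify, along with
agreement with an independent library implementation on tie-free
matrices.  Similarity matrices are converted by min–max normalisation
to [0, 1] followed by diss = 1 − sim; a constant matrix maps to all
zeros with a warning.  The cluster count is always the number of
distinct labels in the label file, never estimated.

## Evaluation metrics

Rand index, homogeneity and completeness are computed from the
class-by-cluster contingency table.  Pair counts derive from it
directly (a = Σ C(n_ck, 2), etc.), so a + b + c + d = C(n, 2) by
construction.  Entropies use the natural log with 0·log 0 = 0; the
ratio H(·|·)/H(·) makes the scores base-invariant.  When the class
entropy is zero (all true labels equal) homogeneity is defined as 1,
and symmetrically for completeness — this is what makes a
single-taxon set score 1.0 on every metric for any clustering, the
degenerate identity the framework must reproduce.  Completeness is
implemented literally as homogeneity with the label roles swapped.

## Synthetic data

The generators are pure functions of (seed, call-site tag): each call
derives its own stream, so adding a generator never shifts another's
output.  Defaults: 3–6 helices of 2–5 stacked pairs, hairpin loops of
3–6 nt, inter-element strands of 2–5 nt (which keeps every generated
dual graph connected), 30 molecules in 3 taxa, planted-partition
dissimilarities with within-taxon mean 0.1 (spread 0.02) and
between-taxon mean 1.0 (spread 0.05); negative draws clamp to 0.
These are small rRNA-like dimensions chosen once for desk-scale runs.
Crossing complexity is planted exactly: each crossing motif interleaves
two helices as a…b…a'…b' in its own coordinate window (one crossing
region pair each, order 1), and m-cliques of mutually crossing regions
(opens 1..m, closes 1..m) give order m − 1.  Labelled sets assign
taxon T*t* structures with clique size t + 1, so taxa differ
systematically in topological complexity.

What passing on synthetic data shows: the pipeline's algebra —
parsing, invariants, distances, clustering, scoring — is correct and
deterministic.  What it does not show: performance on real rRNA,
where taxa are not cleanly separated by any single invariant,
structures are far larger, and label noise exists.  The generators
make no attempt at thermodynamic realism or sequence-dependent
pairing.

## Problem sizes

Default test and acceptance runs use structures of tens of arcs,
molecule sets of 9–60, 1000-structure property sweeps for the genus
law, 120 tree pairs for the alignment-enumeration equivalence and 10⁴
fuzz cases for the metric identities — sizes chosen so the whole suite
completes in well under a minute while still exercising every branch.
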