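# Methods

## Problem and model

We reconcile a gene tree *G* and a species tree *S*, both with known branch
lengths, under the requirement that the reconciliation preserve those
lengths exactly.  A history is a triple (*G*, *S*, Φ) with Φ an isometric
mapping: for every gene edge (*u*, *v*), Φ(*u*) is the ancestor of Φ(*v*)
at distance exactly d(*u*, *v*).  Inputs are *partial* histories
(*G_I*, *S_I*, μ): trees that may be unrooted, carry strictly positive
lengths, contain no one-child (rooted) or degree-two (unrooted) internal
nodes, and a total map μ from gene leaves to species leaves.  The output
history may add nodes to *S_I* (edge subdivisions = duplications, and a
chain above the old root) and at most one node to *G_I* (the recovered
root).  We work in a relaxed event model: several events may map to the
same species point (e.g. a duplication coincident with a speciation); the
`check` routine can test a posteriori whether an answer corresponds to a
positive-branch-length simple history.

## Exact arithmetic

Every length is a `fractions.Fraction`; decimal Newick literals are parsed
exactly and re-serialized as decimals when the denominator is of the form
2^a·5^b, else as `p/q`.  The algorithms repeatedly test exact equalities
(half-slack ε = 0, interval endpoints, distance checks); under binary
floating point these predicates would be ill-posed, which drove the choice
of a small purpose-built tree type and Newick parser over float-based
library containers.  Where a serialization convention was not fixed by the
problem we chose one: unrooted trees are written as a top-level
multifurcation anchored at the internal neighbor of the smallest leaf, and
rootedness is a flag, not a property of the text.

## Query structures

A rooted species tree is preprocessed into: node weights w(u) (root
distance), an Euler-tour + sparse-table LCA (O(1) query), and a heavy-path
decomposition for the weighted level ancestor anc(u, d): an edge to child
*v* is heavy iff subtree(v) ≥ subtree(parent)/2, ties heavy (at most one
heavy child per node).  anc walks the O(log n) heavy paths toward the root
and binary-searches exact weights inside the answering path.  All queries
accept implicit points (node, distance-above), including points on the
infinite edge above the root, so the reconciliation stages need no special
cases.  A naive edge-by-edge walk is kept alongside as a test oracle.

## Reconciliation algorithms

*Rooted/rooted.*  Each internal gene node is mapped from one descendant
leaf (smallest label; a "largest label" policy exists only to test that
the choice cannot matter).  The species tree is then materialized — per
anchor node, implicit points are sorted, deduplicated and inserted as
labelled nodes `D1, D2, …` (above-root chain first, then anchors in
preorder) — and every gene edge is checked for isometry.  Failure of any
check is *irreconcilability*, a result distinct from input-contract
violations (which raise `InvalidInputError`).

*Unrooted gene.*  Leaves are mapped by μ; internal nodes by triangulation
Δ from two already-mapped neighbors (the descendant of the two candidate
level-ancestors; undefined triangulation rejects the input).  Scheduling
uses a counter-and-stack of nodes with ≥ 2 mapped neighbors; the result is
order independent.  Then every gene edge is tested for hosting the root:
with λ = lca of the endpoint images and ε = (d(u,v) − d(Φu,λ) − d(Φv,λ))/2,
a potential root is created iff ε > 0 or λ differs from both images, at
offset d(Φu,λ)+ε, mapping to anc(λ, ε).  A negative ε with λ not among the
endpoint images admits no isometric placement and rejects immediately
(equivalent to letting the final check fail, but with a better message).
Two potential roots, a spurious potential root, or a topmost image owned
by a leaf likewise reject.  The per-edge variant maps each endpoint from a
deterministic leaf pair (the two smallest leaves through distinct neighbor
subtrees) and adds an explicit per-edge distance check; it is contractually
identical and is the basis of the doubly-unrooted solver.  Two-leaf gene
trees are handled like any others (the root lands mid-edge).

*Both unrooted.*  Internal species nodes are tried as roots by exact runs.
For root positions inside an edge (x_a, x_b), all quantities are either
fixed or linear forms d + c·ρ in the root offset ρ; fixed points are kept
in coordinates of the tree rooted at x_a and classified by region (x_a
side, x_b subtree, or on the root edge from either end), which gives exact
ancestor/lca/distance case analysis.  Whenever a sign, equality or
comparison of two forms with different slopes would change inside the
current candidate interval, the interval is split at the breakpoint.
Refinement follows a pooled two-pass scheme iterated to a fixed point:
per candidate interval, each gene edge is resolved independently (its
breakpoints recorded and counted for the instrumentation), all endpoints
are pooled, and the refined partition re-simulated until no new endpoints
appear; the parametric root-selection and final isometry stages may add
further splits into the same pool.  Boundary points and node roots are
always decided by exact fixed-root runs, never as limits of parametric
forms.  Each surviving open interval carries one parametric reconciliation
(`evaluate_at` instantiates it at any interior ρ and asserts the isometry
check).  Adjacent accepted pieces are reported merged iff the boundary's
fixed-root history equals both one-sided instantiation limits
node-for-node (zero-length edges contracted before comparison); this is
how half-open answer sets arise.  The slopes of ε are asserted to lie in
{0, ±1/2, ±1, ±3/2, ±2}.  By default the parametric species tree above the
root stays implicit; `explicit_species=True` refines each accepted
interval further (pairwise breakpoints of the above-root height forms) so
every sub-interval carries a fixed, ordered chain of above-root nodes —
off by default because the implicit form answers most questions at a
fraction of the interval count.

*Scaling.*  Species subtrees with no mapped gene leaf are pruned before
deciding ultrametricity and the factor (pruning never changes the lcas or
depths used); the final reconciliation runs against the unpruned input.
If exactly one tree is ultrametric no factor works.  Otherwise either the
unique candidate α = δ_S/δ_G from the lexicographically first leaf pair
with δ_G ≠ 0 is verified by a full run, or (both ultrametric) the
threshold α* = max over internal gene nodes of h_S(x_v)/h_G(v) is computed
and the reconciliation returned at α = α*.  Below α* some gene node would
have to map below the common ancestor of its leaves' images, so we report
irreconcilable for α < α*; this converse is our reading of the necessity
argument and is exercised by the straddling tests.  A gene tree with no
internal nodes reconciles at any factor; we report a threshold certificate
with α* = 0 and run at α = 1.

## Simulator

`simulate_simple_history` emulates gene family evolution on a pure-birth
species tree of unit height with n extant species (3–8 in the test
conditions).  Split times are distinct dyadic rationals (resolution
2⁻¹²) so all downstream arithmetic is exact; an optional non-ultrametric
mode extends terminal branches by dyadic jitter up to half the height.
Each gene lineage experiences duplications and losses as a Poisson process
(defaults 0.3 events per unit length each — roughly one event per family
at this tree height, a realistic regime for a single family); every event
becomes a dedicated one-child species node at its exact (dyadic, per-branch
deduplicated) time, every speciation copies every lineage into both
daughters, and Φ is recorded exactly, so every species node is a single
event by construction.  A resampling guard (new derived seed per attempt)
enforces bounds on surviving gene count; identical parameters and seed
give identical histories.  What the generator does **not** emulate:
branch-length estimation error (lengths are exact by design — the
algorithms target that regime), rate heterogeneity across lineages (only
the uniform scaling variant covers rates), horizontal transfer, and
multifurcating speciations.  Passing round-trip tests therefore certify
algorithmic correctness on exact inputs, not robustness to noisy branch
lengths.

## History formalism

`classify_species_node` implements the event taxonomy directly
(sample / duplication / loss / generalized speciation, with *speciation*
additionally requiring that no gene edge bypass the node, tested via the
extended inverse mapping).  `inferable_version` applies the six reduction
steps in order (prune unobservable gene nodes, bypass one-child nodes,
contract zero-length edges, trim one-child roots).  `expand_to_simple`
rebuilds a simple history: multi-child preimages of duplication nodes
become chains of binary duplications over zero-length edges (children
assigned in label order, two per node); a g-child species node becomes
g−1 chained speciations; silent sides receive loss leaves whose pendant
edge is half the remaining distance to the next node below (each further
insertion halves the segment again, keeping all event times distinct);
repeated sides receive duplication chains; bypassing gene edges are
subdivided and expanded the same way.  The inferable version of the
expansion reproduces the original history exactly, which the suite checks
on simulated instances.

## Testing strategy and problem sizes

The correctness story is oracle-based: (i) ground-truth round trips —
simulate, derive the input, reconcile, compare node-for-node via canonical
signatures that ignore generated labels (200 instances per mode); (ii) for
the doubly-unrooted solver, equivalence with the fixed-root algorithm
probed at every breakpoint and interval midpoint (100 instances), plus
instantiation equality inside accepted intervals; (iii) naive-walk oracles
for the level-ancestor and lca structures (10³ queries); (iv) order- and
policy-independence (50 permutations); (v) exact rational recovery of
simulated scale factors and threshold straddling at 20 factors.  Instance
sizes (≤ 8 species, ≤ 12 extant genes) are the desk scale at which the
exhaustive oracles above remain exhaustive; the algorithms themselves have
no size-specific code paths.

## Known limitations

Tolerance-based reconciliation for noisy branch lengths is out of scope,
as is the rooted-gene/unrooted-species variant.  The doubly-unrooted
solver re-simulates refined intervals from scratch per pooling pass
(clarity over asymptotics); at desk scale a full solution set takes
milliseconds.  Scaling supports only rooted inputs and a single global
factor.
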