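# isorec — isometric gene tree / species tree reconciliation

`isorec` reconciles a gene tree *G* with a species tree *S* when **branch
lengths are known exactly and must be respected**.  It is aimed at people
studying gene family evolution (duplications and losses) in settings where
branch lengths carry real signal — e.g. reconstruction of ancestral genomes
under an infinite-sites-style model — rather than at parsimony
reconciliation, which uses topology only.

## The model

A mapping Φ from the nodes of a rooted gene tree *G* to the points of a
rooted species tree *S* is **isometric** when, for every gene edge
(*u*, *v*) with *u* the parent,

    Φ(u) = anc(Φ(v), d(u, v)),

i.e. the parent's image is the point exactly `d(u, v)` above the child's
image on the path to the root (`anc` is the weighted level-ancestor).  An
input is a gene tree, a species tree (each rooted or unrooted) and a map μ
from gene leaves to the species they were sampled in.  A reconciliation
roots the unrooted tree(s), subdivides species edges by new nodes
(duplications), possibly adds a path above the species root, and produces
an isometric Φ extending μ.  With a rooted species tree the reconciliation
is **unique** when it exists; the package finds it or reports
irreconcilability:

* **rooted / rooted** — direct mapping from one descendant leaf per node,
  then a full isometry check;
* **unrooted gene / rooted species** — internal nodes mapped by
  *triangulation* from two mapped neighbors; the gene root is recovered,
  possibly strictly inside an edge;
* **both unrooted** — every root position on every species edge is analysed
  parametrically: positions of points above the unknown root are linear
  forms `d + c·ρ` in the root offset ρ, edges are split into *unequivocal
  intervals* at the breakpoints where decisions change, and the full
  solution set (nodes, boundary points, open intervals with one parametric
  reconciliation each) is returned;
* **scaling** — when all gene branch lengths are off by an unknown factor
  α > 0: if neither tree is ultrametric there is at most one candidate
  α = δ_S/δ_G; if both are ultrametric the input reconciles exactly for
  α ≥ α* = max_v h_S(x_v)/h_G(v).

All arithmetic is exact (`fractions.Fraction`); decimal Newick lengths are
parsed exactly, so equality tests in the algorithms are well posed.

A seeded simulator of *simple histories* (species tree from a pure-birth
process; duplications/losses as Poisson events along branches) provides
inputs with known ground truth, and the package includes the event
formalism around it: classification of species nodes as
sample/speciation/duplication/loss, reduction of a simple history to its
*inferable version*, and the reverse expansion.

## Worked example

Three genes: `a1` in species `A`, and two copies `c1`, `c2` in species `C`
that split 0.5 before the B–C speciation — a duplication on the internal
branch.

```
$ cat species.nwk                    $ cat gene.nwk
((B:2,C:2)x:1,A:3)r;                 ((c1:2.5,c2:2.5)y:0.5,a1:3)q;
$ cat map.tsv
gene    species
c1      C
c2      C
a1      A

$ isorec reconcile --gene gene.nwk --species species.nwk --map map.tsv --out-prefix out_
{
  "mode": "rooted",
  "n": 5, "m": 5, "N": 10,
  "outcome": "reconciled",
  ...
}
$ cat out_species.nwk
(A:3,((B:2,C:2)x:0.5)D1:0.5)r;
$ cat out_mapping.tsv
gene    species
q       r
y       D1
a1      A
c1      C
c2      C
```

The species tree gained the one-child node `D1` exactly 0.5 above `x`:
that is the inferred duplication, and the gene node `y` maps onto it; the
gene root `q` maps to the root speciation `r`.  `isorec check` on the
bundle confirms `isometric`, `inferable` and `admits_positive_simple` are
all true — the answer corresponds to a real event history with positive
branch lengths.

Other entry points: `isorec reconcile --gene-unrooted` (recovers the gene
root), `--gene-unrooted --species-unrooted` (JSON report of the entire
root-position solution set, optionally instantiated at a chosen offset via
`--rho`), `--scale` (reports the scaling certificate), and
`isorec simulate` (writes `gene.nwk`, `species.nwk`, `map.tsv`,
`truth.json` for a seeded simulated family).

Exit codes: 0 reconciled / non-empty solution set, 2 invalid input,
3 irreconcilable.

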