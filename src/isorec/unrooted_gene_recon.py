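"""Reconciliation of an unrooted gene tree with a rooted species tree.

Internal gene nodes are mapped by triangulation from two already-mapped
neighbors; afterwards each gene edge is examined to decide whether the gene
root lies strictly inside it (in which case the edge is subdivided by a new
potential-root node ``Q``).  The species tree is then materialized, the gene
tree rooted at the topmost image's preimage, and the whole mapping checked
for isometry.  At most one reconciliation exists and the procedure is
independent of processing order.

A second entry point processes every gene edge independently, mapping each
endpoint by triangulating from a deterministic pair of leaves; it produces
identical output and is the basis of the doubly-unrooted algorithm.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

from .tree_model import (
    InputPartialHistory,
    InvalidInputError,
    PhyloTree,
    TreePoint,
    validate_input,
)
from .tree_index import TreeIndex, triangulate
from .rooted_recon import History, Irreconcilable, materialize_species_tree, verify_isometric

__all__ = [
    "RootCandidate",
    "map_internal_nodes",
    "place_root_on_edge",
    "reconcile_unrooted_gene",
    "reconcile_per_edge",
]


@dataclass(frozen=True)
class RootCandidate:
    """A potential gene root strictly inside gene edge (u, v).

    ``offset`` is measured from ``u``; ``lam`` is the lca of the endpoint
    images, ``eps`` the half-slack of the edge length over the distance
    through ``lam``, and ``image`` the root's image ``anc(lam, eps)``.
    """

    u: int
    v: int
    offset: Fraction
    lam: TreePoint
    eps: Fraction
    image: TreePoint


def map_internal_nodes(
    G: PhyloTree,
    idx: TreeIndex,
    leaf_images: dict[int, TreePoint],
    shuffle: Optional[random.Random] = None,
) -> dict[int, TreePoint]:
    """Map all internal nodes of an unrooted gene tree by triangulation.

    Maintains a counter of mapped neighbors per node and a stack of nodes
    ready to map (>= 2 mapped neighbors); the result does not depend on the
    processing order (``shuffle`` exists so tests can verify this).
    Raises :class:`Irreconcilable` when a triangulation is undefined.
    """
    images = dict(leaf_images)
    counter = {u: 0 for u in G.nodes()}
    ready: list[int] = []
    for leaf in leaf_images:
        for nb in G.neighbors(leaf):
            counter[nb] += 1
            if counter[nb] == 2 and nb not in images:
                ready.append(nb)
    while ready:
        if shuffle is not None:
            i = shuffle.randrange(len(ready))
            ready[i], ready[-1] = ready[-1], ready[i]
        x = ready.pop()
        if x in images:
            continue
        mapped_nb = [v for v in G.neighbors(x) if v in images][:2]
        u, v = mapped_nb
        res = triangulate(
            idx, G.edge_length(u, x), G.edge_length(v, x), images[u], images[v]
        )
        if res.status != "resolved":
            raise Irreconcilable(
                f"triangulation undefined at gene node {G.label(x) or x}"
            )
        images[x] = res.point
        for nb in G.neighbors(x):
            counter[nb] += 1
            if counter[nb] == 2 and nb not in images:
                ready.append(nb)
    if len(images) != len(G):
        raise Irreconcilable("gene tree could not be fully mapped")
    return images


def place_root_on_edge(
    G: PhyloTree,
    u: int,
    v: int,
    phi_u: TreePoint,
    phi_v: TreePoint,
    idx: TreeIndex,
) -> Optional[RootCandidate]:
    """Decide whether the gene root lies strictly inside edge (u, v).

    With ``lam = lca(phi_u, phi_v)`` and
    ``eps = (d(u,v) - d(phi_u,lam) - d(phi_v,lam)) / 2``, a potential root
    is created iff ``eps > 0`` or ``lam`` differs from both endpoint images.
    A negative ``eps`` with ``lam`` not among the endpoint images means no
    isometric placement exists on this edge and the input is rejected.
    """
    d_uv = G.edge_length(u, v)
    lam = idx.lca(phi_u, phi_v)
    d_u = idx.dist(lam, phi_u)
    d_v = idx.dist(lam, phi_v)
    eps = (d_uv - d_u - d_v) / 2
    lam_in = lam == phi_u or lam == phi_v
    if eps > 0 or not lam_in:
        if eps < 0:
            raise Irreconcilable(
                f"gene edge ({G.label(u) or u},{G.label(v) or v}) is shorter "
                f"than the species path between its endpoint images"
            )
        return RootCandidate(
            u=u, v=v, offset=d_u + eps, lam=lam, eps=eps, image=idx.anc(lam, eps)
        )
    return None


def _root_and_check(
    G_work: PhyloTree,
    S_I: PhyloTree,
    images: dict[int, TreePoint],
    candidates: list[RootCandidate],
) -> History:
    """Shared Stages 3(apply)-6: subdivide, materialize, root, verify."""
    if len(candidates) > 1:
        raise Irreconcilable(
            "more than one gene edge would contain the root; no single "
            "rooting can be isometric"
        )
    q = None
    if candidates:
        c = candidates[0]
        q = G_work.subdivide_edge(c.u, c.v, c.offset, label="Q")
        images[q] = c.image
    S, phi = materialize_species_tree(S_I, images)
    # Stage 5: the unique species node with a nonempty preimage all of whose
    # proper ancestors have empty preimages (first in preorder).
    preim: dict[int, list[int]] = {}
    for g, s in phi.items():
        preim.setdefault(s, []).append(g)
    top = next(u for u in S.preorder() if u in preim)
    root = min(preim[top], key=lambda g: (G_work.label(g) or "", g))
    if q is not None and root != q:
        raise Irreconcilable(
            "a potential-root node was created on an edge that cannot host "
            "the root"
        )
    if q is None and len(G_work) > 1 and G_work.degree(root) == 1:
        raise Irreconcilable(
            f"the topmost image belongs to leaf {G_work.label(root)}; a tree "
            f"cannot be rooted in a leaf"
        )
    G_work.set_root(root)
    h = History(G_work, S, phi)
    bad = verify_isometric(h)
    if bad is not None:
        u, v = bad
        raise Irreconcilable(
            f"isometry violated on gene edge "
            f"({G_work.label(u) or u}, {G_work.label(v) or v})"
        )
    return h


def _validate_unrooted_gene(iph: InputPartialHistory) -> None:
    problems = validate_input(iph)
    if problems:
        raise InvalidInputError("; ".join(problems))
    if iph.gene.is_rooted or not iph.species.is_rooted:
        raise InvalidInputError(
            "this variant requires an unrooted gene tree and a rooted "
            "species tree"
        )


def _trivial_single_gene(iph: InputPartialHistory) -> History:
    G = iph.gene.copy()
    (leaf,) = G.nodes()
    G.set_root(leaf)
    mu = iph.leaf_map.ids(G, iph.species)
    return History(G, iph.species.copy(), {leaf: mu[leaf]})


def reconcile_unrooted_gene(
    iph: InputPartialHistory, stage2_shuffle: Optional[random.Random] = None
) -> History:
    """Full pipeline: leaf init, triangulation, root placement, rooting,
    isometry check.  Raises :class:`Irreconcilable` when no reconciliation
    exists."""
    _validate_unrooted_gene(iph)
    if len(iph.gene) == 1:
        return _trivial_single_gene(iph)
    G_work = iph.gene.copy()
    S_I = iph.species
    idx = TreeIndex(S_I)
    mu = iph.leaf_map.ids(G_work, S_I)
    leaf_images = {u: TreePoint(s) for u, s in mu.items()}
    images = map_internal_nodes(G_work, idx, leaf_images, shuffle=stage2_shuffle)
    candidates = []
    for u, v in sorted(G_work.edges()):
        c = place_root_on_edge(G_work, u, v, images[u], images[v], idx)
        if c is not None:
            candidates.append(c)
    return _root_and_check(G_work, S_I, images, candidates)


def leaf_pair_for_node(G: PhyloTree, x: int) -> tuple[int, int]:
    """Deterministic pair of leaves whose connecting path passes through
    ``x``: the two lexicographically smallest leaves reachable through
    distinct neighbor subtrees."""
    per_neighbor = []
    for nb in G.neighbors(x):
        best = None
        stack = [(nb, x)]
        while stack:
            y, came = stack.pop()
            nxt = [z for z in G.neighbors(y) if z != came]
            if not nxt:
                lbl = G.label(y) or ""
                if best is None or (lbl, y) < best:
                    best = (lbl, y)
            stack.extend((z, y) for z in nxt)
        per_neighbor.append(best)
    per_neighbor.sort()
    return per_neighbor[0][1], per_neighbor[1][1]


def reconcile_per_edge(iph: InputPartialHistory) -> History:
    """Edge-local variant of the unrooted-gene algorithm.

    Each gene edge is processed independently: both endpoints are mapped by
    triangulation from a fixed per-node leaf pair (Step A), the edge is
    tested for hosting the root (Step B) and its length checked against the
    species distance (Step C).  Output is identical to
    :func:`reconcile_unrooted_gene` on every input.
    """
    _validate_unrooted_gene(iph)
    if len(iph.gene) == 1:
        return _trivial_single_gene(iph)
    G_work = iph.gene.copy()
    S_I = iph.species
    idx = TreeIndex(S_I)
    mu = iph.leaf_map.ids(G_work, S_I)
    images: dict[int, TreePoint] = {u: TreePoint(s) for u, s in mu.items()}
    pair_cache: dict[int, tuple[int, int]] = {}

    def map_node(x: int) -> TreePoint:
        if x in images:
            return images[x]
        if x not in pair_cache:
            pair_cache[x] = leaf_pair_for_node(G_work, x)
        l1, l2 = pair_cache[x]
        res = triangulate(
            idx,
            G_work.dist(l1, x),
            G_work.dist(l2, x),
            TreePoint(mu[l1]),
            TreePoint(mu[l2]),
        )
        if res.status != "resolved":
            raise Irreconcilable(
                f"triangulation undefined at gene node {G_work.label(x) or x}"
            )
        images[x] = res.point
        return res.point

    candidates = []
    for u, v in sorted(G_work.edges()):
        pu = map_node(u)  # Step A
        pv = map_node(v)
        c = place_root_on_edge(G_work, u, v, pu, pv, idx)  # Step B
        # Step C: the edge length must match the species-tree distance,
        # split across the two half-edges when a potential root exists.
        if c is None:
            lam = idx.lca(pu, pv)
            through = idx.dist(lam, pu) + idx.dist(lam, pv)
            if through != G_work.edge_length(u, v):
                raise Irreconcilable(
                    f"gene edge ({G_work.label(u) or u},{G_work.label(v) or v}) "
                    f"length {G_work.edge_length(u, v)} does not match the "
                    f"species distance {through}"
                )
        else:
            d_uv = G_work.edge_length(u, v)
            if (
                idx.dist(c.image, pu) != c.offset
                or idx.dist(c.image, pv) != d_uv - c.offset
            ):
                raise Irreconcilable(
                    f"half-edge distances at the potential root on "
                    f"({G_work.label(u) or u},{G_work.label(v) or v}) do not "
                    f"match"
                )
            candidates.append(c)
    return _root_and_check(G_work, S_I, images, candidates)
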