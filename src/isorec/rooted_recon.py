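"""Reconciliation of a rooted gene tree with a rooted species tree.

An isometric mapping sends every gene node to the point of the species tree
at exactly its distance above the images of its descendant leaves, so each
internal gene node is mapped from one (arbitrary) descendant leaf, the
species tree is materialized by subdividing edges at the mapped points, and
a final pass checks that the mapping is isometric on every gene edge.  The
result, when it exists, is unique.

The module also implements the branch-length scaling variant: finding the
scale factor alpha for which ``alpha * G`` reconciles with ``S`` (a single
candidate when neither tree is ultrametric, a threshold ``alpha*`` when both
are).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

from .tree_model import (
    InputPartialHistory,
    InvalidInputError,
    PhyloTree,
    TreePoint,
    validate_input,
)
from .tree_index import TreeIndex

__all__ = [
    "Irreconcilable",
    "IrreconcilableForAllScales",
    "History",
    "ScalingCertificate",
    "reconcile_rooted",
    "materialize_species_tree",
    "verify_isometric",
    "is_ultrametric",
    "scale_tree",
    "reconcile_scaled",
    "history_signature",
    "histories_equal",
]


class Irreconcilable(Exception):
    """The input admits no isometric reconciliation (a result, not a bug)."""


class IrreconcilableForAllScales(Irreconcilable):
    """No positive scale factor makes the gene tree reconcilable."""


@dataclass
class History:
    """A rooted gene tree, a rooted species tree and an isometric mapping.

    ``phi`` maps every gene node id to a species node id (after
    materialization the image of every gene node is an explicit node).
    """

    gene: PhyloTree
    species: PhyloTree
    phi: dict[int, int]


# ---------------------------------------------------------------------------
# Core pieces shared by all reconciliation algorithms


def materialize_species_tree(
    S_I: PhyloTree, images: dict[int, TreePoint]
) -> tuple[PhyloTree, dict[int, int]]:
    """Turn implicit image points into explicit species-tree nodes.

    ``images`` maps gene node ids to points of ``S_I`` (or above its root).
    Per anchor node the offsets are sorted, exact duplicates merged, and the
    edge to the parent replaced by a path; points above the root become a
    chain on top, whose highest node is the new root.  Added nodes are
    labelled ``D1, D2, ...`` in deterministic traversal order.  Returns the
    new tree and the relocated mapping (gene node id -> species node id).
    """
    S = S_I.copy()
    by_anchor: dict[int, set[Fraction]] = {}
    for pt in images.values():
        if pt.node not in S_I._adj:
            raise InvalidInputError("image point outside the species tree")
        if pt.above > 0:
            by_anchor.setdefault(pt.node, set()).add(pt.above)
    # resolve (anchor, above) -> new node id
    placed: dict[tuple[int, Fraction], int] = {}
    counter = [0]

    def next_label() -> str:
        counter[0] += 1
        return f"D{counter[0]}"

    root = S_I.root
    order = S_I.preorder()
    # chain above the original root first, then subdivisions in preorder
    if root in by_anchor:
        prev = root
        prev_d = Fraction(0)
        for d in sorted(by_anchor[root]):
            node = S.add_node(next_label())
            S.add_edge(prev, node, d - prev_d)
            placed[(root, d)] = node
            prev, prev_d = node, d
        S.set_root(prev)
    for u in order:
        if u == root or u not in by_anchor:
            continue
        parent = S_I.parent(u)
        edge_len = S_I.edge_length(u, parent)
        cur = u
        prev_d = Fraction(0)
        for d in sorted(by_anchor[u]):
            if d >= edge_len:
                raise InvalidInputError("image point beyond its anchor edge")
            node = S.subdivide_edge(cur, parent, d - prev_d, next_label())
            placed[(u, d)] = node
            cur, prev_d = node, d
    phi = {
        g: (pt.node if pt.above == 0 else placed[(pt.node, pt.above)])
        for g, pt in images.items()
    }
    return S, phi


def verify_isometric(h: History) -> Optional[tuple[int, int]]:
    """Check the isometry condition on every gene edge.

    Returns ``None`` when the mapping is isometric, else the first violating
    (parent, child) gene edge: the parent's image must be the ancestor of the
    child's image at exactly the edge's length.
    """
    idx = TreeIndex(h.species)
    G = h.gene
    for v in G.preorder():
        u = G.parent(v)
        if u is None:
            continue
        d = G.edge_length(u, v)
        want = idx.anc(TreePoint(h.phi[v]), d)
        if want != TreePoint(h.phi[u]):
            return (u, v)
    return None


# ---------------------------------------------------------------------------
# Rooted/rooted reconciliation


def _descendant_leaf(G: PhyloTree, v: int, policy: str) -> int:
    leaves = [u for u in G.subtree(v) if not G.children(u)]
    key = lambda u: (G.label(u) or "", u)
    return min(leaves, key=key) if policy == "smallest" else max(leaves, key=key)


def reconcile_rooted(
    iph: InputPartialHistory, leaf_choice: str = "smallest"
) -> History:
    """Reconcile two rooted trees; raises :class:`Irreconcilable` on failure.

    ``leaf_choice`` selects which descendant leaf anchors each internal
    node's image ("smallest" or "largest" label); the output is independent
    of this policy because the reconciliation, when it exists, is unique.
    """
    problems = validate_input(iph)
    if problems:
        raise InvalidInputError("; ".join(problems))
    if not iph.gene.is_rooted or not iph.species.is_rooted:
        raise InvalidInputError("reconcile_rooted requires two rooted trees")
    G = iph.gene.copy()
    S_I = iph.species
    mu = iph.leaf_map.ids(G, S_I)
    if len(G) == 1:
        (leaf,) = G.nodes()
        S = S_I.copy()
        return History(G, S, {leaf: mu[leaf]})
    idx = TreeIndex(S_I)
    images: dict[int, TreePoint] = {}
    for v in G.preorder():
        if not G.children(v):
            images[v] = TreePoint(mu[v])
        else:
            u = _descendant_leaf(G, v, leaf_choice)
            d = G.depth(u) - G.depth(v)
            images[v] = idx.anc(TreePoint(mu[u]), d)
    S, phi = materialize_species_tree(S_I, images)
    h = History(G, S, phi)
    bad = verify_isometric(h)
    if bad is not None:
        u, v = bad
        raise Irreconcilable(
            f"isometry violated on gene edge "
            f"({G.label(u) or u}, {G.label(v) or v})"
        )
    return h


# ---------------------------------------------------------------------------
# Scaling


def is_ultrametric(T: PhyloTree) -> bool:
    """True iff all leaves are at exactly the same depth (molecular clock)."""
    depths = {T.depth(u) for u in T.leaves()}
    return len(depths) <= 1


def scale_tree(G: PhyloTree, alpha) -> PhyloTree:
    alpha = Fraction(alpha)
    if alpha <= 0:
        raise InvalidInputError("scale factor must be positive")
    T = G.copy()
    for u, v in T.edges():
        T._adj[u][v] = T._adj[u][v] * alpha
        T._adj[v][u] = T._adj[u][v]
    T._cache = None
    return T


@dataclass
class ScalingCertificate:
    """Why a particular scale factor was chosen.

    ``unique-alpha``: neither tree is ultrametric and a single candidate
    ``alpha = delta_S / delta_G`` exists, witnessed by a leaf pair whose
    root-distance differences are ``delta_G`` (gene) and ``delta_S``
    (species).  ``threshold``: both trees are ultrametric and the input is
    reconcilable exactly for ``alpha >= alpha*``, witnessed by the gene node
    maximizing ``h_S(x_v) / h_G(v)``.
    """

    case: str  # "unique-alpha" | "threshold"
    alpha: Optional[Fraction] = None
    alpha_star: Optional[Fraction] = None
    leaf_pair: Optional[tuple[str, str]] = None
    delta_g: Optional[Fraction] = None
    delta_s: Optional[Fraction] = None
    argmax_node: Optional[str] = None
    h_g: Optional[Fraction] = None
    h_s: Optional[Fraction] = None


def _prune_unmapped(S_I: PhyloTree, mapped_leaf_labels: set[str]) -> PhyloTree:
    """Drop species subtrees containing no mapped gene leaf (depths of the
    remaining leaves are unchanged)."""
    S = S_I.copy()
    changed = True
    while changed:
        changed = False
        for u in list(S.nodes()):
            if u == S.root:
                continue
            if S.degree(u) == 1 and (S.label(u) not in mapped_leaf_labels):
                S.remove_node(u)
                changed = True
    return S


def reconcile_scaled(
    iph: InputPartialHistory,
) -> tuple[ScalingCertificate, History]:
    """Find a scale factor for the gene tree and reconcile at it.

    Raises :class:`IrreconcilableForAllScales` when no positive factor can
    work (exactly one tree ultrametric, or the unique candidate fails).
    """
    problems = validate_input(iph)
    if problems:
        raise InvalidInputError("; ".join(problems))
    if not iph.gene.is_rooted or not iph.species.is_rooted:
        raise InvalidInputError("reconcile_scaled requires two rooted trees")
    G = iph.gene
    mapped = set(iph.leaf_map.as_dict().values())
    S_pruned = _prune_unmapped(iph.species, mapped)
    g_ultra = is_ultrametric(G)
    s_ultra = is_ultrametric(S_pruned)
    if g_ultra != s_ultra:
        raise IrreconcilableForAllScales(
            "exactly one of the trees is ultrametric (after pruning unmapped "
            "species subtrees); no scale factor can reconcile them"
        )
    mu = iph.leaf_map.as_dict()
    if not g_ultra:
        # unique candidate from the first leaf pair with a height difference
        leaves = sorted(G.leaves(), key=lambda u: G.label(u) or "")
        pair = None
        for i in range(len(leaves)):
            for j in range(i + 1, len(leaves)):
                a, b = leaves[i], leaves[j]
                dg = G.depth(a) - G.depth(b)
                if dg != 0:
                    if dg < 0:
                        a, b, dg = b, a, -dg
                    pair = (a, b, dg)
                    break
            if pair:
                break
        assert pair is not None
        a, b, delta_g = pair
        sa = S_pruned.node_by_label(mu[G.label(a)])
        sb = S_pruned.node_by_label(mu[G.label(b)])
        delta_s = S_pruned.depth(sa) - S_pruned.depth(sb)
        if delta_s <= 0:
            raise IrreconcilableForAllScales(
                "leaf-pair height differences have incompatible signs"
            )
        alpha = delta_s / delta_g
        cert = ScalingCertificate(
            case="unique-alpha",
            alpha=alpha,
            leaf_pair=(G.label(a), G.label(b)),
            delta_g=delta_g,
            delta_s=delta_s,
        )
        try:
            h = reconcile_rooted(
                InputPartialHistory(scale_tree(G, alpha), iph.species, iph.leaf_map)
            )
        except Irreconcilable as e:
            raise IrreconcilableForAllScales(
                f"the unique candidate alpha={alpha} fails: {e}"
            ) from e
        return cert, h

    # both ultrametric: threshold alpha* = max h_S(x_v) / h_G(v)
    idx = TreeIndex(S_pruned)
    leaf_depth_g = {G.depth(u) for u in G.leaves()}
    hg_base = next(iter(leaf_depth_g)) if leaf_depth_g else Fraction(0)
    s_leaf_depths = {S_pruned.depth(u) for u in S_pruned.leaves()}
    hs_base = next(iter(s_leaf_depths)) if s_leaf_depths else Fraction(0)
    best = None
    for v in G.preorder():
        if not G.children(v):
            continue
        h_g = hg_base - G.depth(v)
        leaf_imgs = [
            S_pruned.node_by_label(mu[G.label(u)])
            for u in G.subtree(v)
            if not G.children(u)
        ]
        x_v = leaf_imgs[0]
        for w in leaf_imgs[1:]:
            x_v = idx.lca_nodes(x_v, w)
        h_s = hs_base - S_pruned.depth(x_v)
        ratio = h_s / h_g
        if best is None or ratio > best[0]:
            best = (ratio, v, h_g, x_v, h_s)
    if best is None:
        # no internal gene nodes: any positive scale reconciles trivially
        cert = ScalingCertificate(case="threshold", alpha_star=Fraction(0))
        h = reconcile_rooted(iph)
        return cert, h
    alpha_star, v, h_g, x_v, h_s = best
    cert = ScalingCertificate(
        case="threshold",
        alpha_star=alpha_star,
        argmax_node=G.label(v) or str(v),
        h_g=h_g,
        h_s=h_s,
    )
    alpha = alpha_star if alpha_star > 0 else Fraction(1)
    h = reconcile_rooted(
        InputPartialHistory(scale_tree(G, alpha), iph.species, iph.leaf_map)
    )
    return cert, h


# ---------------------------------------------------------------------------
# Structural comparison of histories


def _tree_canonical(
    T: PhyloTree,
) -> tuple[tuple, dict[int, int]]:
    """Canonical nested-tuple form of a rooted tree plus a canonical index
    for every node (children ordered by smallest leaf label; generated
    internal labels are ignored)."""
    index: dict[int, int] = {}
    counter = [0]

    def visit(u: int, elen: Optional[Fraction]):
        index[u] = counter[0]
        counter[0] += 1
        kids = T.children(u)
        if not kids:
            return (elen, T.label(u))
        ordered = sorted(kids, key=lambda v: T.min_leaf_label(v, avoid=u))
        return (elen, None, tuple(visit(v, T.edge_length(u, v)) for v in ordered))

    sig = visit(T.root, None)
    return sig, index


def history_signature(h: History) -> tuple:
    """Canonical form of a history: tree shapes, exact lengths, leaf labels
    and the mapping (via canonical species indices).  Generated internal
    labels do not participate, so histories are compared node-for-node."""
    s_sig, s_index = _tree_canonical(h.species)
    G = h.gene

    def visit(u: int, elen):
        kids = G.children(u)
        entry = (elen, G.label(u) if not kids else None, s_index[h.phi[u]])
        if not kids:
            return entry
        ordered = sorted(kids, key=lambda v: G.min_leaf_label(v, avoid=u))
        return entry + (tuple(visit(v, G.edge_length(u, v)) for v in ordered),)

    return (s_sig, visit(G.root, None))


def histories_equal(h1: History, h2: History) -> bool:
    return history_signature(h1) == history_signature(h2)
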