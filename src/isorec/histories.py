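"""Gene-family histories: simulation, event classification and the
correspondence between simple and inferable histories.

A *simple* history is one in which every species-tree node is exactly one
evolutionary event: a sample (leaf), a speciation, a duplication or a loss.
The algorithms in this package output *inferable* histories — histories
containing only structure recoverable from extant genes.  This module
provides a seeded simulator of simple histories (species tree from a
pure-birth process, duplications and losses as Poisson events along species
branches), the reduction of a simple history to its inferable version, the
reverse expansion, and derivation of reconciliation inputs with ground
truth.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Optional

from .tree_model import InputPartialHistory, LeafMap, PhyloTree, TreePoint
from .rooted_recon import History

__all__ = [
    "EventClass",
    "SimParams",
    "SimpleHistory",
    "SimulationError",
    "simulate_simple_history",
    "classify_species_node",
    "extended_inverse",
    "inferable_version",
    "is_inferable",
    "admits_positive_simple",
    "expand_to_simple",
    "derive_input",
]


class EventClass(Enum):
    SAMPLE = "sample"
    SPECIATION = "speciation"
    GENERALIZED_SPECIATION = "generalized_speciation"
    DUPLICATION = "duplication"
    LOSS = "loss"
    OTHER = "other"


class SimulationError(RuntimeError):
    """Raised when the simulator's resampling guard is exhausted."""


@dataclass(frozen=True)
class SimParams:
    """Conditions for the simple-history simulator.

    Rates are events per gene lineage per unit branch length; the species
    tree is a pure-birth (Yule) tree of unit height, so with the default
    rates a family experiences on the order of one duplication/loss.  All
    event times are dyadic rationals (resolution ``1/denominator``) so that
    downstream arithmetic stays exact.  ``seed`` fixes all randomness.
    """

    n_species: int = 5
    dup_rate: float = 0.3
    loss_rate: float = 0.3
    seed: int = 0
    min_extant_genes: int = 2
    max_extant_genes: Optional[int] = None
    ultrametric: bool = True
    height: Fraction = Fraction(1)
    denominator: int = 2**12
    max_retries: int = 200


@dataclass
class SimpleHistory(History):
    """A history whose species nodes each carry exactly one event."""

    events: dict[int, EventClass] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Simulation


def _yule_species_tree(p: SimParams, rng: random.Random) -> PhyloTree:
    """Ultrametric pure-birth species tree of height ``p.height`` with
    dyadic split times; optionally non-ultrametric by extending terminal
    branches."""
    S = PhyloTree()
    n = p.n_species
    if n < 1:
        raise SimulationError("need at least one species")
    if n == 1:
        S.add_node("s1")
        S.set_root(S.nodes()[0])
        return S
    Q = p.denominator
    ticks = rng.sample(range(1, Q), n - 1)
    times = sorted(Fraction(t, Q) * p.height for t in ticks)
    root = S.add_node(None)
    S.set_root(root)
    # active lineages: (attachment node, birth time)
    active = [(root, Fraction(0)), (root, Fraction(0))]
    for t in times[1:]:
        i = rng.randrange(len(active))
        node, born = active.pop(i)
        mid = S.add_node(None)
        S.add_edge(node, mid, t - born)
        active.append((mid, t))
        active.append((mid, t))
    leaf_no = 0
    for node, born in active:
        leaf_no += 1
        extra = Fraction(0)
        if not p.ultrametric:
            extra = Fraction(rng.randrange(0, Q // 2), Q) * p.height
        leaf = S.add_node(f"s{leaf_no}")
        S.add_edge(node, leaf, p.height - born + extra)
    S._cache = None
    return S


def _simulate_once(p: SimParams, rng: random.Random) -> SimpleHistory:
    S0 = _yule_species_tree(p, rng)
    S = S0.copy()
    G = PhyloTree()
    phi: dict[int, int] = {}
    events: dict[int, EventClass] = {}
    total_rate = p.dup_rate + p.loss_rate
    sample_counter: dict[str, int] = {}
    loss_counter = [0]
    ev_counter = [0]

    # per original branch (keyed by the child node), events to insert later
    branch_events: dict[int, list[tuple[Fraction, str, int]]] = {}

    def gene_node(label: Optional[str]) -> int:
        return G.add_node(label)

    def process_node(c: int, arrivals: list[tuple[Optional[int], Fraction]]):
        depth_c = S0.depth(c)
        kids = S0.children(c)
        if not kids:
            events[c] = EventClass.SAMPLE
            base = S0.label(c)
            for gp, t0 in arrivals:
                sample_counter[base] = sample_counter.get(base, 0) + 1
                g = gene_node(f"{base}_{sample_counter[base]}")
                phi[g] = c
                if gp is not None:
                    G.add_edge(gp, g, depth_c - t0)
            return
        events[c] = EventClass.SPECIATION
        child_lineages: dict[int, list[tuple[int, Fraction]]] = {
            cb: [] for cb in kids
        }
        for gp, t0 in arrivals:
            g = gene_node(None)
            phi[g] = c
            if gp is not None:
                G.add_edge(gp, g, depth_c - t0)
            for cb in kids:
                child_lineages[cb].append((g, depth_c))
        for cb in kids:
            process_branch(cb, child_lineages[cb])

    def process_branch(c: int, lineages: list[tuple[int, Fraction]]):
        top = S0.parent(c)
        t_end = S0.depth(c)
        used: set[Fraction] = {S0.depth(top), t_end}
        evs = branch_events.setdefault(c, [])
        survivors: list[tuple[int, Fraction]] = []
        queue = list(lineages)
        while queue:
            gp, t0 = queue.pop()
            t = t0
            while True:
                if total_rate <= 0:
                    survivors.append((gp, t))
                    break
                w = rng.expovariate(total_rate)
                tq = t + Fraction(max(1, round(w * p.denominator)), p.denominator)
                tries = 0
                while tq in used and tries < 50:
                    w = rng.expovariate(total_rate)
                    tq = t + Fraction(
                        max(1, round(w * p.denominator)), p.denominator
                    )
                    tries += 1
                if tq >= t_end or tq in used:
                    survivors.append((gp, t))
                    break
                used.add(tq)
                kind = (
                    "dup"
                    if rng.random() < p.dup_rate / total_rate
                    else "loss"
                )
                if kind == "dup":
                    g = gene_node(None)
                    G.add_edge(gp, g, tq - t)
                    evs.append((tq, "dup", g))
                    queue.append((g, tq))
                    gp, t = g, tq
                else:
                    loss_counter[0] += 1
                    g = gene_node(f"loss{loss_counter[0]}")
                    G.add_edge(gp, g, tq - t)
                    evs.append((tq, "loss", g))
                    break
        process_node(c, survivors)

    root = S0.root
    if S0.children(root):
        process_node(root, [(None, Fraction(0))])
    else:
        process_node(root, [(None, Fraction(0))])

    # insert event nodes into S (sorted per branch from the top down)
    for c, evs in branch_events.items():
        if not evs:
            continue
        parent = S0.parent(c)
        top_depth = S0.depth(parent)
        cur = parent
        prev_depth = top_depth
        for depth, kind, g in sorted(evs):
            ev_counter[0] += 1
            node = S.subdivide_edge(cur, c, depth - prev_depth, f"E{ev_counter[0]}")
            events[node] = (
                EventClass.DUPLICATION if kind == "dup" else EventClass.LOSS
            )
            phi[g] = node
            cur, prev_depth = node, depth

    # the first gene node created is the one at the species root
    G.set_root(min(G.nodes()))
    return SimpleHistory(G, S, phi, events)


def simulate_simple_history(p: SimParams) -> SimpleHistory:
    """Simulate a simple history; deterministic under ``p.seed``.

    Resamples (up to ``p.max_retries``) until the number of surviving
    extant genes falls within the configured guard.
    """
    for attempt in range(p.max_retries):
        rng = random.Random(f"{p.seed}:{attempt}")
        h = _simulate_once(p, rng)
        extant = [
            u
            for u in h.gene.leaves()
            if not h.species.children(h.phi[u])
        ]
        if len(extant) < p.min_extant_genes:
            continue
        if p.max_extant_genes is not None and len(extant) > p.max_extant_genes:
            continue
        return h
    raise SimulationError(
        f"no simulation with the required number of extant genes in "
        f"{p.max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# Event classification


def _is_anc_node(S: PhyloTree, a: int, b: int) -> bool:
    while b is not None:
        if b == a:
            return True
        b = S.parent(b)
    return False


def extended_inverse(h: History, v: int) -> set[TreePoint]:
    """Preimages of ``v`` plus the implicit points where gene edges cross it.

    For every gene node ``a`` mapping strictly below ``v`` whose parent maps
    strictly above, the crossing point ``pt(a, d(Phi(a), v))`` on the edge
    above ``a`` is included.
    """
    S, G = h.species, h.gene
    out: set[TreePoint] = {TreePoint(g) for g, s in h.phi.items() if s == v}
    dv = S.depth(v)
    for a in G.nodes():
        p = G.parent(a)
        if p is None:
            continue
        sa, sp = h.phi[a], h.phi[p]
        if sa == v or sp == v:
            continue
        if _is_anc_node(S, v, sa) and _is_anc_node(S, sp, v):
            out.add(TreePoint(a, S.depth(sa) - dv))
    return out


def classify_species_node(h: History, v: int) -> EventClass:
    """Classify a species node as the single event it represents, if any."""
    S, G = h.species, h.gene
    kids = S.children(v)
    pre = [g for g, s in h.phi.items() if s == v]
    if not kids:
        return EventClass.SAMPLE
    if len(kids) == 1:
        if pre and all(len(G.children(u)) == 2 for u in pre):
            return EventClass.DUPLICATION
        if pre and all(not G.children(u) for u in pre):
            return EventClass.LOSS
        return EventClass.OTHER
    if len(kids) == 2:
        v1, v2 = kids
        for u in pre:
            uk = G.children(u)
            if len(uk) != 2:
                return EventClass.OTHER
            imgs = [h.phi[w] for w in uk]
            split = (
                _is_anc_node(S, v1, imgs[0])
                and _is_anc_node(S, v2, imgs[1])
            ) or (
                _is_anc_node(S, v2, imgs[0])
                and _is_anc_node(S, v1, imgs[1])
            )
            if not split:
                return EventClass.OTHER
        crossing = extended_inverse(h, v) - {TreePoint(g) for g in pre}
        if not crossing:
            return EventClass.SPECIATION
        return EventClass.GENERALIZED_SPECIATION
    return EventClass.OTHER


# ---------------------------------------------------------------------------
# Inferable histories


def _extant_leaves(h: History) -> set[int]:
    return {
        u
        for u in h.gene.leaves()
        if not h.species.children(h.phi[u])
    }


def is_inferable(h: History) -> bool:
    """Positive lengths, every gene node observable, every one-child species
    node carrying at least one preimage."""
    G, S = h.gene, h.species
    for t in (G, S):
        for u, v in t.edges():
            if t.edge_length(u, v) <= 0:
                return False
    extant = _extant_leaves(h)

    def observable(u: int) -> bool:
        if u in extant:
            return True
        count = 0
        for c in G.children(u):
            if any(x in extant for x in G.subtree(c)):
                count += 1
        return count >= 2

    if not all(observable(u) for u in G.nodes()):
        return False
    pre_nonempty = set(h.phi.values())
    for v in S.nodes():
        if len(S.children(v)) == 1 and v not in pre_nonempty:
            return False
    return True


def admits_positive_simple(h: History) -> bool:
    """True iff the history is the inferable version of some simple history
    with strictly positive branch lengths: every species node must be a
    sample, a duplication or a (generalized) speciation."""
    allowed = {
        EventClass.SAMPLE,
        EventClass.DUPLICATION,
        EventClass.SPECIATION,
        EventClass.GENERALIZED_SPECIATION,
    }
    return all(
        classify_species_node(h, v) in allowed for v in h.species.nodes()
    )


def inferable_version(h: History) -> History:
    """Reduce a simple history to the part recoverable from extant genes.

    Applies, in order: deletion of gene subtrees with no extant leaf,
    bypassing one-child gene nodes, bypassing one-child species nodes with
    empty preimage, contraction of zero-length edges, and removal of
    one-child roots.
    """
    G = h.gene.copy()
    S = h.species.copy()
    phi = dict(h.phi)

    extant = {
        u for u in G.leaves() if not S.children(phi[u])
    }
    # 1. delete gene nodes with no extant descendant (the root always has
    # one when any extant leaf exists)
    keep = {u for u in G.nodes() if any(x in extant for x in G.subtree(u))}
    if not keep:
        raise ValueError("history has no extant genes")
    for u in [x for x in G.nodes() if x not in keep]:
        G.remove_node(u)
        phi.pop(u, None)
    # 2. bypass one-child gene nodes (degree 2, non-root)
    changed = True
    while changed:
        changed = False
        for u in list(G.nodes()):
            if u != G.root and G.degree(u) == 2:
                G.bypass(u)
                phi.pop(u, None)
                changed = True
    # 3. bypass one-child species nodes with empty preimage
    used = set(phi.values())
    changed = True
    while changed:
        changed = False
        for v in list(S.nodes()):
            if v != S.root and S.degree(v) == 2 and v not in used:
                S.bypass(v)
                changed = True
    # 4. contract zero-length edges (species first, remapping phi)
    def contract_zero(T: PhyloTree, on_merge):
        done = False
        while not done:
            done = True
            for x in T.preorder():
                p = T.parent(x)
                if p is not None and T.edge_length(p, x) == 0:
                    for c in list(T.neighbors(x)):
                        if c != p:
                            ln = T.edge_length(x, c)
                            T.remove_edge(x, c)
                            T.add_edge(p, c, ln)
                    if T.label(x) and not T.label(p):
                        T.set_label(p, T.label(x))
                    T.remove_node(x)
                    on_merge(x, p)
                    done = False
                    break

    def s_merge(x, p):
        for g, s in list(phi.items()):
            if s == x:
                phi[g] = p

    contract_zero(S, s_merge)

    def g_merge(x, p):
        phi.pop(x, None)

    contract_zero(G, g_merge)
    # 5. drop one-child gene roots
    while G.root is not None and len(G) > 1 and G.degree(G.root) == 1:
        old = G.root
        (child,) = G.neighbors(old)
        G.remove_node(old)
        phi.pop(old, None)
        G.set_root(child)
    # 6. drop one-child empty-preimage species roots
    used = set(phi.values())
    while (
        S.root is not None
        and len(S) > 1
        and S.degree(S.root) == 1
        and S.root not in used
    ):
        old = S.root
        (child,) = S.neighbors(old)
        S.remove_node(old)
        S.set_root(child)
    return History(G, S, phi)


# ---------------------------------------------------------------------------
# Expansion back to a simple history


def _min_label_key(T: PhyloTree, u: int, avoid: int):
    return T.min_leaf_label(u, avoid=avoid)


def expand_to_simple(h: History) -> SimpleHistory:
    """Convert an inferable history into a simple history whose inferable
    version is ``h``.

    Multi-child preimages of one-child species nodes become chains of
    binary duplications (zero-length edges); a g-child species node becomes
    g-1 chained speciations; missing sides get loss leaves (pendant length:
    half the remaining distance to the next node below), repeated sides get
    duplication chains, and gene edges bypassing a speciation are subdivided
    with loss leaves on the silent sides.
    """
    G = h.gene.copy()
    S = h.species.copy()
    phi = dict(h.phi)
    loss_no = [0]

    for v in list(h.species.nodes()):
        kids = S.children(v)
        pre = [g for g, s in phi.items() if s == v]
        if not kids:
            continue
        if len(kids) == 1:
            ell_max = max((len(G.children(u)) for u in pre), default=2)
            if ell_max <= 2:
                continue
            # chain of ell_max - 1 binary duplications (zero-length edges)
            v_chain = [v]
            below = kids[0]
            blen = S.edge_length(v, below)
            S.remove_edge(v, below)
            for _ in range(ell_max - 2):
                nv = S.add_node(None)
                S.add_edge(v_chain[-1], nv, 0)
                v_chain.append(nv)
            S.add_edge(v_chain[-1], below, blen)
            for u in pre:
                cs = sorted(G.children(u), key=lambda c: _min_label_key(G, c, u))
                lens = {c: G.edge_length(u, c) for c in cs}
                for c in cs[1:]:
                    G.remove_edge(u, c)
                u_chain = [u]
                for _ in range(len(cs) - 2):
                    nu = G.add_node(None)
                    G.add_edge(u_chain[-1], nu, 0)
                    u_chain.append(nu)
                # u_chain[i] hosts child cs[i]; the last hosts the final two
                for i, c in enumerate(cs):
                    if i == 0:
                        continue
                    G.add_edge(u_chain[min(i, len(u_chain) - 1)], c, lens[c])
                for i, nu in enumerate(u_chain):
                    phi[nu] = v_chain[i]
            continue
        # speciation-like node with g >= 2 children
        g = len(kids)
        cs = sorted(kids, key=lambda c: _min_label_key(S, c, v))
        clens = {c: S.edge_length(v, c) for c in cs}
        crossing = sorted(
            extended_inverse(h, v) - {TreePoint(x) for x in pre},
            key=lambda ptn: (h.gene.label(ptn.node) or "", ptn.node),
        )
        # already a clean binary speciation?
        if g == 2 and not crossing:
            clean = True
            for u in pre:
                uk = G.children(u)
                uk_sides = [_side_index(S, h.phi[w], cs) for w in uk]
                if len(uk) != 2 or sorted(uk_sides) != [0, 1]:
                    clean = False
                    break
            if clean:
                continue
        # build the speciation chain in S; side_state[j] tracks the node
        # currently hanging directly below the chain on side j
        for c in cs:
            S.remove_edge(v, c)
        v_chain = [v]
        for _ in range(g - 2):
            nv = S.add_node(None)
            S.add_edge(v_chain[-1], nv, 0)
            v_chain.append(nv)
        side_state: dict[int, int] = {}
        for j, c in enumerate(cs):
            S.add_edge(v_chain[min(j, g - 2)], c, clens[c])
            side_state[j] = c

        def add_loss(u_att: int, j: int):
            s_host = v_chain[min(j, g - 2)]
            child = side_state[j]
            delta = S.edge_length(s_host, child) / 2
            w = S.subdivide_edge(s_host, child, delta)
            side_state[j] = w
            loss_no[0] += 1
            leaf = G.add_node(f"loss{loss_no[0]}")
            G.add_edge(u_att, leaf, delta)
            phi[leaf] = w

        def expand_gene_chain(
            u_first: int, side_children: dict[int, list[tuple[int, Fraction]]]
        ):
            """Give u_first a chain u_1..u_{g-1} mapped along v_chain;
            attach per-side subtrees (gene node, edge length) or losses."""
            u_chain = [u_first]
            for _ in range(g - 2):
                nu = G.add_node(None)
                G.add_edge(u_chain[-1], nu, 0)
                u_chain.append(nu)
            for i, nu in enumerate(u_chain):
                phi[nu] = v_chain[i]
            for j in range(g):
                host = u_chain[min(j, g - 2)]
                attached = side_children.get(j, [])
                if not attached:
                    add_loss(host, j)
                elif len(attached) == 1:
                    w, ln = attached[0]
                    G.add_edge(host, w, ln)
                else:
                    # repeated side: duplication chain immediately below
                    s_host = v_chain[min(j, g - 2)]
                    s_child = side_state[j]
                    blen = S.edge_length(s_host, s_child)
                    S.remove_edge(s_host, s_child)
                    cur = s_host
                    d_chain = []
                    for _ in range(len(attached) - 1):
                        nd = S.add_node(None)
                        S.add_edge(cur, nd, 0)
                        d_chain.append(nd)
                        cur = nd
                    S.add_edge(cur, s_child, blen)
                    side_state[j] = d_chain[0]
                    p_prev = host
                    for t, nd in enumerate(d_chain):
                        pg = G.add_node(None)
                        G.add_edge(p_prev, pg, 0)
                        phi[pg] = nd
                        w, ln = attached[t]
                        G.add_edge(pg, w, ln)
                        p_prev = pg
                    w, ln = attached[-1]
                    G.add_edge(p_prev, w, ln)

        for u in pre:
            uk = list(G.children(u))
            side_children: dict[int, list[tuple[int, Fraction]]] = {}
            for w in uk:
                j = _side_index(S, h.phi[w], cs)
                ln = G.edge_length(u, w)
                G.remove_edge(u, w)
                side_children.setdefault(j, []).append((w, ln))
            for j in side_children:
                side_children[j].sort(
                    key=lambda t: (h.gene.label(t[0]) or "", t[0])
                )
            expand_gene_chain(u, side_children)
        for ptn in crossing:
            a = ptn.node
            par = G.parent(a)
            dist = ptn.above
            elen = G.edge_length(par, a)
            u1 = G.subdivide_edge(par, a, elen - dist)
            j = _side_index(S, h.phi[a], cs)
            ln = G.edge_length(u1, a)
            G.remove_edge(u1, a)
            expand_gene_chain(u1, {j: [(a, ln)]})

    out = SimpleHistory(G, S, phi, {})
    out.events = {v: classify_species_node(out, v) for v in S.nodes()}
    return out


def _side_index(S: PhyloTree, img: int, cs: list[int]) -> int:
    for j, c in enumerate(cs):
        if _is_anc_node(S, c, img):
            return j
    raise ValueError("gene child image is not below any side of the speciation")


# ---------------------------------------------------------------------------
# Reconciliation inputs with ground truth


def derive_input(
    h: History, unroot_gene: bool = False, unroot_species: bool = False
) -> InputPartialHistory:
    """Strip a history down to the reconciliation input it determines.

    The species tree loses every one-child node (duplication nodes and any
    chain above the top speciation); the gene tree is optionally unrooted
    (a two-child root is bypassed, merging its edges; a root with three or
    more children simply becomes an ordinary node); the leaf map is the
    restriction of the mapping to leaves.
    """
    S_I = h.species.copy()
    for v in list(S_I.nodes()):
        if v != S_I.root and S_I.degree(v) == 2:
            S_I.bypass(v)
    while S_I.root is not None and len(S_I) > 1 and S_I.degree(S_I.root) == 1:
        old = S_I.root
        (child,) = S_I.neighbors(old)
        S_I.remove_node(old)
        S_I.set_root(child)

    G_I = h.gene.copy()
    if unroot_gene and len(G_I) > 1:
        old_root = G_I.root
        G_I.set_root(None)
        if G_I.degree(old_root) == 2:
            G_I.bypass(old_root)
    mu = {
        h.gene.label(u): h.species.label(h.phi[u])
        for u in h.gene.leaves()
    }
    if unroot_species and len(S_I) > 1:
        old_root = S_I.root
        S_I.set_root(None)
        if S_I.degree(old_root) == 2:
            S_I.bypass(old_root)
    return InputPartialHistory(G_I, S_I, LeafMap.from_dict(mu))
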