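"""Reconciliation when both trees are unrooted.

The species root may sit at any internal node or anywhere inside any edge.
Rooting positions inside an edge (x_a, x_b) are explored parametrically:
with the root at distance ``rho`` from ``x_a``, every quantity the per-edge
algorithm computes is either independent of ``rho`` (*fixed*) or a linear
form ``d + c*rho`` (*parametric*, for points above the root).  Whenever a
comparison between two forms with different slopes would change its outcome
inside the current candidate interval, the interval is split at the
breakpoint; endpoints from all gene edges are pooled and the refinement
iterated to a fixed point.  Each resulting unequivocal interval carries one
parametric reconciliation (or is rejected); interval boundaries and internal
species nodes are handled by exact fixed-root runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Union

from .tree_model import (
    InputPartialHistory,
    InvalidInputError,
    PhyloTree,
    TreePoint,
    validate_input,
)
from .tree_index import TreeIndex
from .rooted_recon import (
    History,
    Irreconcilable,
    history_signature,
    materialize_species_tree,
    verify_isometric,
)
from .unrooted_gene_recon import leaf_pair_for_node, reconcile_unrooted_gene

__all__ = [
    "LinForm",
    "FixedPoint",
    "ParamPoint",
    "CandidateInterval",
    "ParametricHistory",
    "Rejection",
    "SolutionSet",
    "Instrument",
    "solve_breakpoint",
    "param_anc",
    "simulate_interval",
    "reconcile_both_unrooted",
    "evaluate_at",
]

ALLOWED_EPS_SLOPES = {
    Fraction(0),
    Fraction(1, 2),
    Fraction(-1, 2),
    Fraction(1),
    Fraction(-1),
    Fraction(3, 2),
    Fraction(-3, 2),
    Fraction(2),
    Fraction(-2),
}


# ---------------------------------------------------------------------------
# Linear forms and parametric points


@dataclass(frozen=True)
class LinForm:
    """The linear form ``d + c * rho`` in the root offset ``rho``."""

    d: Fraction
    c: Fraction = Fraction(0)

    def __add__(self, o: "LinForm") -> "LinForm":
        return LinForm(self.d + o.d, self.c + o.c)

    def __sub__(self, o: "LinForm") -> "LinForm":
        return LinForm(self.d - o.d, self.c - o.c)

    def __neg__(self) -> "LinForm":
        return LinForm(-self.d, -self.c)

    def scale(self, k) -> "LinForm":
        k = Fraction(k)
        return LinForm(self.d * k, self.c * k)

    def at(self, rho) -> Fraction:
        return self.d + self.c * Fraction(rho)


def const(x) -> LinForm:
    return LinForm(Fraction(x))


@dataclass(frozen=True)
class FixedPoint:
    """A root-independent point, in coordinates of the species tree rooted
    at ``x_a`` (points on the root edge anchor at ``x_b``)."""

    pt: TreePoint


@dataclass(frozen=True)
class ParamPoint:
    """The point ``pt(r, d + c*rho)`` above the unknown root ``r``."""

    h: LinForm


PPoint = Union[FixedPoint, ParamPoint]

ROOT = ParamPoint(LinForm(Fraction(0)))


@dataclass(frozen=True)
class Interval:
    lo: Fraction
    hi: Fraction

    @property
    def mid(self) -> Fraction:
        return (self.lo + self.hi) / 2


@dataclass(frozen=True)
class CandidateInterval:
    """An open interval of root positions on a species edge, measured from
    the endpoint ``edge[0]``."""

    edge: tuple[int, int]
    lo: Fraction
    hi: Fraction


class SplitAt(Exception):
    """A decision changes at ``rho``; the current interval must be split."""

    def __init__(self, rho: Fraction, tag):
        super().__init__(f"split at {rho}")
        self.rho = rho
        self.tag = tag


class RejectInterval(Exception):
    """No isometric reconciliation exists anywhere in the interval."""


@dataclass
class Rejection:
    reason: str


@dataclass
class Instrument:
    """Counters for the combinatorial bounds of the parametric simulation:
    split endpoints created while mapping one gene node, while mapping both
    endpoints of one gene edge (Step A), sub-intervals per gene edge after
    Step A, and the set of slopes observed in the half-slack ``eps``."""

    max_endpoints_per_node: int = 0
    max_endpoints_per_edge: int = 0
    max_subintervals_per_edge: int = 0
    eps_slopes: set = field(default_factory=set)

    def record_edge(self, tag_points: dict) -> None:
        a_sets = {
            tag: pts for tag, pts in tag_points.items()
            if isinstance(tag, tuple) and tag[0] == "A"
        }
        per_node = max((len(p) for p in a_sets.values()), default=0)
        all_a = set().union(*a_sets.values()) if a_sets else set()
        self.max_endpoints_per_node = max(self.max_endpoints_per_node, per_node)
        self.max_endpoints_per_edge = max(self.max_endpoints_per_edge, len(all_a))
        self.max_subintervals_per_edge = max(
            self.max_subintervals_per_edge, len(all_a) + 1
        )


# ---------------------------------------------------------------------------
# Per-edge context


class EdgeCtx:
    """Everything needed to simulate root positions inside one species edge."""

    def __init__(self, iph: InputPartialHistory, xa: int, xb: int):
        self.iph = iph
        self.G = iph.gene
        self.S = iph.species
        self.xa = xa
        self.xb = xb
        self.L = self.S.edge_length(xa, xb)
        SA = self.S.copy()
        SA.set_root(xa)
        self.SA = SA
        self.idxA = TreeIndex(SA)
        self.in_b = set(SA.subtree(xb))
        self.mu = iph.leaf_map.ids(self.G, self.S)
        self.gene_edges = sorted(self.G.edges())
        self._pairs: dict[int, tuple[int, int]] = {}
        self._dists: dict[tuple[int, int], Fraction] = {}

    def pair(self, x: int) -> tuple[int, int]:
        if x not in self._pairs:
            self._pairs[x] = leaf_pair_for_node(self.G, x)
        return self._pairs[x]

    def gdist(self, a: int, b: int) -> Fraction:
        key = (a, b)
        if key not in self._dists:
            self._dists[key] = self.G.dist(a, b)
        return self._dists[key]

    # -- categories and depths ----------------------------------------------

    def cat(self, pt: TreePoint, I: Interval) -> str:
        n, a = pt.node, pt.above
        if n == self.xb and a > 0:
            t = self.L - a  # distance from x_a along the root edge
            if t <= I.lo:
                return "EA"
            if a <= self.L - I.hi:
                return "EB"
            raise AssertionError("fixed point inside the open root interval")
        if n == self.xa and a > 0:
            raise AssertionError("point above the coordinate root")
        return "B" if n in self.in_b else "A"

    def depth(self, p: PPoint, I: Interval) -> LinForm:
        """Depth below the root of the rooted version, as a linear form."""
        if isinstance(p, ParamPoint):
            return -p.h
        w = self.idxA.point_depth(p.pt)
        c = self.cat(p.pt, I)
        if c == "A":
            return LinForm(w, Fraction(1))
        if c == "EA":
            return LinForm(-w, Fraction(1))
        return LinForm(w, Fraction(-1))  # B and EB

    # -- sign / equality of linear forms over the open interval --------------

    def sign(self, I: Interval, f: LinForm, tag) -> int:
        if f.c == 0:
            return (f.d > 0) - (f.d < 0)
        rho = -f.d / f.c
        if I.lo < rho < I.hi:
            raise SplitAt(rho, tag)
        v = f.at(I.mid)
        return (v > 0) - (v < 0)

    def eq(self, I: Interval, f: LinForm, g: LinForm, tag) -> bool:
        diff = f - g
        if diff.d == 0 and diff.c == 0:
            return True
        # equality can hold only at a single rho; record it as a boundary
        return self.sign(I, diff, tag) == 0

    # -- point algebra --------------------------------------------------------

    def anc_fixed(self, pt: TreePoint, e: Fraction, I: Interval, tag) -> PPoint:
        """Level ancestor of a fixed point by a root-independent distance."""
        if e == 0:
            return FixedPoint(pt)
        c = self.cat(pt, I)
        if c in ("A", "EA"):
            if c == "A":
                w = self.idxA.point_depth(pt)
                if e <= w:
                    return FixedPoint(self.idxA.anc(pt, e))
                h = e - w  # height above x_a
            else:
                h = (self.L - pt.above) + e
            if h <= I.lo:
                return FixedPoint(TreePoint(self.xb, self.L - h))
            if h >= I.hi:
                return ParamPoint(LinForm(h, Fraction(-1)))
            raise SplitAt(h, tag)
        # B / EB side: height above x_b
        if c == "B":
            d_to_xb = self.idxA.point_depth(pt) - self.L
            if e <= d_to_xb:
                return FixedPoint(self.idxA.anc(pt, e))
            hb = e - d_to_xb
        else:
            hb = pt.above + e
        if hb <= self.L - I.hi:
            return FixedPoint(TreePoint(self.xb, hb))
        if hb >= self.L - I.lo:
            return ParamPoint(LinForm(hb - self.L, Fraction(1)))
        raise SplitAt(self.L - hb, tag)

    def anc_point(self, p: PPoint, e: LinForm, I: Interval, tag) -> PPoint:
        if isinstance(p, ParamPoint):
            return ParamPoint(p.h + e)
        assert e.c == 0, "parametric climb from a fixed point"
        return self.anc_fixed(p.pt, e.d, I, tag)

    def is_anc(self, p: PPoint, q: PPoint, I: Interval, tag) -> bool:
        if p == q:
            return True
        if isinstance(p, ParamPoint) and isinstance(q, ParamPoint):
            return self.sign(I, p.h - q.h, tag) >= 0
        if isinstance(p, ParamPoint):
            return True
        if isinstance(q, ParamPoint):
            return False
        cp, cq = self.cat(p.pt, I), self.cat(q.pt, I)
        if cp == "EA":
            # EA points anchor at x_b; smaller `above` = farther from x_a =
            # closer to the root
            return cq == "A" or (cq == "EA" and p.pt.above <= q.pt.above)
        if cp == "A":
            return cq == "A" and self.idxA.is_ancestor(p.pt, q.pt)
        if cp == "EB":
            return cq == "B" or (cq == "EB" and p.pt.above >= q.pt.above)
        return cq in ("B", "EB") and self.idxA.is_ancestor(p.pt, q.pt)

    def lca(self, p: PPoint, q: PPoint, I: Interval, tag) -> PPoint:
        if self.is_anc(p, q, I, tag):
            return p
        if self.is_anc(q, p, I, tag):
            return q
        cp, cq = self.cat(p.pt, I), self.cat(q.pt, I)
        a_side = {"A", "EA"}
        if cp in a_side and cq in a_side:
            return FixedPoint(self.idxA.lca(p.pt, q.pt))
        if cp not in a_side and cq not in a_side:
            return FixedPoint(self.idxA.lca(p.pt, q.pt))
        return ROOT


# ---------------------------------------------------------------------------
# Spec-level primitives


def solve_breakpoint(d1, c1, d2, c2, I: CandidateInterval) -> Optional[Fraction]:
    """Solve ``d1 + c1*rho == d2 + c2*rho``; the solution is returned only
    when strictly inside the interval."""
    c1, c2 = Fraction(c1), Fraction(c2)
    if c1 == c2:
        raise ValueError("forms with equal slopes need no breakpoint")
    rho = (Fraction(d1) - Fraction(d2)) / (c2 - c1)
    return rho if I.lo < rho < I.hi else None


def param_anc(ctx: EdgeCtx, leaf_pt: TreePoint, d, I: CandidateInterval):
    """Three-case level ancestor of a leaf image inside a candidate interval.

    Returns ``("fixed", TreePoint)``, ``("param", LinForm)`` or
    ``("split", rho)``.
    """
    try:
        res = ctx.anc_fixed(leaf_pt, Fraction(d), Interval(I.lo, I.hi), tag="A")
    except SplitAt as s:
        return ("split", s.rho)
    if isinstance(res, ParamPoint):
        return ("param", res.h)
    return ("fixed", res.pt)


# ---------------------------------------------------------------------------
# Steps A-C and Stages 5-6, parametrically


@dataclass(frozen=True)
class _Candidate:
    u: int
    v: int
    offset: LinForm
    image: PPoint


def _map_node(ctx: EdgeCtx, I: Interval, x: int, instrument=None) -> PPoint:
    if ctx.G.degree(x) <= 1:
        return FixedPoint(TreePoint(ctx.mu[x]))
    l1, l2 = ctx.pair(x)
    tag = ("A", x)
    xu = ctx.anc_fixed(TreePoint(ctx.mu[l1]), ctx.gdist(l1, x), I, tag)
    xv = ctx.anc_fixed(TreePoint(ctx.mu[l2]), ctx.gdist(l2, x), I, tag)
    if isinstance(xu, FixedPoint) and isinstance(xv, FixedPoint):
        if ctx.is_anc(xu, xv, I, tag):
            return xv
        if ctx.is_anc(xv, xu, I, tag):
            return xu
        raise RejectInterval(f"triangulation undefined at gene node {x}")
    if isinstance(xu, FixedPoint):
        return xu
    if isinstance(xv, FixedPoint):
        return xv
    return xv if ctx.sign(I, xu.h - xv.h, tag) >= 0 else xu


def _steps_abc(ctx: EdgeCtx, I: Interval, ge: tuple[int, int], instrument=None):
    u, v = ge
    pu = _map_node(ctx, I, u, instrument)
    pv = _map_node(ctx, I, v, instrument)
    duv = const(ctx.G.edge_length(u, v))
    # Step B: potential root inside this edge
    anc_uv = ctx.is_anc(pu, pv, I, "B")
    anc_vu = ctx.is_anc(pv, pu, I, "B")
    lam = pu if anc_uv else (pv if anc_vu else ctx.lca(pu, pv, I, "B"))
    lam_in = anc_uv or anc_vu
    s1 = ctx.depth(pu, I) - ctx.depth(lam, I)
    s2 = ctx.depth(pv, I) - ctx.depth(lam, I)
    eps = (duv - s1 - s2).scale(Fraction(1, 2))
    if instrument is not None:
        instrument.eps_slopes.add(eps.c)
    assert eps.c in ALLOWED_EPS_SLOPES
    sgn = ctx.sign(I, eps, "B")
    cand = None
    if sgn > 0 or not lam_in:
        if sgn < 0:
            raise RejectInterval(
                f"gene edge {ge} shorter than the species path between its "
                f"endpoint images"
            )
        offset = s1 + eps
        if (
            ctx.sign(I, offset, "B") <= 0
            or ctx.sign(I, duv - offset, "B") <= 0
        ):
            raise RejectInterval(f"potential root falls outside gene edge {ge}")
        image = ctx.anc_point(lam, eps, I, "B")
        cand = _Candidate(u, v, offset, image)
    # Step C: edge length against species distance
    if cand is None:
        if not ctx.eq(I, s1 + s2, duv, "C"):
            raise RejectInterval(
                f"gene edge {ge} length does not match the species distance"
            )
    else:
        dq_u = ctx.depth(pu, I) - ctx.depth(cand.image, I)
        dq_v = ctx.depth(pv, I) - ctx.depth(cand.image, I)
        if not ctx.eq(I, dq_u, cand.offset, "C") or not ctx.eq(
            I, dq_v, duv - cand.offset, "C"
        ):
            raise RejectInterval(f"half-edge distances fail on gene edge {ge}")
    return pu, pv, cand


@dataclass
class ParametricHistory:
    """One reconciliation valid for every root position in an open interval.

    The gene root is either an original gene node or a new node inside
    ``candidate``'s gene edge at a (possibly parametric) offset; images are
    fixed species points or parametric points above the root.
    """

    ctx: EdgeCtx
    interval: Interval
    phi: dict[int, PPoint]
    candidate: Optional[_Candidate]
    root_owner: object  # "q" or a gene node id
    # with the explicit-species option: parametric nodes above the root,
    # ordered upward, as (height form, owners mapping there)
    param_chain: Optional[list[tuple[LinForm, list]]] = None

    @property
    def edge(self) -> tuple[int, int]:
        return (self.ctx.xa, self.ctx.xb)


def _with_explicit_chain(
    ph: ParametricHistory,
) -> list[tuple[Interval, ParametricHistory]]:
    """Order the parametric image points above the root, splitting the
    interval wherever two height forms cross, so that each sub-interval
    carries a fixed chain of new species nodes above the root."""
    forms: dict[tuple[Fraction, Fraction], list] = {}
    for owner, p in ph.phi.items():
        if isinstance(p, ParamPoint):
            forms.setdefault((p.h.d, p.h.c), []).append(owner)
    keys = sorted(forms)
    cuts: set[Fraction] = set()
    I = ph.interval
    for i, (d1, c1) in enumerate(keys):
        for d2, c2 in keys[i + 1:]:
            if c1 == c2:
                continue
            rho = (d1 - d2) / (Fraction(c2) - c1)
            if I.lo < rho < I.hi:
                cuts.add(rho)
    pts = sorted({I.lo, I.hi} | cuts)
    out = []
    for lo, hi in zip(pts, pts[1:]):
        mid = (lo + hi) / 2
        order = sorted(keys, key=lambda k: k[0] + k[1] * mid)
        chain = [
            (LinForm(d, c), sorted(forms[(d, c)], key=str)) for d, c in order
        ]
        sub = ParametricHistory(
            ph.ctx, Interval(lo, hi), ph.phi, ph.candidate, ph.root_owner,
            param_chain=chain,
        )
        out.append((Interval(lo, hi), sub))
    return out


def _stages_56(
    ctx: EdgeCtx,
    I: Interval,
    phi: dict[int, PPoint],
    cands: list[_Candidate],
) -> ParametricHistory:
    G = ctx.G
    if len(cands) > 1:
        raise RejectInterval("more than one gene edge would host the root")
    cand = cands[0] if cands else None
    if len(G) == 1:
        (leaf,) = G.nodes()
        return ParametricHistory(ctx, I, dict(phi), None, leaf)
    items: list[tuple[object, PPoint]] = []
    if cand is not None:
        items.append(("q", cand.image))
    for x in sorted(G.nodes(), key=lambda n: (G.label(n) or "", n)):
        items.append((x, phi[x]))
    best_owner, best_pt = items[0]
    best_depth = ctx.depth(best_pt, I)
    for owner, pt in items[1:]:
        dep = ctx.depth(pt, I)
        if ctx.sign(I, dep - best_depth, "S5") < 0:
            best_owner, best_pt, best_depth = owner, pt, dep
    if cand is not None and best_owner != "q":
        raise RejectInterval("potential root is not the topmost image")
    if best_owner != "q" and G.degree(best_owner) == 1:
        raise RejectInterval("topmost image belongs to a leaf")
    # Stage 6: isometry along every edge of the rooted gene tree
    root_sym = best_owner

    def edge_iter():
        """Directed (parent, child, length-form) edges of the rooted gene
        tree, with the candidate edge split when the root is inside it."""
        adj: dict[object, list[tuple[object, LinForm]]] = {
            x: [] for x in G.nodes()
        }
        for a, b in G.edges():
            ln = const(G.edge_length(a, b))
            if cand is not None and (a, b) == (cand.u, cand.v):
                continue
            adj[a].append((b, ln))
            adj[b].append((a, ln))
        if cand is not None:
            duv = const(G.edge_length(cand.u, cand.v))
            adj["q"] = [
                (cand.u, cand.offset),
                (cand.v, duv - cand.offset),
            ]
            adj[cand.u].append(("q", cand.offset))
            adj[cand.v].append(("q", duv - cand.offset))
        seen = {root_sym}
        stack = [root_sym]
        while stack:
            p = stack.pop()
            for child, ln in adj[p]:
                if child in seen:
                    continue
                seen.add(child)
                stack.append(child)
                yield p, child, ln

    full_phi = dict(phi)
    if cand is not None:
        full_phi["q"] = cand.image
    for p, c, ln in edge_iter():
        if not ctx.is_anc(full_phi[p], full_phi[c], I, "S6"):
            raise RejectInterval(f"image of {p} is not an ancestor of {c}'s")
        if not ctx.eq(
            I, ctx.depth(full_phi[c], I) - ctx.depth(full_phi[p], I), ln, "S6"
        ):
            raise RejectInterval(f"distance mismatch on rooted gene edge ({p},{c})")
    return ParametricHistory(ctx, I, full_phi, cand, best_owner)


# ---------------------------------------------------------------------------
# Interval refinement driver

_PENDING = object()


def _resolve_edge(ctx: EdgeCtx, I: Interval, ge, instrument=None) -> set[Fraction]:
    """Recursively resolve Steps A-C for one gene edge inside a candidate
    interval, returning every breakpoint discovered (and feeding the
    per-node / per-edge endpoint counters)."""
    tag_points: dict[object, set[Fraction]] = {}

    def rec(sub: Interval):
        try:
            _steps_abc(ctx, sub, ge, instrument)
        except SplitAt as s:
            tag_points.setdefault(s.tag, set()).add(s.rho)
            rec(Interval(sub.lo, s.rho))
            rec(Interval(s.rho, sub.hi))
        except RejectInterval:
            pass

    rec(I)
    if instrument is not None:
        instrument.record_edge(tag_points)
    out: set[Fraction] = set()
    for pts in tag_points.values():
        out |= pts
    return out


def _process_part(ctx: EdgeCtx, I: Interval, sink: set, instrument=None):
    pending = False
    for ge in ctx.gene_edges:
        found = _resolve_edge(ctx, I, ge, instrument)
        inner = {r for r in found if I.lo < r < I.hi}
        if inner:
            sink |= inner
            pending = True
    if pending:
        return _PENDING
    phi: dict[int, PPoint] = {}
    cands: list[_Candidate] = []
    try:
        for ge in ctx.gene_edges:
            pu, pv, cand = _steps_abc(ctx, I, ge, instrument)
            phi[ge[0]] = pu
            phi[ge[1]] = pv
            if cand is not None:
                cands.append(cand)
        if not ctx.gene_edges:  # single-node gene tree
            for x in ctx.G.nodes():
                phi[x] = FixedPoint(TreePoint(ctx.mu[x]))
        return _stages_56(ctx, I, phi, cands)
    except RejectInterval as e:
        return Rejection(str(e))
    except SplitAt as s:
        sink.add(s.rho)
        return _PENDING


def _simulate(ctx: EdgeCtx, I0: Interval, instrument=None):
    endpoints = {I0.lo, I0.hi}
    while True:
        pts = sorted(endpoints)
        parts = [Interval(a, b) for a, b in zip(pts, pts[1:])]
        new: set[Fraction] = set()
        outcomes = []
        for part in parts:
            res = _process_part(ctx, part, new, instrument)
            outcomes.append((part, res))
        fresh = {r for r in new if I0.lo < r < I0.hi} - endpoints
        if not fresh:
            return outcomes
        endpoints |= fresh


def simulate_interval(
    iph: InputPartialHistory,
    ci: CandidateInterval,
    instrument: Optional[Instrument] = None,
) -> list[tuple[CandidateInterval, Union[ParametricHistory, Rejection]]]:
    """Simulate the per-edge algorithm for all root positions inside a
    candidate interval of a species edge, refining it into unequivocal
    sub-intervals."""
    xa, xb = ci.edge
    ctx = EdgeCtx(iph, xa, xb)
    outcomes = _simulate(ctx, Interval(Fraction(ci.lo), Fraction(ci.hi)), instrument)
    return [
        (CandidateInterval(ci.edge, part.lo, part.hi), res)
        for part, res in outcomes
    ]


# ---------------------------------------------------------------------------
# Instantiation


def _fixed_to_rooted(ctx: EdgeCtx, pt: TreePoint, rho: Fraction, R: int) -> TreePoint:
    """Convert an x_a-rooted coordinate point to the tree rooted at
    ``rho`` along (x_a, x_b) (root node ``R``)."""
    n, a = pt.node, pt.above
    if n != ctx.xb or a == 0:
        return TreePoint(n, a)
    t = ctx.L - a  # distance from x_a
    if t < rho:
        return TreePoint(ctx.xa, t)
    if t == rho:
        return TreePoint(R)
    return TreePoint(ctx.xb, a)


def _instantiate(ph: ParametricHistory, rho, strict: bool) -> Optional[History]:
    ctx = ph.ctx
    rho = Fraction(rho)
    if strict and not (ph.interval.lo < rho < ph.interval.hi):
        raise ValueError(f"rho={rho} is not strictly inside the interval")
    S_rho = ctx.S.copy()
    if 0 < rho < ctx.L:
        R = S_rho.subdivide_edge(ctx.xa, ctx.xb, rho)
        S_rho.set_root(R)
    elif rho == 0:
        R = ctx.xa
        if ctx.S.degree(R) == 1 and len(S_rho) > 1:
            return None  # cannot root in a leaf
        S_rho.set_root(R)
    elif rho == ctx.L:
        R = ctx.xb
        if ctx.S.degree(R) == 1 and len(S_rho) > 1:
            return None
        S_rho.set_root(R)
    else:
        return None
    images: dict[object, TreePoint] = {}
    for owner, p in ph.phi.items():
        if isinstance(p, ParamPoint):
            h = p.h.at(rho)
            if h < 0:
                return None
            images[owner] = TreePoint(R, h)
        else:
            images[owner] = _fixed_to_rooted(ctx, p.pt, rho, R)
    G_rho = ctx.G.copy()
    root = ph.root_owner
    if ph.candidate is not None:
        c = ph.candidate
        off = c.offset.at(rho)
        duv = ctx.G.edge_length(c.u, c.v)
        img_q = images.pop("q")
        if 0 < off < duv:
            q = G_rho.subdivide_edge(c.u, c.v, off, label="Q")
            images[q] = img_q
            root = q
        elif off == 0:
            root = c.u
            if images[c.u] != img_q:
                return None
        elif off == duv:
            root = c.v
            if images[c.v] != img_q:
                return None
        else:
            return None
    if len(G_rho) > 1 and G_rho.degree(root) == 1:
        return None
    G_rho.set_root(root)
    try:
        S_m, phi = materialize_species_tree(S_rho, images)
    except (InvalidInputError, ValueError):
        return None
    h = History(G_rho, S_m, phi)
    if verify_isometric(h) is not None:
        if strict:
            raise AssertionError("parametric history failed instantiation")
        return None
    return h


def evaluate_at(ph: ParametricHistory, rho) -> History:
    """Instantiate a parametric reconciliation at an interior root offset.

    The result is a concrete history that passes the isometry check; two
    offsets in the same interval give histories differing only in branch
    lengths.
    """
    h = _instantiate(ph, rho, strict=True)
    assert h is not None
    return h


# ---------------------------------------------------------------------------
# Full solution over all root positions


@dataclass
class MergedRun:
    """A maximal set of accepted root positions on one species edge, with
    closed/open end flags (positions are offsets from edge[0])."""

    edge: tuple[int, int]
    lo: Fraction
    lo_closed: bool
    hi: Fraction
    hi_closed: bool


@dataclass
class SolutionSet:
    """All isometric reconciliations of a doubly-unrooted input.

    ``node_results`` maps internal species nodes to a history or ``None``
    (irreconcilable); ``edge_results`` holds, per species edge, interior
    boundary points with their fixed-root outcome and open intervals with
    their parametric outcome.  ``merged`` reports maximal accepted
    root-position sets per edge.
    """

    species: PhyloTree
    node_results: dict[int, Optional[History]]
    edge_results: dict[
        tuple[int, int],
        list[tuple[str, object, object]],  # ("point", rho, History|None) or
        # ("interval", CandidateInterval, ParametricHistory|Rejection)
    ]
    merged: dict[tuple[int, int], list[MergedRun]] = field(default_factory=dict)

    def accepts_node(self, v: int) -> bool:
        return self.node_results.get(v) is not None

    def accepts_edge_point(self, edge: tuple[int, int], rho) -> bool:
        rho = Fraction(rho)
        u, v = edge
        if (u, v) not in self.edge_results:
            u, v = v, u
            rho = self.species.edge_length(u, v) - rho
        entries = self.edge_results[(u, v)]
        if rho == 0:
            return self.accepts_node(u)
        if rho == self.species.edge_length(u, v):
            return self.accepts_node(v)
        for kind, key, res in entries:
            if kind == "point" and key == rho:
                return res is not None
            if kind == "interval" and key.lo < rho < key.hi:
                return isinstance(res, ParametricHistory)
        return False


def _root_at_edge_point(
    iph: InputPartialHistory, edge: tuple[int, int], rho: Fraction
) -> Optional[History]:
    """Fixed-root run with the species tree rooted at pt(edge, rho)."""
    u, v = edge
    S = iph.species.copy()
    L = S.edge_length(u, v)
    if rho == 0:
        root = u
    elif rho == L:
        root = v
    else:
        root = S.subdivide_edge(u, v, rho)
    if S.degree(root) == 1 and len(S) > 1:
        return None  # cannot root in a leaf
    S.set_root(root)
    try:
        return reconcile_unrooted_gene(
            InputPartialHistory(iph.gene, S, iph.leaf_map)
        )
    except Irreconcilable:
        return None


def _limit_signature(ph: ParametricHistory, rho: Fraction):
    h = _instantiate(ph, rho, strict=False)
    return None if h is None else history_signature(h)


def _merge_edge(
    iph: InputPartialHistory,
    edge: tuple[int, int],
    entries,
    node_results,
) -> list[MergedRun]:
    """Merge adjacent accepted intervals/points whose reconciliations agree
    in the limit into maximal root-position runs."""
    u, v = edge
    L = iph.species.edge_length(u, v)

    # elements in positional order: (lo, hi, closed?, signature or None)
    elems = []
    if iph.species.degree(u) > 1:
        h = node_results.get(u)
        elems.append((Fraction(0), Fraction(0), h is not None,
                      history_signature(h) if h else None))
    for kind, key, res in sorted(
        entries, key=lambda e: e[1] if e[0] == "point" else e[1].lo
    ):
        if kind == "point":
            ok = res is not None
            elems.append((key, key, ok, history_signature(res) if ok else None))
        else:
            ok = isinstance(res, ParametricHistory)
            elems.append((key.lo, key.hi, ok, res if ok else None))
    if iph.species.degree(v) > 1:
        h = node_results.get(v)
        elems.append((L, L, h is not None, history_signature(h) if h else None))

    runs: list[MergedRun] = []
    cur: Optional[MergedRun] = None
    prev = None
    for lo, hi, ok, payload in elems:
        is_interval = hi > lo
        if not ok:
            cur = None
            prev = None
            continue
        joins = False
        if cur is not None and prev is not None and cur.hi == lo:
            p_kind, p_payload = prev
            if p_kind == "interval" and not is_interval:
                joins = _limit_signature(p_payload, lo) == payload
            elif p_kind == "point" and is_interval:
                joins = _limit_signature(payload, lo) == p_payload
            else:
                joins = False
        if joins:
            cur.hi = hi
            cur.hi_closed = not is_interval
        else:
            cur = MergedRun(edge, lo, not is_interval, hi, not is_interval)
            runs.append(cur)
        prev = ("interval" if is_interval else "point", payload)
    return runs


def reconcile_both_unrooted(
    iph: InputPartialHistory,
    instrument: Optional[Instrument] = None,
    explicit_species: bool = False,
) -> SolutionSet:
    """Enumerate every rooting of the species tree that admits an isometric
    reconciliation: exact runs at internal nodes and at interval boundaries,
    parametric reconciliations on the unequivocal open intervals.

    With ``explicit_species`` each accepted interval is further refined so
    that the chain of new species nodes above the root has a fixed order
    (``param_chain``); by default the parametric species tree stays
    implicit.
    """
    problems = validate_input(iph)
    if problems:
        raise InvalidInputError("; ".join(problems))
    if iph.gene.is_rooted or iph.species.is_rooted:
        raise InvalidInputError(
            "reconcile_both_unrooted requires two unrooted trees"
        )
    S = iph.species
    node_results: dict[int, Optional[History]] = {}
    for nd in S.nodes():
        if S.degree(nd) == 1 and len(S) > 1:
            continue  # cannot root in a leaf
        S_r = S.copy()
        S_r.set_root(nd)
        try:
            node_results[nd] = reconcile_unrooted_gene(
                InputPartialHistory(iph.gene, S_r, iph.leaf_map)
            )
        except Irreconcilable:
            node_results[nd] = None
    edge_results: dict[tuple[int, int], list] = {}
    for edge in sorted(S.edges()):
        L = S.edge_length(*edge)
        pieces = simulate_interval(
            iph, CandidateInterval(edge, Fraction(0), L), instrument
        )
        if explicit_species:
            refined = []
            for ci, res in pieces:
                if isinstance(res, ParametricHistory):
                    for sub, ph in _with_explicit_chain(res):
                        refined.append(
                            (CandidateInterval(edge, sub.lo, sub.hi), ph)
                        )
                else:
                    refined.append((ci, res))
            pieces = refined
        entries: list[tuple[str, object, object]] = []
        boundary = sorted(
            {ci.lo for ci, _ in pieces} | {ci.hi for ci, _ in pieces}
        )
        for rho in boundary:
            if 0 < rho < L:
                entries.append(
                    ("point", rho, _root_at_edge_point(iph, edge, rho))
                )
        for ci, res in pieces:
            entries.append(("interval", ci, res))
        edge_results[edge] = entries
    sol = SolutionSet(S, node_results, edge_results)
    for edge, entries in edge_results.items():
        sol.merged[edge] = _merge_edge(iph, edge, entries, node_results)
    return sol
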