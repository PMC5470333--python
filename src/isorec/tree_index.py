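"""Preprocessed queries on a rooted species tree.

Provides lowest common ancestors (Euler tour + sparse table, O(1) query),
ancestor tests, exact distances, and the weighted level ancestor
``anc(p, d)`` via heavy-path decomposition with binary search over exact
rational node weights.  All queries are extended to implicit
:class:`~isorec.tree_model.TreePoint` arguments, including points on the
infinite edge above the root.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

from .tree_model import PhyloTree, TreeError, TreePoint

__all__ = ["TreeIndex", "TriangulationResult", "triangulate", "build_index"]


class TreeIndex:
    """Query structure over a rooted tree with positive rational lengths."""

    def __init__(self, tree: PhyloTree) -> None:
        if not tree.is_rooted:
            raise TreeError("TreeIndex requires a rooted tree")
        self.tree = tree
        order = tree.preorder()
        self.w: dict[int, Fraction] = {u: tree.depth(u) for u in order}

        # subtree sizes and heavy children; an edge (p, v) is heavy iff
        # size(v) >= size(p) / 2 (ties heavy); each node has at most one
        # heavy child because two children cannot both reach half.
        size: dict[int, int] = {}
        for u in reversed(order):
            size[u] = 1 + sum(size[v] for v in tree.children(u))
        self.size = size
        heavy: dict[int, Optional[int]] = {}
        for u in order:
            h = None
            for v in tree.children(u):
                if 2 * size[v] >= size[u] and (h is None or size[v] > size[h]):
                    h = v
            heavy[u] = h
        self.heavy = heavy

        # heavy paths: contiguous runs of heavy edges; isolated nodes form
        # length-0 paths.  For each node: its path id and position; for each
        # path: the head (highest node), node list and ascending weights.
        self.path_of: dict[int, int] = {}
        self.pos_in_path: dict[int, int] = {}
        self.path_nodes: list[list[int]] = []
        self.path_w: list[list[Fraction]] = []
        for u in order:
            p = tree.parent(u)
            if p is not None and heavy[p] == u:
                pid = self.path_of[p]
                self.path_of[u] = pid
                self.pos_in_path[u] = len(self.path_nodes[pid])
                self.path_nodes[pid].append(u)
                self.path_w[pid].append(self.w[u])
            else:
                pid = len(self.path_nodes)
                self.path_of[u] = pid
                self.pos_in_path[u] = 0
                self.path_nodes.append([u])
                self.path_w.append([self.w[u]])

        # Euler tour + sparse table for O(1) node-level lca
        self._first: dict[int, int] = {}
        euler: list[int] = []
        depth_i: list[int] = []
        stack: list[tuple[int, int, int]] = [(tree.root, 0, 0)]
        # iterative Euler tour
        idepth = {tree.root: 0}
        for u in order:
            p = tree.parent(u)
            if p is not None:
                idepth[u] = idepth[p] + 1
        parent = {u: tree.parent(u) for u in order}
        visit_stack: list[tuple[int, int]] = [(tree.root, 0)]
        children = {u: tree.children(u) for u in order}
        while visit_stack:
            u, ci = visit_stack.pop()
            if ci == 0:
                self._first[u] = len(euler)
            euler.append(u)
            depth_i.append(idepth[u])
            if ci < len(children[u]):
                visit_stack.append((u, ci + 1))
                visit_stack.append((children[u][ci], 0))
        self._euler = euler
        n = len(euler)
        logs = [0] * (n + 1)
        for i in range(2, n + 1):
            logs[i] = logs[i // 2] + 1
        self._logs = logs
        table = [list(range(n))]
        j = 1
        while (1 << j) <= n:
            prev = table[-1]
            cur = []
            for i in range(n - (1 << j) + 1):
                a, b = prev[i], prev[i + (1 << (j - 1))]
                cur.append(a if depth_i[a] <= depth_i[b] else b)
            table.append(cur)
            j += 1
        self._sparse = table
        self._depth_i = depth_i
        self.parent = parent

    # -- node-level queries --------------------------------------------------

    def lca_nodes(self, u: int, v: int) -> int:
        a, b = self._first[u], self._first[v]
        if a > b:
            a, b = b, a
        j = self._logs[b - a + 1]
        x = self._sparse[j][a]
        y = self._sparse[j][b - (1 << j) + 1]
        return self._euler[x] if self._depth_i[x] <= self._depth_i[y] else self._euler[y]

    def is_ancestor_nodes(self, u: int, v: int) -> bool:
        return self.lca_nodes(u, v) == u

    # -- point queries -------------------------------------------------------

    def point_depth(self, p: TreePoint) -> Fraction:
        """Weighted depth of a point; negative above the root."""
        return self.w[p.node] - p.above

    def anc(self, p: TreePoint, d) -> TreePoint:
        """The point exactly ``d`` above ``p`` toward the root.

        Walks at most O(log n) heavy paths and binary-searches the node
        weights inside the answering path.  Above the root the result is a
        point on the implicit infinite edge.
        """
        d = Fraction(d)
        if d < 0:
            raise TreeError("anc distance must be non-negative")
        target = self.point_depth(p) - d
        root = self.tree.root
        if target <= 0:
            return TreePoint(root, -target)
        u = p.node
        if self.w[u] < target:
            # p is above u (on the edge to the parent or higher): the target
            # depth is met inside that same climb.
            raise TreeError("non-canonical point")
        while True:
            pid = self.path_of[u]
            head = self.path_nodes[pid][0]
            if self.w[head] <= target:
                ws = self.path_w[pid]
                lo, hi = 0, self.pos_in_path[u]
                # highest node in [lo, hi] with w >= target
                while lo < hi:
                    mid = (lo + hi) // 2
                    if ws[mid] >= target:
                        hi = mid
                    else:
                        lo = mid + 1
                v = self.path_nodes[pid][lo]
                return TreePoint(v, self.w[v] - target)
            par = self.parent[head]
            if self.w[par] < target:
                # strictly inside the light edge above this path's head
                return TreePoint(head, self.w[head] - target)
            u = par

    def lca(self, p: TreePoint, q: TreePoint) -> TreePoint:
        """Lowest common ancestor of two (possibly implicit) points."""
        u, v = p.node, q.node
        if u == v:
            return p if p.above >= q.above else q
        m = self.lca_nodes(u, v)
        if m == u:
            return p  # p sits on the edge above u, hence on q's root path
        if m == v:
            return q
        return TreePoint(m, Fraction(0))

    def is_ancestor(self, p: TreePoint, q: TreePoint) -> bool:
        """True iff ``p`` lies on the path from ``q`` to the root, inclusive."""
        return self.lca(p, q) == p

    def dist(self, p: TreePoint, q: TreePoint) -> Fraction:
        """Distance from ancestor ``p`` down to descendant ``q``."""
        if not self.is_ancestor(p, q):
            raise TreeError("dist requires p to be an ancestor of q")
        return self.point_depth(q) - self.point_depth(p)

    # -- oracles (reference implementations for testing) ---------------------

    def naive_anc(self, p: TreePoint, d) -> TreePoint:
        """Edge-by-edge walk; reference for :meth:`anc`."""
        d = Fraction(d) + p.above
        u = p.node
        root = self.tree.root
        while u != root:
            par = self.parent[u]
            length = self.tree.edge_length(u, par)
            if d < length:
                return TreePoint(u, d)
            d -= length
            u = par
        return TreePoint(root, d)


def build_index(S: PhyloTree) -> TreeIndex:
    """Build the query structure for a rooted species tree."""
    return TreeIndex(S)


@dataclass(frozen=True)
class TriangulationResult:
    """Outcome of mapping a gene node from two mapped relatives."""

    status: str  # "resolved" | "undefined"
    point: Optional[TreePoint]
    x_u: TreePoint
    x_v: TreePoint


def triangulate(
    idx: TreeIndex, d_ux, d_vx, u_img: TreePoint, v_img: TreePoint
) -> TriangulationResult:
    """Map a gene node ``x`` lying on the path between ``u`` and ``v``.

    ``x_u = anc(u_img, d(u, x))`` and ``x_v = anc(v_img, d(v, x))``; if one
    is an ancestor of the other the descendant is the image of ``x`` (in any
    true history exactly one of the two candidates equals the image), else
    the triangulation is undefined.
    """
    x_u = idx.anc(u_img, d_ux)
    x_v = idx.anc(v_img, d_vx)
    if idx.is_ancestor(x_u, x_v):
        return TriangulationResult("resolved", x_v, x_u, x_v)
    if idx.is_ancestor(x_v, x_u):
        return TriangulationResult("resolved", x_u, x_u, x_v)
    return TriangulationResult("undefined", None, x_u, x_v)
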