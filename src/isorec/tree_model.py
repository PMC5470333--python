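"""Edge-weighted phylogenetic trees with exact rational branch lengths.

Trees may be rooted or unrooted.  All branch lengths are stored as
:class:`fractions.Fraction` and decimal Newick literals are parsed exactly,
because the reconciliation algorithms in this package test exact equalities
(distance checks, interval endpoints) that would be ill-posed under binary
floating point.

Node identity is an opaque integer id.  Leaves carry labels; internal labels
are optional and preserved through I/O.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Optional

__all__ = [
    "TreeError",
    "NewickError",
    "InvalidInputError",
    "PhyloTree",
    "TreePoint",
    "EdgePoint",
    "edge_point",
    "canonical_point",
    "LeafMap",
    "InputPartialHistory",
    "parse_newick",
    "write_newick",
    "format_length",
    "parse_leaf_map",
    "validate_input",
]


class TreeError(ValueError):
    """Base error for malformed trees or tree operations."""


class NewickError(TreeError):
    """Raised on malformed Newick input."""


class InvalidInputError(TreeError):
    """Raised when a reconciliation input violates its structural contract."""


# ---------------------------------------------------------------------------
# PhyloTree


class PhyloTree:
    """Connected acyclic graph with positive rational edge lengths.

    A tree is *rooted* when :attr:`root` is set; parent/child orientation and
    node depths are then derived from the root.  Unrooted trees are plain
    adjacency structures.
    """

    def __init__(self) -> None:
        self._labels: dict[int, Optional[str]] = {}
        self._adj: dict[int, dict[int, Fraction]] = {}
        self._next_id = 0
        self.root: Optional[int] = None
        self._cache: Optional[dict] = None

    # -- construction -------------------------------------------------------

    def add_node(self, label: Optional[str] = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self._labels[nid] = label
        self._adj[nid] = {}
        self._cache = None
        return nid

    def add_edge(self, u: int, v: int, length) -> None:
        length = Fraction(length)
        if u == v or v in self._adj[u]:
            raise TreeError(f"bad edge ({u},{v})")
        self._adj[u][v] = length
        self._adj[v][u] = length
        self._cache = None

    def set_root(self, node: Optional[int]) -> None:
        if node is not None and node not in self._adj:
            raise TreeError(f"unknown node {node}")
        self.root = node
        self._cache = None

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t._labels = dict(self._labels)
        t._adj = {u: dict(nb) for u, nb in self._adj.items()}
        t._next_id = self._next_id
        t.root = self.root
        return t

    # -- basic queries -------------------------------------------------------

    @property
    def is_rooted(self) -> bool:
        return self.root is not None

    def nodes(self) -> list[int]:
        return list(self._adj)

    def __len__(self) -> int:
        return len(self._adj)

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in self._adj for v in self._adj[u] if u < v]

    def neighbors(self, u: int) -> list[int]:
        return list(self._adj[u])

    def degree(self, u: int) -> int:
        return len(self._adj[u])

    def label(self, u: int) -> Optional[str]:
        return self._labels[u]

    def set_label(self, u: int, label: Optional[str]) -> None:
        self._labels[u] = label

    def node_by_label(self, label: str) -> Optional[int]:
        for u, lbl in self._labels.items():
            if lbl == label:
                return u
        return None

    def leaves(self) -> list[int]:
        if len(self._adj) == 1:
            return list(self._adj)
        out = []
        for u in self._adj:
            deg = len(self._adj[u])
            if self.is_rooted:
                if u == self.root:
                    continue
                if deg == 1:
                    out.append(u)
            elif deg == 1:
                out.append(u)
        # a rooted tree consisting of a root with no children
        if self.is_rooted and not out and len(self._adj) == 1:
            out = [self.root]
        return out

    def edge_length(self, u: int, v: int) -> Fraction:
        try:
            return self._adj[u][v]
        except KeyError:
            raise TreeError(f"no edge ({u},{v})") from None

    # -- rooted orientation --------------------------------------------------

    def _maps(self) -> dict:
        if self._cache is None:
            if self.root is None:
                raise TreeError("tree is unrooted")
            parent: dict[int, Optional[int]] = {self.root: None}
            depth: dict[int, Fraction] = {self.root: Fraction(0)}
            children: dict[int, list[int]] = {}
            order = [self.root]
            stack = [self.root]
            while stack:
                u = stack.pop()
                kids = [v for v in self._adj[u] if v != parent[u]]
                children[u] = kids
                for v in kids:
                    parent[v] = u
                    depth[v] = depth[u] + self._adj[u][v]
                    order.append(v)
                    stack.append(v)
            self._cache = {
                "parent": parent,
                "depth": depth,
                "children": children,
                "preorder": order,
            }
        return self._cache

    def parent(self, u: int) -> Optional[int]:
        return self._maps()["parent"][u]

    def children(self, u: int) -> list[int]:
        return self._maps()["children"][u]

    def depth(self, u: int) -> Fraction:
        return self._maps()["depth"][u]

    def preorder(self) -> list[int]:
        return list(self._maps()["preorder"])

    def subtree(self, u: int) -> list[int]:
        out = [u]
        stack = [u]
        ch = self._maps()["children"]
        while stack:
            x = stack.pop()
            for v in ch[x]:
                out.append(v)
                stack.append(v)
        return out

    # -- distances -----------------------------------------------------------

    def dist(self, u: int, v: int) -> Fraction:
        """Path length between two nodes (naive traversal)."""
        if u == v:
            return Fraction(0)
        prev = {u: None}
        stack = [u]
        while stack:
            x = stack.pop()
            for y in self._adj[x]:
                if y not in prev:
                    prev[y] = x
                    if y == v:
                        stack = []
                        break
                    stack.append(y)
        if v not in prev:
            raise TreeError("nodes not connected")
        d = Fraction(0)
        x = v
        while prev[x] is not None:
            d += self._adj[x][prev[x]]
            x = prev[x]
        return d

    def path(self, u: int, v: int) -> list[int]:
        prev = {u: None}
        queue = [u]
        for x in queue:
            for y in self._adj[x]:
                if y not in prev:
                    prev[y] = x
                    queue.append(y)
        out = [v]
        while prev[out[-1]] is not None:
            out.append(prev[out[-1]])
        return out[::-1]

    # -- surgery -------------------------------------------------------------

    def subdivide_edge(self, u: int, v: int, d, label: Optional[str] = None) -> int:
        """Split edge (u, v) at distance ``d`` from ``u`` by a new node."""
        d = Fraction(d)
        length = self.edge_length(u, v)
        if not (0 < d < length):
            raise TreeError(f"subdivision point {d} outside edge of length {length}")
        x = self.add_node(label)
        del self._adj[u][v]
        del self._adj[v][u]
        self.add_edge(u, x, d)
        self.add_edge(x, v, length - d)
        self._cache = None
        return x

    def bypass(self, x: int) -> None:
        """Replace degree-2 node ``x`` by a single edge of the same length."""
        nb = list(self._adj[x])
        if len(nb) != 2:
            raise TreeError(f"cannot bypass node {x} of degree {len(self._adj[x])}")
        u, v = nb
        length = self._adj[x][u] + self._adj[x][v]
        self.remove_node(x)
        self.add_edge(u, v, length)

    def remove_node(self, x: int) -> None:
        for y in list(self._adj[x]):
            del self._adj[y][x]
        del self._adj[x]
        del self._labels[x]
        if self.root == x:
            self.root = None
        self._cache = None

    def remove_edge(self, u: int, v: int) -> None:
        del self._adj[u][v]
        del self._adj[v][u]
        self._cache = None

    def min_leaf_label(self, u: int, avoid: Optional[int] = None) -> str:
        """Smallest leaf label reachable from ``u`` without passing ``avoid``."""
        best = None
        stack = [(u, avoid)]
        while stack:
            x, came = stack.pop()
            nbs = [y for y in self._adj[x] if y != came]
            if not nbs or (len(self._adj[x]) == 1 and x != u):
                lbl = self._labels[x]
                if lbl is not None and (best is None or lbl < best):
                    best = lbl
            for y in nbs:
                stack.append((y, x))
        if best is None:
            lbl = self._labels[u]
            best = lbl if lbl is not None else ""
        return best


# ---------------------------------------------------------------------------
# Points


@dataclass(frozen=True)
class TreePoint:
    """A point in a rooted tree: ``above`` units above ``node`` toward the root.

    ``above == 0`` denotes the node itself.  When ``node`` is the root,
    ``above`` may be arbitrarily large (the implicit infinite edge above the
    root).  Canonical points satisfy ``above < d(node, parent(node))`` for
    non-root nodes.
    """

    node: int
    above: Fraction = Fraction(0)

    def __post_init__(self):
        object.__setattr__(self, "above", Fraction(self.above))

    @property
    def is_node(self) -> bool:
        return self.above == 0


@dataclass(frozen=True)
class EdgePoint:
    """A point on an undirected edge, canonically oriented.

    Construct via :func:`edge_point`; ``pt(u, v, d)`` and
    ``pt(v, u, len - d)`` normalize to the same object and compare equal.
    """

    u: int
    v: int
    d: Fraction


def edge_point(u: int, v: int, d, length) -> EdgePoint:
    d = Fraction(d)
    length = Fraction(length)
    if not (0 <= d <= length):
        raise TreeError(f"point at {d} outside edge of length {length}")
    if v < u:
        u, v, d = v, u, length - d
    return EdgePoint(u, v, d)


def canonical_point(tree: PhyloTree, node: int, above) -> TreePoint:
    """Normalize a (node, above) pair by walking up, for a rooted tree."""
    above = Fraction(above)
    if above < 0:
        raise TreeError("negative offset")
    while node != tree.root:
        p = tree.parent(node)
        length = tree.edge_length(node, p)
        if above < length:
            break
        above -= length
        node = p
    return TreePoint(node, above)


# ---------------------------------------------------------------------------
# Newick I/O

_LABEL_RE = re.compile(r"[^,:;()\[\]\s]+")


def parse_newick(text: str, rooted: bool = True) -> PhyloTree:
    """Parse a Newick string with mandatory branch lengths.

    The top-level node carries no branch length.  With ``rooted=False`` the
    top-level node is only an anchor; a degree-2 anchor is merged away so
    that unrooted trees never contain degree-2 internal nodes from parsing.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError("missing terminating ';'")
    s = s[:-1].strip()
    tree = PhyloTree()
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(f"{msg} at position {pos}: ...{s[pos:pos + 20]!r}")

    def parse_label() -> Optional[str]:
        nonlocal pos
        m = _LABEL_RE.match(s, pos)
        if m:
            pos = m.end()
            return m.group(0)
        return None

    def parse_length() -> Optional[Fraction]:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            m = _LABEL_RE.match(s, pos)
            if not m:
                raise error("missing branch length after ':'")
            token = m.group(0)
            pos = m.end()
            try:
                val = Fraction(token)
            except (ValueError, ZeroDivisionError):
                raise error(f"unparseable branch length {token!r}") from None
            return val
        return None

    def parse_subtree(top: bool) -> int:
        nonlocal pos
        if pos < len(s) and s[pos] == "(":
            pos += 1
            kids = []
            while True:
                kids.append(parse_subtree(False))
                if pos < len(s) and s[pos] == ",":
                    pos += 1
                    continue
                if pos < len(s) and s[pos] == ")":
                    pos += 1
                    break
                raise error("expected ',' or ')'")
            label = parse_label()
            node = tree.add_node(label)
            for child, length in kids:
                if length is None:
                    raise NewickError(
                        f"missing branch length on edge above "
                        f"{tree.label(child) or 'internal node'}"
                    )
                if length <= 0:
                    raise NewickError(
                        f"non-positive length {length} on edge above "
                        f"{tree.label(child) or 'internal node'}"
                    )
                tree.add_edge(node, child, length)
        else:
            label = parse_label()
            if label is None:
                raise error("expected label or '('")
            node = tree.add_node(label)
        length = parse_length()
        if top:
            if length is not None:
                raise NewickError("branch length not allowed on the top-level node")
            return node
        return (node, length)

    top = parse_subtree(True)
    if pos != len(s):
        raise error("trailing characters")
    if rooted:
        tree.set_root(top)
    else:
        tree.root = None
        if tree.degree(top) == 2 and len(tree) > 2:
            tree.bypass(top)
        elif tree.degree(top) == 2:
            tree.bypass(top)
    return tree


def format_length(x: Fraction) -> str:
    """Render a rational exactly: decimal when the denominator is 2^a·5^b,
    otherwise as ``p/q``."""
    x = Fraction(x)
    den = x.denominator
    a = b = 0
    while den % 2 == 0:
        den //= 2
        a += 1
    while den % 5 == 0:
        den //= 5
        b += 1
    if den != 1:
        return f"{x.numerator}/{x.denominator}"
    k = max(a, b)
    if k == 0:
        return str(x.numerator)
    scaled = x.numerator * 10**k // x.denominator
    sign = "-" if scaled < 0 else ""
    scaled = abs(scaled)
    digits = str(scaled).rjust(k + 1, "0")
    whole, frac = digits[:-k], digits[-k:]
    frac = frac.rstrip("0")
    return f"{sign}{whole}.{frac}" if frac else f"{sign}{whole}"


def write_newick(tree: PhyloTree) -> str:
    """Serialize with children in deterministic smallest-leaf-label order.

    Unrooted trees are written anchored at the internal neighbor of the
    lexicographically smallest leaf (a top-level multifurcation); a two-node
    unrooted tree is written as ``(B:len)A;``.
    """
    if len(tree) == 1:
        (only,) = tree.nodes()
        return f"{tree.label(only) or ''};"

    def emit(u: int, came: Optional[int]) -> str:
        kids = [v for v in tree.neighbors(u) if v != came]
        lbl = tree.label(u) or ""
        if not kids:
            return lbl
        parts = sorted(
            ((tree.min_leaf_label(v, avoid=u), v) for v in kids), key=lambda p: p[0]
        )
        inner = ",".join(
            f"{emit(v, u)}:{format_length(tree.edge_length(u, v))}" for _, v in parts
        )
        return f"({inner}){lbl}"

    if tree.is_rooted:
        return emit(tree.root, None) + ";"
    # unrooted: pick anchor near the smallest leaf
    leaves = sorted(tree.leaves(), key=lambda u: tree.label(u) or "")
    small = leaves[0]
    if len(tree) == 2:
        other = tree.neighbors(small)[0]
        return (
            f"({tree.label(other) or ''}:"
            f"{format_length(tree.edge_length(small, other))})"
            f"{tree.label(small) or ''};"
        )
    anchor = tree.neighbors(small)[0]
    return emit(anchor, None) + ";"


# ---------------------------------------------------------------------------
# Leaf map and input validation


@dataclass(frozen=True)
class LeafMap:
    """Total map from gene-tree leaf labels to species-tree leaf labels."""

    mapping: tuple[tuple[str, str], ...]

    @staticmethod
    def from_dict(d: dict) -> "LeafMap":
        return LeafMap(tuple(sorted(d.items())))

    def as_dict(self) -> dict[str, str]:
        return dict(self.mapping)

    def __getitem__(self, gene_label: str) -> str:
        return self.as_dict()[gene_label]

    def ids(self, gene: PhyloTree, species: PhyloTree) -> dict[int, int]:
        """Resolve the label map to node ids for a concrete tree pair."""
        d = self.as_dict()
        out = {}
        for leaf in gene.leaves():
            lbl = gene.label(leaf)
            out[leaf] = species.node_by_label(d[lbl])
        return out


@dataclass(frozen=True)
class InputPartialHistory:
    """A gene tree, a species tree (each rooted or unrooted) and a leaf map."""

    gene: PhyloTree
    species: PhyloTree
    leaf_map: LeafMap


def parse_leaf_map(table, gene: PhyloTree, species: PhyloTree) -> LeafMap:
    """Parse a two-column TSV (``gene<TAB>species``, optional header).

    All validation problems are collected and reported together.
    """
    if isinstance(table, str):
        lines = table.splitlines()
    else:
        lines = [str(x) for x in table]
    rows = []
    for ln in lines:
        ln = ln.strip()
        if not ln:
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise InvalidInputError(f"expected two tab-separated columns: {ln!r}")
        rows.append((parts[0], parts[1]))
    if rows and rows[0] == ("gene", "species"):
        rows = rows[1:]

    errors = []
    gene_leaves = {gene.label(u): u for u in gene.leaves()}
    species_leaves = {species.label(u) for u in species.leaves()}
    seen = {}
    for g, sp in rows:
        if g in seen:
            errors.append(f"duplicate row for gene leaf {g}")
            continue
        seen[g] = sp
        if g not in gene_leaves:
            if gene.node_by_label(g) is not None:
                errors.append(f"gene label {g} is not a leaf")
            else:
                errors.append(f"unknown gene leaf {g}")
        if sp not in species_leaves:
            if species.node_by_label(sp) is not None:
                errors.append(f"gene leaf {g} maps to non-leaf {sp}")
            else:
                errors.append(f"unknown species leaf {sp}")
    for lbl in gene_leaves:
        if lbl not in seen:
            errors.append(f"unmapped gene leaf {lbl}")
    if errors:
        raise InvalidInputError("; ".join(sorted(errors)))
    return LeafMap.from_dict(seen)


def validate_input(iph: InputPartialHistory) -> list[str]:
    """Check the structural contract on reconciliation inputs.

    Positive lengths; rooted internal nodes (and the root) have >= 2
    children; unrooted internal nodes have >= 3 neighbors; the leaf map is a
    total function onto species leaves.  Violations are returned as data,
    not raised.
    """
    out: list[str] = []

    def check_tree(t: PhyloTree, name: str) -> None:
        for u, v in t.edges():
            if t.edge_length(u, v) <= 0:
                out.append(f"{name}: non-positive length on edge ({u},{v})")
        if len(t) == 1:
            return
        if t.is_rooted:
            for u in t.nodes():
                kids = t.degree(u) - (0 if u == t.root else 1)
                if kids == 1:
                    out.append(
                        f"{name}: internal node {t.label(u) or u} has a single child"
                    )
        else:
            for u in t.nodes():
                if t.degree(u) == 2:
                    out.append(
                        f"{name}: unrooted internal node {t.label(u) or u} "
                        f"has only two neighbors"
                    )

    check_tree(iph.gene, "gene tree")
    check_tree(iph.species, "species tree")

    gene_leaves = {iph.gene.label(u) for u in iph.gene.leaves()}
    species_leaves = {iph.species.label(u) for u in iph.species.leaves()}
    m = iph.leaf_map.as_dict()
    for g in sorted(gene_leaves):
        if g not in m:
            out.append(f"leaf map: unmapped gene leaf {g}")
        elif m[g] not in species_leaves:
            out.append(f"leaf map: gene leaf {g} maps to non-leaf {m[g]}")
    for g in sorted(m):
        if g not in gene_leaves:
            out.append(f"leaf map: unknown gene leaf {g}")
    return out
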