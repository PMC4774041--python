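"""Molecular trees and the order relations behind the canonical normal form.

A contracted molecule is stored as a rooted ordered tree of :class:`Node`
objects.  Three nested total preorders drive canonicalization:

* the *structural* order ``>_s`` compares labels, then child lists
  lexicographically (a longer child list with an equal prefix is greater);
* the *multigraph* order ``>_m`` refines ``>_s`` by the sequence of edge
  multiplicities in breadth-first order (a merge bond counts as 2);
* the *assigned* order ``>_C`` refines ``>_m`` by the carbon position lists of
  benzene nodes, decided at the highest BFS index where they differ.

The canonical representative of a molecule is *center-rooted* (root = center
of a longest path, or an endpoint of the center edge with the heavier half
below) and *left-heavy* (siblings non-increasing under ``>=_m``).  Where
``>=_m`` ties, siblings are ordered by a deterministic deep tie-break that
also looks at parent-edge multiplicities; the tie-break never changes which
trees are emitted, only their internal child order.
"""

from __future__ import annotations

from collections import deque
from typing import Iterator, Optional

from .formula import BENZENE, LabelTable


class Node:
    """One contracted tree node.

    ``mult`` is the multiplicity of the edge to the parent (0 at the root);
    a *merge bond* is an edge of multiplicity 2 between two benzene nodes.
    """

    __slots__ = (
        "label", "rank", "val", "mult", "children", "parent",
        "index", "_skey", "_mkey", "_dkey",
    )

    def __init__(self, label: str, table: LabelTable, mult: int = 1):
        self.label = label
        self.rank = table.rank(label)
        self.val = table.valence(label)
        self.mult = mult
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.index = -1
        self._skey = self._mkey = self._dkey = None

    # -- construction ---------------------------------------------------
    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def is_merge_edge(self) -> bool:
        """True when the edge to the parent is a merge bond."""
        return (
            self.parent is not None
            and self.mult == 2
            and self.label == BENZENE
            and self.parent.label == BENZENE
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label}, mult={self.mult}, #ch={len(self.children)})"


# ---------------------------------------------------------------------------
# traversal and keys
# ---------------------------------------------------------------------------

def bfs_nodes(root: Node) -> list[Node]:
    """Level-order node sequence respecting child order."""
    out = [root]
    q = deque([root])
    while q:
        v = q.popleft()
        for c in v.children:
            out.append(c)
            q.append(c)
    return out


def bfs_sequence(root: Node) -> tuple[list[Node], list[tuple[Node, Node]]]:
    """BFS node sequence and edge sequence (edges follow child-node order)."""
    nodes = bfs_nodes(root)
    return nodes, [(v.parent, v) for v in nodes[1:]]


def number_bfs(root: Node) -> list[Node]:
    """Assign 1-based BFS indices (``index(v, T)``) and return the sequence."""
    seq = bfs_nodes(root)
    for i, v in enumerate(seq):
        v.index = i + 1
    return seq


def s_key(node: Node):
    """Hashable key whose tuple order realizes the structural order ``>_s``."""
    k = node._skey
    if k is None:
        k = (node.rank, tuple(s_key(c) for c in node.children))
        node._skey = k
    return k


def bfs_mult_seq(node: Node) -> tuple[int, ...]:
    """Edge multiplicities of the subtree in BFS edge order."""
    return tuple(v.mult for v in bfs_nodes(node)[1:])


def m_key(node: Node):
    """Key realizing the multigraph order ``>_m`` (parent edge excluded)."""
    k = node._mkey
    if k is None:
        k = (s_key(node), bfs_mult_seq(node))
        node._mkey = k
    return k


def deep_key(node: Node):
    """Fully recursive serialization: label, parent-edge mult, ordered children.

    Equal deep keys mean identical ordered multiplicity-labeled trees; used for
    deduplication and for breaking ``=_m`` ties deterministically.
    """
    k = node._dkey
    if k is None:
        k = (node.rank, node.mult, tuple(deep_key(c) for c in node.children))
        node._dkey = k
    return k


def sibling_sort_key(node: Node):
    return (m_key(node), node.mult, deep_key(node))


def clear_keys(root: Node) -> None:
    for v in bfs_nodes(root):
        v._skey = v._mkey = v._dkey = None


def canonicalize(root: Node) -> Node:
    """Sort every child list to be left-heavy (``>=_m`` desc, deep tie-break)."""
    def rec(v: Node) -> None:
        for c in v.children:
            rec(c)
        v.children.sort(key=sibling_sort_key, reverse=True)
        v._skey = v._mkey = v._dkey = None
    rec(root)
    number_bfs(root)
    return root


def clone(root: Node, table: LabelTable) -> Node:
    def rec(v: Node) -> Node:
        n = Node(v.label, table, v.mult)
        for c in v.children:
            n.add(rec(c))
        return n
    r = rec(root)
    r.mult = 0
    number_bfs(r)
    return r


# ---------------------------------------------------------------------------
# comparison operations (spec surface; -1 / 0 / +1)
# ---------------------------------------------------------------------------

def _cmp(a, b) -> int:
    return (a > b) - (a < b)


def compare_s(u: Node, v: Node) -> int:
    return _cmp(s_key(u), s_key(v))


def compare_m(u: Node, v: Node) -> int:
    return _cmp(m_key(u), m_key(v))


def subtree_benzenes(node: Node) -> list[Node]:
    return [v for v in bfs_nodes(node) if v.label == BENZENE]


def compare_assigned(u: Node, v: Node, cmap) -> int:
    """The assigned order ``>_C`` between two subtrees of one tree.

    Requires ``u`` and ``v`` to carry carbon position lists for every benzene
    node in ``cmap``.  The multigraph order decides first; among ``=_m`` trees
    the benzene node with the *highest* BFS index whose position lists differ
    decides.
    """
    c = compare_m(u, v)
    if c:
        return c
    bu, bv = subtree_benzenes(u), subtree_benzenes(v)
    for a, b in zip(reversed(bu), reversed(bv)):
        c = _cmp(cmap[a], cmap[b])
        if c:
            return c
    return 0


# ---------------------------------------------------------------------------
# center and rooting predicates
# ---------------------------------------------------------------------------

def _neighbors(v: Node) -> Iterator[Node]:
    if v.parent is not None:
        yield v.parent
    yield from v.children


def _farthest(start: Node) -> tuple[Node, dict]:
    prev = {start: None}
    last = start
    q = deque([start])
    while q:
        v = q.popleft()
        last = v
        for w in _neighbors(v):
            if w not in prev:
                prev[w] = v
                q.append(w)
    return last, prev


def longest_path_center(root: Node) -> tuple[Node, ...]:
    """Center of a longest path: a 1-tuple (node) or 2-tuple (edge).

    All longest paths of a tree share their center, so any diametral path
    serves.
    """
    u, _ = _farthest(root)
    w, prev = _farthest(u)
    path = []
    v: Optional[Node] = w
    while v is not None:
        path.append(v)
        v = prev[v]
    n = len(path)
    if n % 2:
        return (path[n // 2],)
    return (path[n // 2 - 1], path[n // 2])


def is_center_rooted(root: Node) -> bool:
    return root in longest_path_center(root)


def is_left_heavy(root: Node) -> bool:
    for v in bfs_nodes(root):
        for a, b in zip(v.children, v.children[1:]):
            if m_key(a) < m_key(b):
                return False
    return True


# ---------------------------------------------------------------------------
# re-rooted subtrees: T^sub(v1, v2)
# ---------------------------------------------------------------------------
# A re-rooted component is materialized as a lightweight *view*: a tuple
# (original node, multiplicity of the edge to the view parent, sorted child
# views).  Views keep references to the original nodes so carbon position
# lists can still be looked up on them.

View = tuple  # (Node, int, tuple[View, ...])


def view_s_key(v: View):
    return (v[0].rank, tuple(view_s_key(c) for c in v[2]))


def _view_bfs(v: View) -> list[View]:
    out = [v]
    q = deque([v])
    while q:
        x = q.popleft()
        for c in x[2]:
            out.append(c)
            q.append(c)
    return out


def view_m_key(v: View):
    return (view_s_key(v), tuple(x[1] for x in _view_bfs(v)[1:]))


def view_deep_key(v: View):
    return (v[0].rank, v[1], tuple(view_deep_key(c) for c in v[2]))


def _view_sort_key(v: View):
    return (view_m_key(v), v[1], view_deep_key(v))


def away_view(x: Node, y: Node | None) -> View:
    """Left-heavy view of the component containing ``x`` once edge (x,y) is cut.

    With ``y is None`` the whole tree is re-rooted at ``x``.  Equals the plain
    subtree of ``x`` when ``x`` is a child of ``y``.
    """
    def build(node: Node, came_from: Node | None, mult: int) -> View:
        kids = []
        for c in node.children:
            if c is not came_from:
                kids.append(build(c, node, c.mult))
        p = node.parent
        if p is not None and p is not came_from:
            kids.append(build(p, node, node.mult))
        kids.sort(key=_view_sort_key, reverse=True)
        return (node, mult, tuple(kids))

    return build(x, y, 0)


def subtree_away(x: Node, y: Node, table: LabelTable) -> Node:
    """``T^sub(x, y)`` as a fresh left-heavy :class:`Node` tree."""
    if y.parent is not x and x.parent is not y:
        raise ValueError("subtree_away requires an edge of the tree")
    def to_node(v: View) -> Node:
        n = Node(v[0].label, table, v[1] or 1)
        for c in v[2]:
            n.add(to_node(c))
        return n
    root = to_node(away_view(x, y))
    root.mult = 0
    number_bfs(root)
    return root


def view_benzenes(v: View) -> list[Node]:
    return [x[0] for x in _view_bfs(v) if x[0].label == BENZENE]


# ---------------------------------------------------------------------------
# paths and symmetric paths
# ---------------------------------------------------------------------------

def tree_path(a: Node, b: Node) -> list[Node]:
    """Unique path between two nodes (inclusive)."""
    seen = {}
    v: Optional[Node] = a
    while v is not None:
        seen[v] = True
        v = v.parent
    chain_b = []
    v = b
    while v not in seen:
        chain_b.append(v)
        v = v.parent
    apex = v
    out = []
    v = a
    while v is not apex:
        out.append(v)
        v = v.parent
    out.append(apex)
    out.extend(reversed(chain_b))
    return out


def assigned_view_key(v: View, cmap):
    """Canonical key of a view including carbon position lists (``=_C``)."""
    kids = tuple(sorted((assigned_view_key(c, cmap) for c in v[2]), reverse=True))
    own = cmap.get(v[0], ()) if v[0].label == BENZENE else ()
    return (v[0].rank, v[1], own, kids)


def _chain_child(v: View, nxt: Node) -> View:
    for c in v[2]:
        if c[0] is nxt:
            return c
    raise AssertionError("path node missing from view")


def _sym_match(va: View, vb: View, chain_a: list[Node], chain_b: list[Node],
               i: int, cmap) -> bool:
    """Chain-respecting ``=_m`` + inner-``C``-equality match of two path halves."""
    na, nb = chain_a[i], chain_b[i]
    if na.rank != nb.rank or va[1] != vb[1]:
        return False
    if i == len(chain_a) - 1:
        # endpoint subtrees: structure+multiplicity equality only; their
        # position lists are compared by the ordering constraint instead
        return view_m_key(va) == view_m_key(vb)
    if na.label == BENZENE and cmap.get(na) != cmap.get(nb):
        return False
    ka = _chain_child(va, chain_a[i + 1])
    kb = _chain_child(vb, chain_b[i + 1])
    if ka[1] != kb[1] or view_m_key(ka) != view_m_key(kb):
        return False
    others_a = sorted(assigned_view_key(c, cmap) for c in va[2] if c is not ka)
    others_b = sorted(assigned_view_key(c, cmap) for c in vb[2] if c is not kb)
    if others_a != others_b:
        return False
    return _sym_match(ka, kb, chain_a, chain_b, i + 1, cmap)


class SymmetricPair:
    """A node pair whose connecting path can be symmetric.

    ``left``/``right`` are oriented per the normal-form rule ("left of"); the
    half views and chains are cached so that, per carbon-position assignment,
    only the C-dependent part of the symmetry test reruns.
    """

    __slots__ = ("left", "right", "next_l", "next_r", "chain_l", "chain_r",
                 "view_l", "view_r", "merge_pair")

    def __init__(self, left, right, next_l, next_r, chain_l, chain_r,
                 view_l, view_r, merge_pair):
        self.left = left
        self.right = right
        self.next_l = next_l    # second node on the path starting at left
        self.next_r = next_r    # second node on the path starting at right
        self.chain_l = chain_l
        self.chain_r = chain_r
        self.view_l = view_l
        self.view_r = view_r
        self.merge_pair = merge_pair

    def is_symmetric(self, cmap) -> bool:
        return _sym_match(self.view_l, self.view_r, self.chain_l, self.chain_r,
                          0, cmap)


def _subtree_sizes(root: Node) -> dict[Node, int]:
    sizes: dict[Node, int] = {}
    for v in reversed(bfs_nodes(root)):
        sizes[v] = 1 + sum(sizes[c] for c in v.children)
    return sizes


def _side_size(x: Node, y: Node, sizes: dict[Node, int], total: int) -> int:
    """Nodes in the component containing ``x`` once edge (x, y) is cut."""
    if x.parent is y:
        return sizes[x]
    return total - sizes[y]


class _PairContext:
    """Per-tree caches for candidate detection: subtree sizes, re-rooted
    views per directed edge, and their multigraph keys."""

    def __init__(self, root: Node):
        self.root = root
        self.sizes = _subtree_sizes(root)
        self.total = self.sizes[root]
        self._views: dict[tuple[int, int], View] = {}
        self._keys: dict[tuple[int, int], tuple] = {}

    def view(self, x: Node, y: Node) -> View:
        key = (id(x), id(y))
        v = self._views.get(key)
        if v is None:
            v = away_view(x, y)
            self._views[key] = v
        return v

    def mkey(self, x: Node, y: Node):
        key = (id(x), id(y))
        k = self._keys.get(key)
        if k is None:
            k = view_m_key(self.view(x, y))
            self._keys[key] = k
        return k


def _pair_candidate(root: Node, a: Node, b: Node,
                    ctx: _PairContext | None = None) -> SymmetricPair | None:
    p = tree_path(a, b)
    n = len(p)
    if n < 2:
        return None
    m = n // 2
    if ctx is None:
        ctx = _PairContext(root)
    # mirror-equal halves must at least match in size; this kills nearly all
    # ancestor-descendant pairs without building re-rooted views
    if _side_size(p[m - 1], p[m], ctx.sizes, ctx.total) != \
            _side_size(p[n - m], p[n - m - 1], ctx.sizes, ctx.total):
        return None
    if ctx.mkey(p[m - 1], p[m]) != ctx.mkey(p[n - m], p[n - m - 1]):
        return None
    v1 = ctx.view(p[m - 1], p[m])
    v2 = ctx.view(p[n - m], p[n - m - 1])
    # orientation: a is left of b when the half-point on b's side is the
    # root, and vice versa; otherwise the smaller BFS index is left
    if p[n - m] is root:
        left, right = a, b
    elif p[m - 1] is root:
        left, right = b, a
    elif a.index < b.index:
        left, right = a, b
    else:
        left, right = b, a
    if left is a:
        next_l, next_r = p[1], p[n - 2]
        chain_l = [p[i] for i in range(m - 1, -1, -1)]
        chain_r = [p[i] for i in range(n - m, n)]
        view_l, view_r = v1, v2
    else:
        next_l, next_r = p[n - 2], p[1]
        chain_l = [p[i] for i in range(n - m, n)]
        chain_r = [p[i] for i in range(m - 1, -1, -1)]
        view_l, view_r = v2, v1
    merge_pair = (
        n == 2 and (a.parent is b and a.is_merge_edge()
                    or b.parent is a and b.is_merge_edge())
    )
    return SymmetricPair(left, right, next_l, next_r, chain_l, chain_r,
                         view_l, view_r, merge_pair)


def symmetric_pair_candidates(root: Node) -> list[SymmetricPair]:
    """All node pairs passing the C-independent half of the symmetry test.

    Pairs whose endpoint subtrees contain no benzene node are dropped: the
    ordering constraint they would impose compares empty position-list
    sequences and can never fail.
    """
    nodes = bfs_nodes(root)
    has_benz: dict[Node, bool] = {}
    for v in reversed(nodes):
        has_benz[v] = v.label == BENZENE or any(has_benz[c] for c in v.children)
    ctx = _PairContext(root)
    out = []
    for i, a in enumerate(nodes):
        if not has_benz[a]:
            continue
        for b in nodes[i + 1:]:
            if not has_benz[b]:
                continue
            cand = _pair_candidate(root, a, b, ctx)
            if cand is not None:
                out.append(cand)
    return out


def is_symmetric_path(root: Node, u: Node, w: Node, cmap=None) -> bool:
    """Whether the path from ``u`` to ``w`` is a symmetric path."""
    cand = _pair_candidate(root, u, w)
    if cand is None:
        return False
    return cand.is_symmetric(cmap or {})


def left_of(root: Node, u: Node, w: Node) -> bool:
    """Orientation of a symmetric path: is ``u`` the left endpoint?"""
    cand = _pair_candidate(root, u, w)
    if cand is None:
        raise ValueError("nodes are not endpoints of a symmetric-path candidate")
    return cand.left is u
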