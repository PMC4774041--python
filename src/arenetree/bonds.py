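"""Bond-multiplicity and merge-bond assignment on canonical skeletons.

For every skeleton this stage chooses ``n_n`` benzene-benzene edges as merge
bonds (a matching: each benzene node joins at most one merge bond, so fused
chains longer than naphthalene never form) and distributes the remaining
``E - n_n`` multiplicity increments over edges not touching a benzene node
(ring carbons bind substituents by single bonds only).  Multiplicities are
capped at 3 and weighted degrees at the valence; unused valence becomes
implicit hydrogen.

Every raw assignment is re-canonicalized (left-heavy re-sort; re-rooting is
never needed because a multiplicity flip across a tied center edge is instead
discarded, its mirror assignment surviving) and de-duplicated by the full
serialization key, so exactly one representative per multigraph-isomorphism
class is emitted, still satisfying the center-rooted / left-heavy conditions.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterator

from .formula import BENZENE, LabelTable
from .mtree import (
    Node, away_view, bfs_nodes, canonicalize, deep_key, longest_path_center,
    m_key, view_m_key,
)


def _distributions(eligible: list[Node], total: int,
                   slack: dict[Node, int]) -> Iterator[tuple[int, ...]]:
    """Increment vectors over the eligible edges, capacity-pruned.

    ``slack[v]`` is the valence room left at node v after the base (single /
    merge) multiplicities; an increment on an edge consumes one unit at both
    endpoints.  Per-edge increments are capped at 2 (triple bonds at most).
    """
    n = len(eligible)
    out: list[int] = [0] * n

    def rec(i: int, rem: int) -> Iterator[tuple[int, ...]]:
        if rem == 0:
            yield tuple(out[:i]) + (0,) * (n - i)
            return
        if i == n or rem > 2 * (n - i):
            return
        v = eligible[i]
        p = v.parent
        for k in range(min(2, rem, slack[v], slack[p]) + 1):
            out[i] = k
            slack[v] -= k
            slack[p] -= k
            yield from rec(i + 1, rem - k)
            slack[v] += k
            slack[p] += k
        out[i] = 0

    yield from rec(0, total)


def _rebuild(root: Node, mult: dict[Node, int], table: LabelTable) -> Node:
    def rec(v: Node) -> Node:
        n = Node(v.label, table, mult.get(v, 1))
        for c in v.children:
            n.add(rec(c))
        return n
    r = rec(root)
    r.mult = 0
    return r


def enumerate_bond_assignments(
    skel: Node, n_n: int, increments: int, table: LabelTable
) -> Iterator[Node]:
    """Stream canonical multiplicity assignments of one skeleton.

    ``increments`` is the total surplus E; ``n_n`` of it is spent on merge
    bonds.  The empty stream means the skeleton admits no valid assignment.
    """
    nodes = bfs_nodes(skel)
    edges = nodes[1:]
    bb = [v for v in edges if v.label == BENZENE and v.parent.label == BENZENE]
    eligible = [v for v in edges
                if v.label != BENZENE and v.parent.label != BENZENE]
    extra = increments - n_n
    if extra < 0 or len(bb) < n_n:
        return
    seen: set = set()
    for merge in combinations(bb, n_n):
        endpoints: set[Node] = set()
        ok = True
        for v in merge:
            if v in endpoints or v.parent in endpoints:
                ok = False
                break
            endpoints.add(v)
            endpoints.add(v.parent)
        if not ok:
            continue
        base = {v: 1 for v in edges}
        for v in merge:
            base[v] = 2
        slack: dict[Node, int] = {}
        feasible = True
        for v in nodes:
            wdeg = sum(base[c] for c in v.children)
            if v.parent is not None:
                wdeg += base[v]
            slack[v] = v.val - wdeg
            if slack[v] < 0:
                feasible = False
        if not feasible:
            continue
        for incs in _distributions(eligible, extra, slack):
            mult = dict(base)
            for v, k in zip(eligible, incs):
                mult[v] = 1 + k
            t = _rebuild(skel, mult, table)
            canonicalize(t)
            if not _rooting_canonical(t):
                continue
            key = deep_key(t)
            if key in seen:
                continue
            seen.add(key)
            yield t


def _rooting_canonical(root: Node) -> bool:
    center = longest_path_center(root)
    if len(center) == 1:
        return center[0] is root
    if root not in center:
        return False
    v = center[0] if center[1] is root else center[1]
    return m_key(v) >= view_m_key(away_view(root, v))
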