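"""Carbon-position assignment: turning multiplicity-assigned trees into
normal trees.

Every benzene node ``v`` carries an *adjacent node list* ``A_v`` -- its
neighbors grouped by equivalence of the subtrees hanging away from ``v``
(merge-bond neighbors always form singleton groups), groups ordered by size
then by the BFS index of their first member -- and a *carbon position list*
``C_v`` giving the ring carbons (1..6) each group binds, ascending within a
group.  For a fused pair the two ring lists induce an 8-position naphthalene
list (parent-ring carbons 3..6 map to 1..4, child-ring carbons 3..6 to 5..8;
the shared carbons are 1,2 in both rings, identified anti-parallel).

The assignment sweeps benzene nodes in reverse BFS order (an adjacent node
list depends on the position lists of descendant benzene nodes).  Candidate
lists are pruned by the ring-symmetry conditions:

* condition 4: ``C_v`` minimal under the dihedral group of the hexagon, for
  every benzene node not merge-bonded to its parent;
* condition 5: at a merge bond incident to the root, the naphthalene list is
  minimal under the order-4 naphthalene group when the two halves are
  equivalent, else the child list respects the long-axis reflection whenever
  the parent list is fixed by it;
* condition 6: across every symmetric path whose endpoints are not
  merge-bonded, the left subtree dominates under the assigned order.

Trees with no symmetric-path candidates and no root merge bond factor into
independent per-ring choices; their assignment count is a plain product.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Iterator, NamedTuple

from .formula import BENZENE, LabelTable
from .mtree import (
    Node, assigned_view_key, away_view, bfs_nodes, m_key,
    subtree_benzenes, symmetric_pair_candidates, view_benzenes, view_m_key,
)


def _perm_group_b() -> tuple[tuple[int, ...], ...]:
    perms = []
    for k in range(6):
        perms.append(tuple([0] + [((i + k) % 6) + 1 for i in range(6)]))
        perms.append(tuple([0] + [((k - i) % 6) + 1 for i in range(6)]))
    return tuple(dict.fromkeys(perms))


#: the 12 dihedral automorphisms of the benzene positions 1..6 (index 0 unused)
AUT_B = _perm_group_b()

#: long-axis reflection of a merge-bonded ring in its own coordinates
PHI_REF = (0, 2, 1, 6, 5, 4, 3)

#: non-identity automorphisms of the naphthalene positions 1..8
AUT_N = (
    (0, 5, 6, 7, 8, 1, 2, 3, 4),  # rotation by pi
    (0, 4, 3, 2, 1, 8, 7, 6, 5),  # reflection mapping each ring to itself
    (0, 8, 7, 6, 5, 4, 3, 2, 1),  # their composition (swaps the rings)
)

#: root shortcut lists for large first groups (sizes (|A[1]|, |A[2]|))
ROOT_SHORTCUT_TABLE: dict[tuple[int, int], tuple] = {
    (3, 0): (((1, 2, 3),), ((1, 2, 4),), ((1, 3, 5),)),
    (3, 3): (((1, 2, 3), (4, 5, 6)), ((1, 2, 4), (3, 5, 6)),
             ((1, 3, 5), (2, 4, 6))),
    (4, 0): (((1, 2, 3, 4),), ((1, 2, 3, 5),), ((1, 2, 4, 5),)),
    (5, 0): (((1, 2, 3, 4, 5),),),
    (6, 0): (((1, 2, 3, 4, 5, 6),),),
}

_ADJ_PAIRS = ((1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (1, 6))


def root_shortcut_lists(sizes: tuple[int, int]) -> tuple:
    """Carbon position lists for a root benzene with ``|A[1]| >= 3``."""
    try:
        return ROOT_SHORTCUT_TABLE[sizes]
    except KeyError:
        raise ValueError(f"no shortcut for group sizes {sizes}") from None


def apply_perm(perm: tuple[int, ...], cpl: tuple) -> tuple:
    """Image of a position list under a ring automorphism, each group re-sorted."""
    return tuple(tuple(sorted(perm[p] for p in grp)) for grp in cpl)


def check_condition4(cpl: tuple) -> bool:
    """Is the list minimal in its dihedral orbit?"""
    return all(apply_perm(perm, cpl) >= cpl for perm in AUT_B[1:])


def to_naphthalene_positions(c_parent: tuple, c_child: tuple) -> tuple:
    """Naphthalene list from the two ring lists of an equivalent-halves pair.

    Both lists must start with the merge group ``(1, 2)``.  Ring positions
    3..6 of the parent map to naphthalene 1..4, those of the child to 5..8;
    corresponding substituent groups of the two rings coincide (the halves
    are equivalent) and are united position-wise.
    """
    if not (c_parent and c_child and c_parent[0] == (1, 2) and c_child[0] == (1, 2)):
        raise ValueError("both rings must carry the merge bond at positions (1, 2)")
    if len(c_parent) != len(c_child):
        raise ValueError("ring lists of an equivalent-halves pair must align")
    out = []
    for gp, gc in zip(c_parent[1:], c_child[1:]):
        out.append(tuple(sorted([p - 2 for p in gp] + [p + 2 for p in gc])))
    return tuple(out)


class Assignment(NamedTuple):
    """One normal tree: the tree plus its carbon position data."""

    tree: Node
    cmap: dict          # benzene node -> carbon position list (tuple of tuples)
    amap: dict          # benzene node -> adjacent node list (tuple of tuples)
    posmap: dict        # benzene node -> {neighbor: positions tuple}


def adjacent_groups(v: Node, cmap: dict) -> tuple:
    """Adjacent node list ``A_v`` given descendant position lists."""
    if v.label != BENZENE:
        raise ValueError("adjacent node lists exist for benzene nodes only")
    return _groups_of(v, lambda c: tuple(cmap[x] for x in subtree_benzenes(c)))


def _groups_of(v: Node, profile) -> tuple:
    groups: list[tuple[Node, ...]] = []
    if v.parent is not None:
        groups.append((v.parent,))
    clusters: dict = {}
    order: list = []
    for c in v.children:
        if c.is_merge_edge():
            groups.append((c,))
            continue
        k = (m_key(c), profile(c))
        if k not in clusters:
            clusters[k] = []
            order.append(k)
        clusters[k].append(c)
    for k in order:
        groups.append(tuple(clusters[k]))
    groups.sort(key=lambda g: (len(g), g[0].index))
    return tuple(groups)


def naph_adjacent_groups(v1: Node, v2: Node, cmap: dict) -> tuple:
    """Adjacent node list of a fused pair: all substituents of both rings."""
    if not (v2.parent is v1 and v2.is_merge_edge()):
        raise ValueError("(v1, v2) must be a merge bond with v1 the parent")
    members = [c for c in v1.children if c is not v2] + list(v2.children)
    clusters: dict = {}
    order: list = []
    for c in members:
        k = (m_key(c), tuple(cmap[x] for x in subtree_benzenes(c)))
        if k not in clusters:
            clusters[k] = []
            order.append(k)
        clusters[k].append(c)
    groups = [tuple(clusters[k]) for k in order]
    groups.sort(key=lambda g: (len(g), g[0].index))
    return tuple(groups)


class PositionAssigner:
    """Enumerates (or counts) the normal trees extending one multiplicity tree."""

    def __init__(self, root: Node, table: LabelTable):
        self.root = root
        self.table = table
        self.nodes = bfs_nodes(root)
        self.benz = [v for v in self.nodes if v.label == BENZENE]
        self.rev_benz = list(reversed(self.benz))
        self.sub_benz = {v: subtree_benzenes(v) for v in self.nodes}
        self._cand_memo: dict = {}
        # root-incident merge bond (condition 5 context)
        self.root_merge: Node | None = None
        self._rm_m_sym = False
        if root.label == BENZENE:
            for c in root.children:
                if c.is_merge_edge():
                    self.root_merge = c
                    self._rm_away = away_view(root, c)
                    self._rm_sub = away_view(c, root)
                    self._rm_m_sym = (
                        view_m_key(self._rm_away) == view_m_key(self._rm_sub)
                    )
        self.pairs = [p for p in symmetric_pair_candidates(root)
                      if not p.merge_pair]
        # endpoint-side views for the >=_C comparison of condition 6
        self._eviews = {
            id(p): (away_view(p.left, p.next_l), away_view(p.right, p.next_r))
            for p in self.pairs
        }
        self.fast = not self.pairs and self.root_merge is None

    # -- candidate generation -------------------------------------------
    def _groups(self, v: Node, cmap: dict) -> tuple:
        if self.fast:
            return _groups_of(v, lambda c: ())
        return _groups_of(
            v, lambda c: tuple(cmap[x] for x in self.sub_benz[c]))

    def _candidates(self, v: Node, groups: tuple) -> list:
        key = (v.index, tuple(tuple(n.index for n in g) for g in groups))
        memo = self._cand_memo.get(key)
        if memo is not None:
            return memo
        merge_to_parent = v.is_merge_edge()

        def is_merge_group(g: tuple) -> bool:
            m = g[0]
            return len(g) == 1 and (
                (m is v.parent and merge_to_parent)
                or (m.parent is v and m.is_merge_edge())
            )

        results: list = []
        if (v.parent is None and groups and len(groups[0]) >= 3):
            sizes = (len(groups[0]), len(groups[1]) if len(groups) > 1 else 0)
            lists = root_shortcut_lists(sizes)
            for cpl in lists:
                results.append((cpl, _posmap_of(groups, cpl)))
            self._cand_memo[key] = results
            return results

        def rec(gi: int, free: frozenset, acc: list):
            if gi == len(groups):
                cpl = tuple(acc)
                if merge_to_parent or check_condition4(cpl):
                    results.append((cpl, _posmap_of(groups, cpl)))
                return
            g = groups[gi]
            if is_merge_group(g):
                if gi == 0:
                    opts = ([(1, 2)] if g[0] is v.parent else [(1, 2), (1, 6)])
                else:
                    opts = [p for p in _ADJ_PAIRS
                            if p[0] in free and p[1] in free]
            elif gi == 0:
                opts = [(1,) + rest for rest in
                        combinations(sorted(free - {1}), len(g) - 1)]
            else:
                opts = list(combinations(sorted(free), len(g)))
            for opt in opts:
                acc.append(opt)
                rec(gi + 1, free - frozenset(opt), acc)
                acc.pop()

        rec(0, frozenset(range(1, 7)), [])
        self._cand_memo[key] = results
        return results

    # -- conditions 5 and 6 ---------------------------------------------
    def _cond5_ok(self, cmap: dict, posmap: dict) -> bool:
        v1, v2 = self.root, self.root_merge
        if self._rm_m_sym and (
            _akey_excl_root(self._rm_away, cmap)
            == _akey_excl_root(self._rm_sub, cmap)
        ):
            groups = naph_adjacent_groups(v1, v2, cmap)
            nc = []
            for g in groups:
                poss = []
                for c in g:
                    ring = c.parent
                    p = posmap[ring][c][0]
                    poss.append(p - 2 if ring is v1 else p + 2)
                nc.append(tuple(sorted(poss)))
            nc = tuple(nc)
            return all(apply_perm(phi, nc) >= nc for phi in AUT_N)
        c1 = cmap[v1]
        if apply_perm(PHI_REF, c1) == c1:
            c2 = cmap[v2]
            if apply_perm(PHI_REF, c2) < c2:
                return False
        return True

    def _cond6_ok(self, cmap: dict) -> bool:
        for p in self.pairs:
            if not p.is_symmetric(cmap):
                continue
            vl, vr = self._eviews[id(p)]
            if _view_cmp_assigned(vl, vr, cmap) < 0:
                return False
        return True

    # -- driving ---------------------------------------------------------
    def count(self) -> int:
        if self.fast:
            total = 1
            for v in self.rev_benz:
                total *= len(self._candidates(v, self._groups(v, {})))
                if not total:
                    return 0
            return total
        return self._count_rec(0, {}, {})

    def _count_rec(self, i: int, cmap: dict, posmap: dict) -> int:
        if i == len(self.rev_benz):
            if self.root_merge is not None and not self._cond5_ok(cmap, posmap):
                return 0
            return 1 if self._cond6_ok(cmap) else 0
        v = self.rev_benz[i]
        total = 0
        for cpl, pm in self._candidates(v, self._groups(v, cmap)):
            cmap[v] = cpl
            posmap[v] = pm
            total += self._count_rec(i + 1, cmap, posmap)
        return total

    def assignments(self) -> Iterator[Assignment]:
        if self.fast:
            per_node = [(v, self._candidates(v, self._groups(v, {})))
                        for v in self.rev_benz]
            for combo in product(*(c for _, c in per_node)):
                cmap, posmap, amap = {}, {}, {}
                for (v, _), (cpl, pm) in zip(per_node, combo):
                    cmap[v] = cpl
                    posmap[v] = pm
                    amap[v] = self._groups(v, cmap)
                yield Assignment(self.root, cmap, amap, posmap)
            return
        yield from self._iter_rec(0, {}, {}, {})

    def _iter_rec(self, i, cmap, amap, posmap) -> Iterator[Assignment]:
        if i == len(self.rev_benz):
            if self.root_merge is not None and not self._cond5_ok(cmap, posmap):
                return
            if self._cond6_ok(cmap):
                yield Assignment(self.root, dict(cmap), dict(amap), dict(posmap))
            return
        v = self.rev_benz[i]
        groups = self._groups(v, cmap)
        for cpl, pm in self._candidates(v, groups):
            cmap[v] = cpl
            amap[v] = groups
            posmap[v] = pm
            yield from self._iter_rec(i + 1, cmap, amap, posmap)
            del cmap[v], amap[v], posmap[v]


def _posmap_of(groups: tuple, cpl: tuple) -> dict:
    pm: dict = {}
    for g, poss in zip(groups, cpl):
        if len(g) == 1:
            pm[g[0]] = tuple(poss)
        else:
            for node, pos in zip(g, poss):
                pm[node] = (pos,)
    return pm


def _akey_excl_root(view, cmap):
    kids = tuple(sorted((assigned_view_key(c, cmap) for c in view[2]),
                        reverse=True))
    return (view[0].rank, view[1], (), kids)


def _view_cmp_assigned(v1, v2, cmap) -> int:
    b1, b2 = view_benzenes(v1), view_benzenes(v2)
    for a, b in zip(reversed(b1), reversed(b2)):
        ca, cb = cmap[a], cmap[b]
        if ca != cb:
            return 1 if ca > cb else -1
    return 0


def compare_position_lists(ca: tuple, cb: tuple) -> int:
    """Lexicographic order over groups, then elements (-1 / 0 / +1).

    Both lists must share the adjacent-node-list shape.
    """
    if tuple(len(g) for g in ca) != tuple(len(g) for g in cb):
        raise ValueError("position lists have different group shapes")
    return (ca > cb) - (ca < cb)


def automorphism_images(cpl: tuple, perms=AUT_B) -> set:
    """All images of a position list under a ring automorphism group."""
    if perms is AUT_N:
        perms = ((0, 1, 2, 3, 4, 5, 6, 7, 8),) + AUT_N
    return {apply_perm(p, cpl) for p in perms}


def check_condition5(root: Node, cmap: dict, posmap: dict,
                     table: LabelTable) -> bool:
    """Condition 5 for a root benzene merge-bonded to a child.

    True vacuously when the root carries no merge bond.
    """
    pa = PositionAssigner(root, table)
    if pa.root_merge is None:
        return True
    return pa._cond5_ok(cmap, posmap)


def check_condition6(root: Node, cmap: dict, table: LabelTable) -> bool:
    """Condition 6: symmetric-path ordering over the whole assigned tree."""
    return PositionAssigner(root, table)._cond6_ok(cmap)


def assign_positions(tree: Node, table: LabelTable) -> Iterator[Assignment]:
    """Stream the normal trees extending one multiplicity-assigned tree."""
    yield from PositionAssigner(tree, table).assignments()


def count_positions(tree: Node, table: LabelTable) -> int:
    return PositionAssigner(tree, table).count()
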