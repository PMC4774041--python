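"""Enumeration of simple (all-single-bond) contracted skeletons.

Each isomorphism class of node-labeled trees over the budget's node multiset
is emitted exactly once, already in canonical rooted form: center-rooted,
left-heavy, and -- when the center of the longest path is an edge (r, v) with
root r -- with the heavier half below (``T(v) >=_m T^sub(r, v)``).

Strategy: generate every unordered rooted labeled tree once (recursive
composition with non-increasing child keys, memoized on the label multiset),
then keep exactly the rootings the canonical form allows.  A free tree with a
tied center edge yields the *same* unordered rooted tree from either
endpoint, so no duplicate can survive the filter.
"""

from __future__ import annotations

from typing import Iterator

from .formula import NodeBudget
from .mtree import (
    Node, away_view, longest_path_center, m_key, number_bfs, view_m_key,
)


def _submultisets(ms: tuple[int, ...]) -> Iterator[tuple[int, ...]]:
    """All non-empty sub-multisets of a count vector."""
    def rec(i: int, cur: list[int]):
        if i == len(ms):
            if any(cur):
                yield tuple(cur)
            return
        for c in range(ms[i] + 1):
            cur.append(c)
            yield from rec(i + 1, cur)
            cur.pop()
    yield from rec(0, [])


class _SkeletonGenerator:
    def __init__(self, budget: NodeBudget):
        self.table = budget.table
        self.labels = sorted(budget.counts, key=self.table.rank, reverse=True)
        self.ranks = [self.table.rank(l) for l in self.labels]
        self.vals = [self.table.valence(l) for l in self.labels]
        self.rank_to_label = dict(zip(self.ranks, self.labels))
        self.ms0 = tuple(budget.counts[l] for l in self.labels)
        self._sub_memo: dict[tuple[int, ...], list] = {}

    # tree repr: (rank, (child reprs, descending)); tuple order == >_s
    def _subtrees(self, ms: tuple[int, ...]) -> list:
        res = self._sub_memo.get(ms)
        if res is not None:
            return res
        res = []
        for i, c in enumerate(ms):
            if not c:
                continue
            rest = list(ms)
            rest[i] -= 1
            for forest in self._forests(tuple(rest), self.vals[i] - 1, None):
                res.append((self.ranks[i], forest))
        res.sort(reverse=True)
        self._sub_memo[ms] = res
        return res

    def _forests(self, ms, slots: int, bound) -> Iterator[tuple]:
        if not any(ms):
            yield ()
            return
        if slots == 0:
            return
        for sub in _submultisets(ms):
            rest = tuple(a - b for a, b in zip(ms, sub))
            for t in self._subtrees(sub):
                if bound is not None and t > bound:
                    continue
                for f in self._forests(rest, slots - 1, t):
                    yield (t,) + f

    def _rooted(self) -> Iterator[tuple]:
        for i, c in enumerate(self.ms0):
            if not c:
                continue
            rest = list(self.ms0)
            rest[i] -= 1
            for forest in self._forests(tuple(rest), self.vals[i], None):
                yield (self.ranks[i], forest)

    def _build(self, repr_: tuple) -> Node:
        node = Node(self.rank_to_label[repr_[0]], self.table)
        for ch in repr_[1]:
            node.add(self._build(ch))
        return node

    def trees(self) -> Iterator[Node]:
        for repr_ in self._rooted():
            root = self._build(repr_)
            root.mult = 0
            number_bfs(root)
            center = longest_path_center(root)
            if len(center) == 1:
                if center[0] is not root:
                    continue
            else:
                if root not in center:
                    continue
                v = center[0] if center[1] is root else center[1]
                # condition 2: the half below the center edge is the heavier
                if m_key(v) < view_m_key(away_view(root, v)):
                    continue
            yield root


def enumerate_skeletons(budget: NodeBudget) -> Iterator[Node]:
    """Stream every non-isomorphic canonical skeleton for the budget.

    Nodes respect ``deg(v) <= val(l(v))`` (the slack is later consumed by bond
    multiplicities and implicit hydrogens).  Deterministic: repeated runs yield
    the identical sequence.
    """
    yield from _SkeletonGenerator(budget).trees()
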