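import itertools
import random

import pytest

from arenetree.formula import EnumerationSpec, contract_budget
from arenetree.mtree import (
    away_view, bfs_sequence, canonicalize, compare_m, compare_s,
    is_center_rooted, is_left_heavy, is_symmetric_path, left_of,
    longest_path_center, m_key, number_bfs, subtree_away, view_m_key,
)
from arenetree.skeletons import enumerate_skeletons


def test_bfs_sequence_level_order(mk):
    root = mk("C", mk("C", mk("O")), mk("N"))
    number_bfs(root)
    nodes, edges = bfs_sequence(root)
    assert [n.label for n in nodes] == ["C", "C", "N", "O"]
    assert [(a.label, b.label) for a, b in edges] == [
        ("C", "C"), ("C", "N"), ("C", "O")]
    single = mk("C")
    assert bfs_sequence(single) == ([single], [])


def test_compare_s_label_dominates(mk):
    assert compare_s(mk("C"), mk("N")) > 0
    assert compare_s(mk("O"), mk("N")) < 0


def test_compare_s_equal_and_child_count(mk):
    a = mk("C", mk("C"), mk("O"))
    b = mk("C", mk("C"), mk("O"))
    assert compare_s(a, b) == 0
    # equal first children, two children beat one (h=2 > 1=k)
    u = mk("C", mk("C"), mk("O"))
    v = mk("C", mk("C"))
    assert compare_s(u, v) > 0


def test_compare_m_multiplicity_tiebreak(mk):
    u = mk("C", mk("C", mult=2))
    v = mk("C", mk("C", mult=1))
    assert compare_s(u, v) == 0
    assert compare_m(u, v) > 0
    assert compare_m(v, v) == 0
    # structural order dominates multiplicities
    w = mk("N", mk("C", mult=2))
    x = mk("C", mk("C"))
    assert compare_m(x, w) > 0


def _random_tree(mk, rng, n):
    nodes = [mk(rng.choice("CNOb"))]
    for _ in range(n - 1):
        parent = rng.choice(nodes)
        child = mk(rng.choice("CNO"), mult=rng.choice((1, 1, 2)))
        parent.add(child)
        nodes.append(child)
    root = nodes[0]
    root.mult = 0
    return canonicalize(root)


def test_orders_are_total_preorders(mk):
    """Trichotomy and transitivity of >_s and >_m on random subtree pairs."""
    rng = random.Random(7)
    trees = [_random_tree(mk, rng, rng.randint(1, 6)) for _ in range(40)]
    for a, b, c in itertools.islice(itertools.combinations(trees, 3), 300):
        for cmp_ in (compare_s, compare_m):
            ab, ba = cmp_(a, b), cmp_(b, a)
            assert ab == -ba
            if cmp_(a, b) >= 0 and cmp_(b, c) >= 0:
                assert cmp_(a, c) >= 0


def test_subtree_away_child_side_is_plain_subtree(mk, table):
    root = mk("C", mk("C", mk("O")), mk("N"))
    root.mult = 0
    canonicalize(root)
    child = root.children[0]
    away = subtree_away(child, root, table)
    assert m_key(away) == m_key(child)


def test_subtree_away_requires_edge(mk, table):
    root = mk("C", mk("C"), mk("N"))
    canonicalize(root)
    with pytest.raises(ValueError):
        subtree_away(root.children[0], root.children[1], table)


def test_proposition1_exhaustive_small_trees():
    """Parent-side and child-side components of an internal node never tie
    under the multigraph order, on every center-rooted skeleton <= 7 nodes."""
    for formula, n_b in [("C7H16", 0), ("C5H12O", 0), ("C9H12", 1)]:
        budget = contract_budget(EnumerationSpec.from_string(formula, n_b, 0))
        for skel in enumerate_skeletons(budget):
            for v in skel.children:
                for w in v.children:  # v has both a parent and a child
                    up = view_m_key(away_view(v.parent, v))
                    down = view_m_key(away_view(w, v))
                    assert up != down


def test_longest_path_center(mk):
    path3 = mk("C", mk("C", mk("C")))
    canonicalize(path3)
    assert longest_path_center(path3) == (path3.children[0],)
    path4 = mk("C", mk("C", mk("C", mk("C"))))
    canonicalize(path4)
    c = longest_path_center(path4)
    assert len(c) == 2
    star = mk("C", mk("O"), mk("O"), mk("N"), mk("N"))
    canonicalize(star)
    assert longest_path_center(star) == (star,)


def test_center_rooted_and_left_heavy_predicates(mk):
    single = mk("C")
    canonicalize(single)
    assert is_center_rooted(single) and is_left_heavy(single)
    # a 5-node path rooted at an end is not center-rooted
    chain = mk("C", mk("C", mk("C", mk("C", mk("C")))))
    canonicalize(chain)
    assert not is_center_rooted(chain)
    # lighter child before heavier child violates left-heaviness
    bad = mk("C")
    bad.add(mk("O"))
    bad.add(mk("N"))
    number_bfs(bad)
    assert not is_left_heavy(bad)


def test_symmetric_path_midpoints(t7, fig8_t4):
    """Midpoint behavior on symmetric-path candidates: an even-length path
    has the root as one of its two central nodes; an odd-length path has its
    apex strictly shallower than every other path node."""
    from arenetree.mtree import symmetric_pair_candidates, tree_path

    def depth(v):
        d = 0
        while v.parent is not None:
            v = v.parent
            d += 1
        return d

    seen = 0
    for root in (t7, fig8_t4):
        for cand in symmetric_pair_candidates(root):
            p = tree_path(cand.left, cand.right)
            n = len(p)
            if n % 2 == 0:
                assert root in (p[n // 2 - 1], p[n // 2])
            else:
                apex = p[n // 2]
                assert all(depth(apex) < depth(v) for v in p if v is not apex)
            seen += 1
    assert seen > 0


def test_symmetric_path_and_left_of(mk, t7):
    v2, v3 = t7.children
    cmap = {}
    # equal sibling subtrees: the 3-node path through the root is symmetric
    assert is_symmetric_path(t7, v2, v3, cmap)
    assert left_of(t7, v2, v3) and not left_of(t7, v3, v2)
    # different-label sibling leaves are not symmetric
    root = mk("C", mk("N"), mk("O"))
    canonicalize(root)
    assert not is_symmetric_path(root, root.children[0], root.children[1])
    # deeper mirrored pair becomes symmetric only when the inner benzene
    # position lists agree
    v4 = v2.children[0]
    v5 = v3.children[0]
    eq = {v2: ((1,), (2, 3)), v3: ((1,), (2, 3)),
          v4: ((1, 2), (4,)), v5: ((1, 2), (4,))}
    ne = dict(eq)
    ne[v3] = ((1,), (3, 4))
    assert is_symmetric_path(t7, v4, v5, eq)
    assert not is_symmetric_path(t7, v4, v5, ne)
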