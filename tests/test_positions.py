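import pytest

from arenetree.formula import EnumerationSpec
from arenetree.mtree import canonicalize
from arenetree.pipeline import enumerate_assigned
from arenetree.positions import (
    AUT_B, AUT_N, PositionAssigner, adjacent_groups, apply_perm,
    automorphism_images, check_condition4, naph_adjacent_groups,
    root_shortcut_lists, to_naphthalene_positions,
)


# -- adjacency grouping ------------------------------------------------------

def test_adjacent_groups_equal_pair_last(fig6_t1):
    v1 = fig6_t1
    v2, v3, v4, v5 = v1.children  # two C (equal pair), N, O
    groups = adjacent_groups(v1, {})
    assert groups == ((v4,), (v5,), (v2, v3))


def test_adjacent_groups_merge_is_singleton(fig6_t3):
    v1 = fig6_t3
    v2, v3, v4, v5 = v1.children  # merge benzene, C, N, O
    groups = adjacent_groups(v1, {v2: ()})
    assert groups == ((v2,), (v3,), (v4,), (v5,))


def test_adjacent_groups_leaf_benzene_parent_first(mk, table):
    root = mk("C", mk("b"), mk("C"))
    root.mult = 0
    canonicalize(root)
    benz = root.children[0]
    assert adjacent_groups(benz, {}) == ((root,),)


def test_naph_adjacent_groups_fig8(fig8_t4):
    v1 = fig8_t4
    v2 = v1.children[0]
    v3, v4 = v1.children[1], v1.children[2]   # N, O on the root ring
    v5, v6 = v2.children                       # N, O on the child ring
    groups = naph_adjacent_groups(v1, v2, {})
    assert groups == ((v3, v5), (v4, v6))


def test_naph_adjacent_groups_unsubstituted(mk, table):
    root = mk("b", mk("b", mult=2))
    root.mult = 0
    canonicalize(root)
    assert naph_adjacent_groups(root, root.children[0], {}) == ()


# -- position-list algebra ---------------------------------------------------

def test_position_list_comparison_is_lexicographic():
    from arenetree.positions import compare_position_lists

    assert compare_position_lists(((1,), (4,), (2, 3)), ((3,), (4,), (1, 2))) < 0
    assert compare_position_lists(((1, 2), (3,)), ((1, 2), (4,))) < 0
    assert compare_position_lists(((1, 2), (4,), (3,)), ((1, 2), (4,), (3,))) == 0
    with pytest.raises(ValueError):
        compare_position_lists(((1, 2),), ((1,), (2,)))


def test_automorphism_images_reflection_example():
    images = automorphism_images(((3,), (4,), (1, 2)))
    assert ((6,), (5,), (1, 2)) in images          # reflection across (1,2)
    assert ((3,), (4,), (1, 2)) in images          # identity
    assert len(AUT_B) == 12
    # rotation by pi on the naphthalene frame
    assert apply_perm(AUT_N[0], ((2, 6), (3, 5))) == ((2, 6), (1, 7))


def test_aut_groups_closed_under_composition():
    perms = {p[1:] for p in AUT_B}
    for p in AUT_B:
        for q in AUT_B:
            comp = tuple(p[q[i]] for i in range(1, 7))
            assert comp in perms
    autn = {(0, 1, 2, 3, 4, 5, 6, 7, 8)} | set(AUT_N)
    for p in autn:
        for q in autn:
            comp = (0,) + tuple(p[q[i]] for i in range(1, 9))
            assert comp in autn


def test_check_condition4_examples():
    assert not check_condition4(((1,), (4, 5)))   # reflection gives ((1),(3,4))
    assert check_condition4(((1,),))
    assert check_condition4(((1, 2), (4,), (3,)))


def test_to_naphthalene_positions_fig8():
    assert to_naphthalene_positions(((1, 2), (4,), (3,)), ((1, 2), (4,), (5,))) \
        == ((2, 6), (1, 7))
    assert to_naphthalene_positions(((1, 2), (4,), (5,)), ((1, 2), (4,), (3,))) \
        == ((2, 6), (3, 5))
    assert to_naphthalene_positions(((1, 2),), ((1, 2),)) == ()
    with pytest.raises(ValueError):
        to_naphthalene_positions(((2, 3), (1,)), ((1, 2), (4,)))


def test_root_shortcut_table():
    assert root_shortcut_lists((3, 0)) == (((1, 2, 3),), ((1, 2, 4),), ((1, 3, 5),))
    assert root_shortcut_lists((5, 0)) == (((1, 2, 3, 4, 5),),)
    assert root_shortcut_lists((3, 3)) == (
        ((1, 2, 3), (4, 5, 6)), ((1, 2, 4), (3, 5, 6)), ((1, 3, 5), (2, 4, 6)))
    with pytest.raises(ValueError):
        root_shortcut_lists((2, 0))


@pytest.mark.parametrize("k, want", [(3, 3), (4, 3), (5, 1), (6, 1)])
def test_shortcut_equals_orbit_minimization(k, want):
    """The table rows are exactly the dihedral-orbit minima among ascending
    k-subsets containing position 1 (computed here independently)."""
    from itertools import combinations
    generic = [((1,) + rest,) for rest in combinations(range(2, 7), k - 1)]
    minimal = [c for c in generic if check_condition4(c)]
    assert minimal == list(root_shortcut_lists((k, 0)))
    assert len(minimal) == want


def test_shortcut_two_groups_equals_orbit_minimization():
    from itertools import combinations
    generic = []
    for rest in combinations(range(2, 7), 2):
        g0 = (1,) + rest
        g1 = tuple(p for p in range(1, 7) if p not in g0)
        generic.append((g0, g1))
    minimal = [c for c in generic if check_condition4(c)]
    assert minimal == list(root_shortcut_lists((3, 3)))


def test_assigned_order_decided_by_root_lists(mk, table):
    """Two same-shape substituted rings compare by their position lists."""
    from arenetree.mtree import compare_assigned

    t1 = mk("b", mk("C"), mk("C"), mk("N"), mk("O"))
    t2 = mk("b", mk("C"), mk("C"), mk("N"), mk("O"))
    for t in (t1, t2):
        t.mult = 0
        canonicalize(t)
    cmap = {t1: ((3,), (4,), (1, 2)), t2: ((1,), (4,), (2, 3))}
    assert compare_assigned(t1, t2, cmap) > 0
    cmap[t2] = cmap[t1]
    assert compare_assigned(t1, t2, cmap) == 0


def test_assigned_order_highest_index_dominates(t7, table):
    """When two benzene nodes differ, the deeper (higher BFS index) one
    decides regardless of the shallower one's lists."""
    from arenetree.mtree import compare_assigned

    v2, v3 = t7.children
    v4, v5 = v2.children[0], v3.children[0]
    cmap = {v2: ((1,), (3, 4)), v3: ((1,), (2, 3)),   # favors v2 ...
            v4: ((1, 2), (3,)), v5: ((1, 2), (6,))}   # ... but v4 < v5 wins
    assert compare_assigned(v2, v3, cmap) < 0
    cmap[v4], cmap[v5] = cmap[v5], cmap[v4]
    assert compare_assigned(v2, v3, cmap) > 0


# -- condition 5 on the fused pair (Fig 8 worked values) ---------------------

def test_condition5_keeps_one_of_each_rotated_pair(fig8_t4, table):
    v1 = fig8_t4
    v2 = v1.children[0]
    emitted = {(a.cmap[v1], a.cmap[v2])
               for a in PositionAssigner(v1, table).assignments()}
    assert (((1, 2), (4,), (3,)), ((1, 2), (4,), (5,))) in emitted
    # the pi-rotated twin encodes the same molecule and must be absent
    assert (((1, 2), (4,), (5,)), ((1, 2), (4,), (3,))) not in emitted
    for c1, _ in emitted:
        assert c1[0] == (1, 2)  # merge carbons of a symmetric root pair


# -- the worked example ------------------------------------------------------

def test_worked_example_candidate_filtering(t7, table):
    pa = PositionAssigner(t7, table)
    v2, v3 = t7.children             # parent rings
    v4 = v2.children[0]              # child ring (merge)
    cands_v4 = [c for c, _ in pa._candidates(v4, pa._groups(v4, {}))]
    assert cands_v4 == [((1, 2), (3,)), ((1, 2), (4,)),
                        ((1, 2), (5,)), ((1, 2), (6,))]
    cmap = {x: ((1, 2), (3,)) for x in (v4, v3.children[0])}
    cands_v2 = [c for c, _ in pa._candidates(v2, pa._groups(v2, cmap))]
    assert cands_v2 == [((1,), (2, 3)), ((1,), (3, 4))]


def test_worked_example_totals(t7, table):
    pa = PositionAssigner(t7, table)
    assert pa.count() == 36
    sym = sum(1 for a in pa.assignments()
              if a.cmap[t7.children[0]] == a.cmap[t7.children[1]])
    assert sym == 20 and pa.count() - sym == 16


# -- propositions across whole enumerations ---------------------------------

@pytest.mark.parametrize(
    "formula, n_b, n_n",
    [("C8H10O", 1, 0), ("C12H12", 0, 1), ("C13H12", 2, 0), ("C12H11N", 0, 1)],
)
def test_every_list_starts_at_position_one(formula, n_b, n_n):
    spec = EnumerationSpec.from_string(formula, n_b, n_n)
    seen = 0
    for a in enumerate_assigned(spec):
        for v, cpl in a.cmap.items():
            if cpl:
                assert cpl[0][0] == 1
                for grp in cpl:
                    assert list(grp) == sorted(grp)  # ascending within groups
                flat = [p for grp in cpl for p in grp]
                assert len(flat) == len(set(flat))
        seen += 1
    assert seen > 0


def test_root_merge_pair_minimal_under_ring_group():
    """Symmetric root naphthalenes carry the merge bond at (1,2) and a list
    minimal under the hexagon group."""
    spec = EnumerationSpec.from_string("C12H12", 0, 1)
    for a in enumerate_assigned(spec):
        root = a.tree
        if root.label != "b":
            continue
        for c in root.children:
            if c.is_merge_edge():
                assert a.cmap[root][0] == (1, 2) or check_condition4(a.cmap[root])
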