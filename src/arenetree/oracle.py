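"""Independent brute-force oracle for small instances.

The oracle answers the same question as the main pipeline -- how many
non-isomorphic molecules realize a formula with the requested ring counts --
by the most naive route possible: every labeled tree over the contracted
node multiset (Pruefer sequences), every raw bond/merge assignment, every raw
injective placement of ring substituents onto ring carbons, expanded to an
explicit graph and de-duplicated by a canonical graph key.  It shares with
the pipeline only the formula parser, the passive MolecularGraph container
and the key function; the generation and expansion logic is written from
scratch so that the two routes are independent evidence.
"""

from __future__ import annotations

import random
from itertools import combinations, permutations, product

import networkx as nx

from .expand import AROMATIC, MolecularGraph, to_rdkit
from .formula import BENZENE, HYDROGEN, EnumerationSpec
from . import pipeline


class InstanceTooLarge(ValueError):
    pass


def canonical_graph_key(g: MolecularGraph) -> str:
    """Equal keys iff the molecules are isomorphic (labels, bond orders,
    hydrogen counts all respected): RDKit canonical SMILES."""
    from rdkit import Chem

    return Chem.MolToSmiles(to_rdkit(g))


# ---------------------------------------------------------------------------
# raw enumeration
# ---------------------------------------------------------------------------

def _node_labels(spec: EnumerationSpec) -> tuple[list[str], int]:
    # re-derived from the problem statement: a benzene ring contracts to one
    # node of label 'b', a naphthalene ring to two merge-bonded 'b' nodes
    labels: list[str] = [BENZENE] * (spec.n_b + 2 * spec.n_n)
    n_c = spec.formula.get("C", 0) - 6 * spec.n_b - 10 * spec.n_n
    if n_c < 0:
        raise ValueError("not enough carbon for the requested rings")
    labels += ["C"] * n_c
    for lab, c in sorted(spec.formula.items()):
        if lab not in ("C", HYDROGEN):
            labels += [lab] * c
    return labels, spec.formula.get(HYDROGEN, 0)


def _labeled_trees(n: int):
    """Adjacency lists of all labeled trees on n nodes."""
    if n == 1:
        yield [[]]
        return
    if n == 2:
        yield [[1], [0]]
        return
    for seq in product(range(n), repeat=n - 2):
        g = nx.from_prufer_sequence(list(seq))
        yield [sorted(g.neighbors(v)) for v in range(n)]


def _tree_code(adj, labels, emult) -> tuple:
    """Canonical code of a free labeled multigraph tree (min over rootings)."""
    n = len(adj)

    def code(v, parent):
        ch = sorted(
            (code(c, v) for c in adj[v] if c != parent), reverse=True)
        m = emult.get(frozenset((v, parent)), 0) if parent is not None else 0
        return (labels[v], m, tuple(ch))

    return min(code(v, None) for v in range(n))


def _assignments(adj, labels, vals, n_n, extra):
    """All merge/increment assignments as edge->multiplicity maps."""
    n = len(adj)
    edges = [frozenset((u, v)) for u in range(n) for v in adj[u] if u < v]
    bb = [e for e in edges if all(labels[x] == BENZENE for x in e)]
    plain = [e for e in edges if all(labels[x] != BENZENE for x in e)]
    for merge in combinations(bb, n_n):
        used = set()
        ok = True
        for e in merge:
            if e & used:
                ok = False
                break
            used |= e
        if not ok:
            continue
        for incs in product(range(3), repeat=len(plain)):
            if sum(incs) != extra:
                continue
            emult = {e: 1 for e in edges}
            for e in merge:
                emult[e] = 2
            for e, k in zip(plain, incs):
                emult[e] = 1 + k
            deg_ok = True
            for v in range(n):
                w = sum(emult[frozenset((v, u))] for u in adj[v])
                if w > vals[labels[v]]:
                    deg_ok = False
                    break
            if deg_ok:
                yield emult


def _expand_all(adj, labels, emult, vals):
    """All raw substituent placements of one multigraph tree, as graphs."""
    n = len(adj)
    merge_partner = {}
    for e, m in emult.items():
        u, v = tuple(e)
        if m == 2 and labels[u] == BENZENE:
            merge_partner[u] = v
            merge_partner[v] = u

    g0_atoms: list[str] = []
    g0_bonds: list[tuple[int, int, object]] = []
    rings: dict[int, tuple[int, ...]] = {}
    fused: list[tuple[int, int]] = []
    free: dict[int, list[int]] = {}
    atom_of: dict[int, int] = {}
    shared: set[int] = set()

    def add_atom(el):
        g0_atoms.append(el)
        return len(g0_atoms) - 1

    done = set()
    ring_no: dict[int, int] = {}
    for v in range(n):
        if labels[v] != BENZENE:
            atom_of[v] = add_atom(labels[v])
            continue
        if v in done:
            continue
        if v in merge_partner:
            w = merge_partner[v]
            s1, s2 = add_atom("C"), add_atom("C")
            shared.update((s1, s2))
            a = [add_atom("C") for _ in range(4)]
            b = [add_atom("C") for _ in range(4)]
            cyc_a = [s1] + a + [s2]
            cyc_b = [s1] + b + [s2]
            for cyc in (cyc_a, cyc_b):
                for x, y in zip(cyc, cyc[1:]):
                    g0_bonds.append((x, y, AROMATIC))
            g0_bonds.append((s1, s2, AROMATIC))
            ring_no[v] = len(rings)
            rings[v] = tuple(cyc_a)
            ring_no[w] = len(rings)
            rings[w] = tuple(cyc_b)
            fused.append((ring_no[v], ring_no[w]))
            free[v] = a
            free[w] = b
            done.update((v, w))
        else:
            c = [add_atom("C") for _ in range(6)]
            for x, y in zip(c, c[1:] + c[:1]):
                g0_bonds.append((x, y, AROMATIC))
            ring_no[v] = len(rings)
            rings[v] = tuple(c)
            free[v] = c
            done.add(v)

    # substituent edges per benzene node, in a fixed order
    benz_nbrs = {
        v: [u for u in adj[v] if merge_partner.get(v) != u]
        for v in range(n) if labels[v] == BENZENE
    }
    choices = []
    benz_list = sorted(benz_nbrs)
    for v in benz_list:
        choices.append(list(permutations(free[v], len(benz_nbrs[v]))))

    plain_edges = [
        (u, v) for u in range(n) for v in adj[u]
        if u < v and labels[u] != BENZENE and labels[v] != BENZENE
    ]

    for combo in product(*choices):
        site = {}
        for v, placement in zip(benz_list, combo):
            for u, atom in zip(benz_nbrs[v], placement):
                site[(v, u)] = atom
        bonds = list(g0_bonds)
        subst: dict[int, int] = {}
        for u in range(n):
            for v in adj[u]:
                if u >= v or merge_partner.get(u) == v:
                    continue
                m = emult[frozenset((u, v))]
                if labels[u] == BENZENE:
                    a = site[(u, v)]
                    subst[a] = subst.get(a, 0) + 1
                else:
                    a = atom_of[u]
                if labels[v] == BENZENE:
                    b = site[(v, u)]
                    subst[b] = subst.get(b, 0) + 1
                else:
                    b = atom_of[v]
                bonds.append((a, b, m))
        wdeg = [0] * len(g0_atoms)
        for a, b, order in bonds:
            if order != AROMATIC:
                wdeg[a] += order
                wdeg[b] += order
        hs = []
        ring_atoms = {i for r in rings.values() for i in r}
        for i, el in enumerate(g0_atoms):
            if i in ring_atoms:
                hs.append(0 if i in shared else 1 - subst.get(i, 0))
            else:
                hs.append(vals[el] - wdeg[i])
        yield MolecularGraph(
            atoms=list(g0_atoms), bonds=bonds, h_counts=hs,
            rings=list(rings.values()), fused=list(fused))


def brute_force_enumerate(
    spec: EnumerationSpec, max_nodes: int = 8
) -> tuple[int, set[str]]:
    """Exact isomer count and canonical key set by exhaustive generation."""
    labels, n_h = _node_labels(spec)
    n = len(labels)
    if n == 0:
        raise ValueError("no heavy-atom nodes")
    if n > max_nodes:
        raise InstanceTooLarge(f"{n} contracted nodes exceeds guard {max_nodes}")
    vals = dict(spec.table.valences)
    twice = 2 + sum(vals[l] - 2 for l in labels) - n_h
    if twice % 2 or twice < 0 or twice // 2 < spec.n_n:
        return 0, set()
    extra = twice // 2 - spec.n_n

    seen_trees = set()
    tree_reps = []
    for adj in _labeled_trees(n):
        if any(len(adj[v]) > vals[labels[v]] for v in range(n)):
            continue
        code = _tree_code(adj, labels, {})
        if code in seen_trees:
            continue
        seen_trees.add(code)
        tree_reps.append(adj)

    keys: set[str] = set()
    for adj in tree_reps:
        seen_mult = set()
        for emult in _assignments(adj, labels, vals, spec.n_n, extra):
            code = _tree_code(adj, labels, emult)
            if code in seen_mult:
                continue
            seen_mult.add(code)
            for g in _expand_all(adj, labels, emult, vals):
                if any(h < 0 for h in g.h_counts):
                    continue
                keys.add(canonical_graph_key(g))
    return len(keys), keys


def random_normal_tree(spec: EnumerationSpec, seed: int):
    """Reproducible pseudo-random normal tree (an ``Assignment``) for tests."""
    pool = list(pipeline.enumerate_assigned(spec))
    if not pool:
        raise ValueError("spec admits no structure")
    return random.Random(seed).choice(pool)
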