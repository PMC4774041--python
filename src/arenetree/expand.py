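"""Expansion of assigned trees into explicit molecular graphs, plus
SMILES / SDF serialization through RDKit.

A benzene node becomes a six-carbon aromatic ring whose substituents sit at
the carbons named by the node's carbon position list; a merge-bonded pair
becomes a fused ten-carbon bicyclic.  The two shared carbons are the parent
ring's merge pair (i, i+1) and the child ring's carbons (1, 2), identified
anti-parallel: child-1 = parent-(i+1), child-2 = parent-i.  Whatever valence
the heavy-atom multigraph leaves unused is implicit hydrogen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .formula import BENZENE, HYDROGEN, LabelTable
from .mtree import Node, bfs_nodes
from .positions import Assignment

AROMATIC = "ar"


@dataclass
class MolecularGraph:
    """Explicit heavy-atom multigraph with implicit hydrogen counts."""

    atoms: list[str] = field(default_factory=list)
    bonds: list[tuple[int, int, object]] = field(default_factory=list)
    h_counts: list[int] = field(default_factory=list)
    rings: list[tuple[int, ...]] = field(default_factory=list)
    fused: list[tuple[int, int]] = field(default_factory=list)

    def formula(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for el in self.atoms:
            out[el] = out.get(el, 0) + 1
        n_h = sum(self.h_counts)
        if n_h:
            out[HYDROGEN] = out.get(HYDROGEN, 0) + n_h
        return out


def expand_to_graph(assignment: Assignment, table: LabelTable) -> MolecularGraph:
    """Expand a normal tree into its (unique) molecular graph."""
    tree = assignment.tree
    posmap = assignment.posmap
    g = MolecularGraph()
    atom_of: dict[Node, int] = {}
    ring_atoms: dict[Node, dict[int, int]] = {}
    ring_index: dict[Node, int] = {}
    shared: set[int] = set()

    def new_atom(el: str) -> int:
        g.atoms.append(el)
        return len(g.atoms) - 1

    for v in bfs_nodes(tree):
        if v.label != BENZENE:
            atom_of[v] = new_atom(v.label)
            continue
        if v.is_merge_edge():
            par = v.parent
            lo, hi = posmap[par][v]
            if hi != lo + 1:
                raise AssertionError("merge carbons must be ring-adjacent")
            amap = {1: ring_atoms[par][hi], 2: ring_atoms[par][lo]}
            shared.update(amap.values())
            for p in (3, 4, 5, 6):
                amap[p] = new_atom("C")
            for a, b in ((2, 3), (3, 4), (4, 5), (5, 6), (6, 1)):
                g.bonds.append((amap[a], amap[b], AROMATIC))
            ring_atoms[v] = amap
            ring_index[v] = len(g.rings)
            g.rings.append(tuple(amap[p] for p in range(1, 7)))
            g.fused.append((ring_index[par], ring_index[v]))
        else:
            amap = {p: new_atom("C") for p in range(1, 7)}
            for p in range(1, 7):
                g.bonds.append((amap[p], amap[p % 6 + 1], AROMATIC))
            ring_atoms[v] = amap
            ring_index[v] = len(g.rings)
            g.rings.append(tuple(amap[p] for p in range(1, 7)))

    subst: dict[int, int] = {}
    for v in bfs_nodes(tree)[1:]:
        if v.is_merge_edge():
            continue
        par = v.parent
        if par.label == BENZENE:
            a = ring_atoms[par][posmap[par][v][0]]
            subst[a] = subst.get(a, 0) + 1
        else:
            a = atom_of[par]
        if v.label == BENZENE:
            b = ring_atoms[v][posmap[v][par][0]]
            subst[b] = subst.get(b, 0) + 1
        else:
            b = atom_of[v]
        g.bonds.append((a, b, v.mult))

    wdeg = [0] * len(g.atoms)
    for a, b, order in g.bonds:
        if order != AROMATIC:
            wdeg[a] += order
            wdeg[b] += order
    for i, el in enumerate(g.atoms):
        ring_atom = any(i in r for r in g.rings)
        if ring_atom:
            h = 0 if i in shared else 1 - subst.get(i, 0)
        else:
            h = table.valence(el) - wdeg[i]
        if h < 0:
            raise AssertionError("valence overflow during expansion")
        g.h_counts.append(h)
    return g


# ---------------------------------------------------------------------------
# RDKit serialization
# ---------------------------------------------------------------------------

_BOND_TYPES = None


def to_rdkit(g: MolecularGraph):
    """Build a sanitized RDKit molecule (aromatic rings, explicit H counts)."""
    global _BOND_TYPES
    from rdkit import Chem

    if _BOND_TYPES is None:
        _BOND_TYPES = {
            1: Chem.BondType.SINGLE,
            2: Chem.BondType.DOUBLE,
            3: Chem.BondType.TRIPLE,
            AROMATIC: Chem.BondType.AROMATIC,
        }
    mol = Chem.RWMol()
    aromatic_atoms = {i for ring in g.rings for i in ring}
    for i, el in enumerate(g.atoms):
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        atom.SetNumExplicitHs(g.h_counts[i])
        if i in aromatic_atoms:
            atom.SetIsAromatic(True)
        mol.AddAtom(atom)
    seen = set()
    for a, b, order in g.bonds:
        e = (min(a, b), max(a, b))
        if e in seen:
            continue
        seen.add(e)
        mol.AddBond(a, b, _BOND_TYPES[order])
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    return m


def write_smiles(g: MolecularGraph) -> str:
    """Canonical SMILES of the expanded graph."""
    from rdkit import Chem

    return Chem.MolToSmiles(to_rdkit(g))


def write_sdf(graphs: Iterable[MolecularGraph], sink: TextIO) -> int:
    """Write V2000 molfile records; returns the number written.

    Aromatic rings are kekulized on output (any alternation is as good as
    another; no Kekule structure is distinguished by the enumeration).
    """
    from rdkit import Chem

    n = 0
    for g in graphs:
        sink.write(Chem.MolToMolBlock(to_rdkit(g), kekulize=True))
        sink.write("$$$$\n")
        n += 1
    return n
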