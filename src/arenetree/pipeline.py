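"""End-to-end enumeration pipeline.

skeletons -> bond/merge assignment -> carbon positions -> expansion.
"""

from __future__ import annotations

from typing import Iterator

from .bonds import enumerate_bond_assignments
from .expand import MolecularGraph, expand_to_graph, write_smiles
from .formula import (
    EnumerationSpec, InfeasibleSpec, contract_budget, increment_budget,
)
from .mtree import Node
from .positions import Assignment, PositionAssigner
from .skeletons import enumerate_skeletons


def iter_bond_trees(spec: EnumerationSpec) -> Iterator[Node]:
    """Canonical multiplicity-assigned trees for a request."""
    budget = contract_budget(spec)
    e = increment_budget(budget)
    for skel in enumerate_skeletons(budget):
        yield from enumerate_bond_assignments(skel, spec.n_n, e, spec.table)


def enumerate_assigned(spec: EnumerationSpec) -> Iterator[Assignment]:
    """Stream every normal tree (one per molecule)."""
    try:
        trees = iter_bond_trees(spec)
    except InfeasibleSpec:
        return
    for t in trees:
        yield from PositionAssigner(t, spec.table).assignments()


def count_structures(spec: EnumerationSpec) -> int:
    """Exact isomer count without materializing expansions."""
    try:
        total = 0
        for t in iter_bond_trees(spec):
            total += PositionAssigner(t, spec.table).count()
        return total
    except InfeasibleSpec:
        return 0


def enumerate_graphs(spec: EnumerationSpec) -> Iterator[MolecularGraph]:
    for a in enumerate_assigned(spec):
        yield expand_to_graph(a, spec.table)


def enumerate_smiles(spec: EnumerationSpec) -> Iterator[str]:
    for g in enumerate_graphs(spec):
        yield write_smiles(g)


def ring_combo_counts(spec: EnumerationSpec) -> list[tuple[int, int, int]]:
    """Counts for every feasible (n_b, n_n) pair of the spec's formula."""
    n_c = spec.formula.get("C", 0)
    out = []
    for n_n in range(n_c // 10 + 1):
        for n_b in range((n_c - 10 * n_n) // 6 + 1):
            sub = EnumerationSpec(spec.formula, n_b, n_n, spec.table)
            try:
                contract_budget(sub)
                increment_budget(contract_budget(sub))
            except InfeasibleSpec:
                continue
            out.append((n_b, n_n, count_structures(sub)))
    return out
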