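"""Chemical formulas, valence tables and contracted-node budgets.

A molecule is encoded as a *contracted tree*: every benzene ring becomes a
single node with the special label ``b`` (valence 6), a naphthalene ring
becomes two ``b`` nodes joined by a *merge bond* (a double-weight edge that
stands for the two shared carbons), and hydrogens are implicit -- every unused
valence slot of the final multigraph absorbs one hydrogen.  This module holds
the bookkeeping that turns a chemical formula plus ring counts into the node
multiset and bond-increment budget that the enumeration stages consume.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

BENZENE = "b"
HYDROGEN = "H"

#: default valences; further elements may be supplied through a LabelTable
DEFAULT_VALENCES: dict[str, int] = {BENZENE: 6, "C": 4, "N": 3, "O": 2, "H": 1}

#: default comparison order (descending): b > C > N > O > ... > H
_DEFAULT_ORDER = (BENZENE, "C", "N", "O", HYDROGEN)

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula string or unknown element symbol."""


class InfeasibleSpec(ValueError):
    """The requested formula / ring counts admit no structure."""


@dataclass(frozen=True)
class LabelTable:
    """Total order and valences for atom labels.

    ``order`` lists labels in descending comparison rank; ``b`` (the contracted
    benzene node) always ranks highest.  Elements not named in the default
    order are slotted between ``O`` and ``H`` in descending valence.
    """

    valences: Mapping[str, int]
    order: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.order[0] != BENZENE:
            raise ValueError("benzene label 'b' must rank highest")
        if len(set(self.order)) != len(self.order):
            raise ValueError("label order contains duplicates")
        for lab in self.order:
            if self.valences.get(lab, 0) < 1:
                raise ValueError(f"label {lab!r} needs a valence >= 1")

    @classmethod
    def default(
        cls,
        extra_valences: Mapping[str, int] | None = None,
        order: tuple[str, ...] | None = None,
    ) -> "LabelTable":
        val = dict(DEFAULT_VALENCES)
        if extra_valences:
            val.update(extra_valences)
        if order is None:
            extra = sorted(
                (lab for lab in val if lab not in _DEFAULT_ORDER),
                key=lambda lab: (-val[lab], lab),
            )
            order = _DEFAULT_ORDER[:4] + tuple(extra) + (HYDROGEN,)
        return cls(valences=val, order=tuple(order))

    def rank(self, label: str) -> int:
        """Numeric rank, larger = greater in the label order."""
        try:
            return len(self.order) - self.order.index(label)
        except ValueError:
            raise FormulaError(f"label {label!r} not in label order") from None

    def valence(self, label: str) -> int:
        try:
            return self.valences[label]
        except KeyError:
            raise FormulaError(f"no valence known for {label!r}") from None


def parse_formula(text: str, table: LabelTable | None = None) -> dict[str, int]:
    """Parse a Hill-style formula string such as ``"C8O3H10"``.

    Returns a mapping element -> count.  Every symbol must have a valence in
    ``table`` (default table if omitted); repeated symbols accumulate.
    """
    table = table or LabelTable.default()
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} near position {pos}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        if sym == BENZENE or sym not in table.valences:
            raise FormulaError(f"unknown element {sym!r} in formula {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if pos != len(text) or not counts:
        raise FormulaError(f"malformed formula {text!r}")
    return counts


@dataclass(frozen=True)
class EnumerationSpec:
    """One enumeration request: formula plus benzene / naphthalene counts."""

    formula: Mapping[str, int]
    n_b: int = 0
    n_n: int = 0
    table: LabelTable = field(default_factory=LabelTable.default)

    @classmethod
    def from_string(
        cls, formula: str, n_b: int = 0, n_n: int = 0, table: LabelTable | None = None
    ) -> "EnumerationSpec":
        table = table or LabelTable.default()
        return cls(parse_formula(formula, table), n_b, n_n, table)

    def validate(self) -> None:
        if self.n_b < 0 or self.n_n < 0:
            raise InfeasibleSpec("ring counts must be non-negative")
        if any(c < 0 for c in self.formula.values()):
            raise InfeasibleSpec("negative atom count")
        heavy = sum(c for lab, c in self.formula.items() if lab != HYDROGEN)
        if heavy == 0:
            raise InfeasibleSpec("formula needs at least one non-hydrogen atom")


@dataclass(frozen=True)
class NodeBudget:
    """Contracted-node multiset for one request.

    ``counts`` maps tree-node labels (hydrogen excluded) to multiplicities;
    ``hydrogen_count`` is kept separately because hydrogens never become tree
    nodes: the heavy-atom multigraph determines their placement uniquely.
    """

    counts: Mapping[str, int]
    hydrogen_count: int
    n_b: int
    n_n: int
    table: LabelTable

    @property
    def n_nodes(self) -> int:
        return sum(self.counts.values())


def contract_budget(spec: EnumerationSpec) -> NodeBudget:
    """Node budget of the contracted tree.

    The benzene-node count is ``n_b + 2 n_n`` and the residual carbon count is
    ``n_C - 6 n_b - 10 n_n``; every other heavy element carries over unchanged.
    """
    spec.validate()
    counts: dict[str, int] = {}
    n_c = spec.formula.get("C", 0)
    carbon_nodes = n_c - 6 * spec.n_b - 10 * spec.n_n
    if carbon_nodes < 0:
        raise InfeasibleSpec(
            f"{n_c} carbons cannot host {spec.n_b} benzene and {spec.n_n} naphthalene rings"
        )
    n_benz = spec.n_b + 2 * spec.n_n
    if n_benz:
        counts[BENZENE] = n_benz
    if carbon_nodes:
        counts["C"] = carbon_nodes
    for lab, c in spec.formula.items():
        if lab in ("C", HYDROGEN) or c == 0:
            continue
        counts[lab] = counts.get(lab, 0) + c
    if not counts:
        raise InfeasibleSpec("no heavy-atom tree nodes")
    return NodeBudget(
        counts=counts,
        hydrogen_count=spec.formula.get(HYDROGEN, 0),
        n_b=spec.n_b,
        n_n=spec.n_n,
        table=spec.table,
    )


def increment_budget(budget: NodeBudget) -> int:
    """Total bond-multiplicity surplus E over a simple tree.

    On a tree with deg(v) = val(l(v)) after hydrogens are attached, the
    degree-sum identity forces

        E = 1 + sum_v (val(l(v)) - 2) / 2

    with the sum over *all* nodes including benzene nodes (valence 6) and the
    implicit hydrogens (valence 1, contributing -1/2 each).  Of these E
    surplus units, n_n are consumed by merge bonds; the rest become double or
    triple bonds between ordinary nodes.
    """
    table = budget.table
    twice = 2 + sum(
        c * (table.valence(lab) - 2) for lab, c in budget.counts.items()
    ) - budget.hydrogen_count
    if twice % 2:
        raise InfeasibleSpec("formula has odd valence parity; no molecule exists")
    e = twice // 2
    if e < 0:
        raise InfeasibleSpec("too many hydrogens for the heavy-atom skeleton")
    if e < budget.n_n:
        raise InfeasibleSpec(
            f"increment budget E={e} cannot host {budget.n_n} merge bonds"
        )
    return e
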