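import pytest

from arenetree.formula import LabelTable
from arenetree.mtree import Node, canonicalize


@pytest.fixture(scope="session")
def table() -> LabelTable:
    return LabelTable.default()


def build(table: LabelTable, label: str, *children: Node, mult: int = 1) -> Node:
    n = Node(label, table, mult)
    for c in children:
        n.add(c)
    return n


@pytest.fixture(scope="session")
def mk(table):
    """Terse tree builder: ``mk('C', mk('O'), mult=1)``."""
    def _mk(label, *children, mult=1):
        return build(table, label, *children, mult=mult)
    return _mk


@pytest.fixture()
def fig6_t1(table, mk):
    """Benzene root with an equal pair of C substituents plus N and O.

    Adjacent node list ((v4), (v5), (v2, v3)) with v2, v3 the equal pair.
    """
    root = mk("b", mk("C"), mk("C"), mk("N"), mk("O"))
    root.mult = 0
    return canonicalize(root)


@pytest.fixture()
def fig6_t3(table, mk):
    """Benzene root with a merge-bonded bare benzene child and three
    pairwise-distinct leaf substituents: all adjacency groups are singletons."""
    root = mk("b", mk("b", mult=2), mk("C"), mk("N"), mk("O"))
    root.mult = 0
    return canonicalize(root)


@pytest.fixture()
def fig8_t4(table, mk):
    """Fused pair at the root, each ring bearing one N and one O substituent."""
    child_ring = mk("b", mk("N"), mk("O"), mult=2)
    root = mk("b", child_ring, mk("N"), mk("O"))
    root.mult = 0
    return canonicalize(root)


@pytest.fixture()
def t7(table, mk):
    """Worked-example tree: a degree-two carbon root carrying two identical
    naphthalene branches, each child ring with one terminal substituent."""
    def branch():
        return mk("b", mk("b", mk("C"), mult=2))
    root = mk("C", branch(), branch())
    root.mult = 0
    return canonicalize(root)
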