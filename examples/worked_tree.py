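"""The worked-example tree: counting its carbon-position assignments.

A degree-two carbon root carries two identical naphthalene branches, each a
parent benzene merge-bonded to a child benzene with one terminal methyl.
Ring-symmetry pruning leaves 4 candidate lists per child ring and 2 per
parent ring; the symmetric-path ordering then cuts the raw 4*4*2*2 = 64
combinations to 36 normal trees: 16 with the two branches assigned
differently plus two symmetric sub-cases of 10.
"""

from arenetree.formula import LabelTable
from arenetree.mtree import Node, canonicalize
from arenetree.positions import PositionAssigner

table = LabelTable.default()


def branch() -> Node:
    ring = Node("b", table, 1)
    child = Node("b", table, 2)      # merge bond -> fused naphthalene
    child.add(Node("C", table, 1))
    ring.add(child)
    return ring


root = Node("C", table, 0)
root.add(branch())
root.add(branch())
canonicalize(root)

assigner = PositionAssigner(root, table)
total = assigner.count()
sym = sum(1 for a in assigner.assignments()
          if a.cmap[root.children[0]] == a.cmap[root.children[1]])
print(f"assigned normal trees: {total}")
print(f"  branches assigned differently: {total - sym}")
print(f"  branches assigned equally:     {sym} (2 sub-cases of 10)")
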