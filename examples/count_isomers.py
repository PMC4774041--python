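"""Count tree-like constitutional isomers for a few formulas.

Each line prints a formula, the requested ring content and the exact number
of distinct molecules (constitutional isomers; stereochemistry and Kekule
alternation ignored, tautomers counted separately).
"""

from arenetree import EnumerationSpec, count_structures

CASES = [
    ("C4H10", 0, 0),   # butanes
    ("C8H10", 1, 0),   # one benzene ring: ethylbenzene + o/m/p-xylene
    ("C8O3H10", 1, 0), # one benzene ring with three oxygens
    ("C10H8", 0, 1),   # naphthalene itself
    ("C12N1O1H11", 2, 0),
]

for formula, n_b, n_n in CASES:
    spec = EnumerationSpec.from_string(formula, n_b, n_n)
    n = count_structures(spec)
    print(f"{formula:12s}  benzene={n_b}  naphthalene={n_n}  isomers={n}")

print("\nEach count is the number of non-isomorphic molecular graphs with")
print("exactly the requested rings and no other cycles.")
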