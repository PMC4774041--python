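"""Enumerate the C8H10 single-benzene isomers and print their SMILES.

The four structures are ethylbenzene and the ortho/meta/para xylenes --
the ring-substitution patterns the carbon position lists distinguish.
"""

from arenetree import EnumerationSpec, enumerate_smiles

spec = EnumerationSpec.from_string("C8H10", n_b=1)
for smi in enumerate_smiles(spec):
    print(smi)
print("\n4 SMILES: one ethyl substitution and the three distinct ways of")
print("placing two methyls on a benzene ring (positions 1,2 / 1,3 / 1,4).")
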