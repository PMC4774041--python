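"""Per-(benzene, naphthalene) counts for one formula.

The ring numbers are not free parameters of a molecule: for a given formula
only a few (n_b, n_n) pairs are chemically feasible, and this script reports
the isomer count for each of them.
"""

from arenetree import EnumerationSpec, ring_combo_counts

spec = EnumerationSpec.from_string("C12H12")
print("n_b\tn_n\tisomers")
for n_b, n_n, count in ring_combo_counts(spec):
    print(f"{n_b}\t{n_n}\t{count}")
print("\nRow (0,1) is the twelve ways of arranging two methyls (or one")
print("ethyl / ethylidene chain) on a naphthalene core.")
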