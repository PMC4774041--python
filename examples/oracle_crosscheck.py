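"""Cross-validate the enumerator against the brute-force oracle.

For each small instance the pipeline count must equal the count obtained by
exhaustively expanding every labeled tree / bond assignment / substituent
placement and de-duplicating by canonical SMILES.
"""

from arenetree import EnumerationSpec, count_structures
from arenetree.oracle import brute_force_enumerate

for formula, n_b, n_n in [
    ("C5H12", 0, 0), ("C8H10", 1, 0), ("C8H11N", 1, 0),
    ("C12H12", 0, 1), ("C13H12", 2, 0),
]:
    spec = EnumerationSpec.from_string(formula, n_b, n_n)
    mine = count_structures(spec)
    ref, _ = brute_force_enumerate(spec)
    status = "ok" if mine == ref else "MISMATCH"
    print(f"{formula:8s} b={n_b} n={n_n}  enumerator={mine:4d} "
          f"oracle={ref:4d}  {status}")
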