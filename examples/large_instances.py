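"""Count-only runs of the largest reference instances.

These are correctness checks, not demonstrations: the two biggest requests
enumerate millions of structures each and take tens of minutes in count-only
mode.  Run when you mean it.
"""

import time

from arenetree import EnumerationSpec, count_structures

ROWS = [
    ("C13O2H12", 1, 0, 162122),
    ("C10N2O4H10", 1, 0, 8333991),
    ("C14O4H12", 1, 0, 19514480),
]

for formula, n_b, n_n, reference in ROWS:
    t0 = time.time()
    got = count_structures(EnumerationSpec.from_string(formula, n_b, n_n))
    status = "ok" if got == reference else "MISMATCH"
    print(f"{formula:12s} b={n_b} n={n_n}  count={got}  "
          f"reference={reference}  {status}  ({time.time() - t0:.0f}s)")
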