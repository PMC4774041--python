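"""Optional long-running tier: reference counts too large for the default
suite.  Run explicitly with ``pytest tests_long/``."""

import pytest

from arenetree.formula import EnumerationSpec
from arenetree.pipeline import count_structures


@pytest.mark.parametrize(
    "formula, n_b, n_n, want",
    [
        ("C13O2H12", 1, 0, 162122),
        ("C14O4H12", 1, 0, 19514480),
        ("C10N2O4H10", 1, 0, 8333991),
    ],
)
def test_large_reference_counts(formula, n_b, n_n, want):
    spec = EnumerationSpec.from_string(formula, n_b, n_n)
    assert count_structures(spec) == want
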