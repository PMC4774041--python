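# Methods

## Problem

Enumerate, without repetition, every molecular multigraph with a prescribed
formula in which every node has degree equal to its valence (after implicit
hydrogens) and whose only cycles are `n_b` benzene rings and `n_n`
naphthalene rings.  Both ring counts may be zero, in which case the problem
reduces to acyclic (tree-like) isomer enumeration.  Stereochemistry is not
modeled (the representation is a 2-D tree), Kekulé bond alternation inside
aromatic rings is deliberately not distinguished, and tautomers are distinct
outputs.  Charged or unusual-valence atoms are handled by declaring extra
labels with their own valences in the label table.

## Representation

Rings are contracted: a benzene ring becomes one node `b` with valence 6; a
naphthalene ring becomes two `b` nodes joined by a *merge bond*, an edge of
multiplicity 2 between benzene nodes (it removes two free valences from each
ring, exactly what sharing two carbons does).  Ordinary double/triple bonds
are multiplicity 2/3 edges between non-ring nodes; ring carbons bind their
substituents by single bonds only.  Hydrogens are never explicit nodes:
every unused valence slot of the heavy-atom multigraph is a hydrogen, and
the implementation asserts `Σ_v (val − weighted degree) = n_H` on every
output.  This loses nothing (the heavy-atom multigraph determines hydrogen
placement uniquely) and keeps the canonical form free of leaf clutter.

### Node budget and increment budget

`num(b) = n_b + 2 n_n`, `num(C) = n_C − 6 n_b − 10 n_n`, all other heavy
elements carry over.  The total bond-multiplicity surplus over a simple tree
is forced by the degree-sum identity `deg(v) = val(l(v))` on a tree:

    E = 1 + Σ_v (val(l(v)) − 2) / 2,

the sum running over **all** nodes — benzene nodes at valence 6 and the
implicit hydrogens at valence 1 (−1/2 each).  Merge bonds consume `n_n` of
these units; the remainder becomes double/triple bonds.  A formula whose `E`
is negative, fractional, or smaller than `n_n` is infeasible and counts 0.
(A published variant of this formula omits the benzene term; it fails the
degree-sum identity on toluene and naphthalene, so the identity-derived form
above is used.)

## Canonical form

Each molecule corresponds to exactly one *normal tree*, characterized by six
conditions.  Three nested total preorders drive this:

* `>_s` — labels first (`b > C > N > O > … > H`), then child lists
  lexicographically, longer list winning on an equal prefix;
* `>_m` — `>_s`, then the BFS sequence of edge multiplicities;
* `>_C` — `>_m`, then carbon position lists compared at the **highest** BFS
  index where they differ.

Conditions: (1) the root is the center of a longest path, or an endpoint of
the center edge, with siblings non-increasing under `≥_m` (left-heavy);
(2) at a center edge the half below it is the `≥_m`-heavier one; (3) carbon
positions ascend within each group of the adjacent node list; (4) every
benzene node not merge-bonded to its parent carries a position list minimal
under the dihedral group of the hexagon; (5) a merge bond at the root is
minimal under the order-4 naphthalene group when its two halves are
equivalent, else the child ring respects the long-axis reflection whenever
the parent ring is fixed by it; (6) across every *symmetric path* (the two
halves mirror-equal under `≥_m` with equal position lists on the inner
region) whose endpoints are not merge-bonded, the left endpoint's subtree
dominates under `≥_C`.

Where `≥_m` leaves ties among siblings, the implementation orders them by a
deterministic deep key that also includes parent-edge multiplicities.  The
tie-break changes internal child order only, never the emitted set; without
it, an assignment placing a double bond on one of two identical leaves would
admit two "left-heavy" encodings of the same molecule.

### Merge-bond geometry

The shared carbons of a fused pair are the parent ring's adjacent pair
(i, i+1) — forced to (1, 2) at a root by condition 4 — and the child ring's
carbons (1, 2), identified anti-parallel (child-1 = parent-(i+1), child-2 =
parent-i).  The naphthalene coordinate frame maps parent carbons 3..6 to
positions 1..4 and child carbons 3..6 to 5..8, giving the order-4
automorphism group {identity; rotation i ↦ i+4 (mod 8); the within-ring
reflection 1↔4, 2↔3, 5↔8, 6↔7; the ring-swapping reflection 1↔8, 2↔7, 3↔6,
4↔5} and the per-ring reflection 1↔2, 3↔6, 4↔5 used by condition 5.  The
convention reproduces every worked position-list value and is validated
wholesale by the oracle sweep.

## Algorithms

**Skeletons.**  Unordered rooted labeled trees are generated recursively —
choose the root label, then a multiset of child subtrees in non-increasing
canonical order, memoized on the label multiset — so each rooted isomorphism
class appears exactly once; center-rootedness and the center-edge tie-break
then select exactly one rooting per free tree.  Degree ≤ valence is enforced
throughout.

**Bonds.**  Per skeleton: all merge matchings × all increment distributions
(per-edge cap 3, weighted degree ≤ valence), each result re-sorted
bottom-up, rootings that put the `≥_m`-lighter half below a tied center edge
discarded, and survivors de-duplicated by a full serialization key.  Raw
assignment counts per skeleton are small, so the generate-and-canonicalize
route is both simple and exact.

**Carbon positions.**  Benzene nodes are processed in reverse BFS order
(adjacent node lists depend on descendants' positions).  Per node the
candidate lists are generated group-by-group — position 1 always goes to the
first group; merge groups take ring-adjacent pairs; an eligible root with a
first group of ≥ 3 equivalent neighbors takes its lists from a precomputed
table of dihedral orbit minima — and pruned by condition 4 immediately,
condition 5 at the root, condition 6 after full assignment.  Trees with no
symmetric-path candidates and no root merge factor into independent per-ring
choices, so counting is a product without materialization; only symmetric
trees pay for backtracking.  Symmetric-path candidates are precomputed at
the multiplicity level once per tree; per assignment only the position-list
part of the test reruns.

**Expansion.**  Benzene nodes become aromatic 6-cycles with substituents at
the listed carbons, merge pairs become fused 10-carbon bicyclics under the
geometry above, leftover valence becomes hydrogen.  SMILES/SDF writing and
canonicalization go through RDKit; SDF output kekulizes arbitrarily, which
is a format necessity and not a chemical claim.

## The brute-force oracle

Correctness of the canonical form is not argued, it is tested: an
independent oracle enumerates, for any instance with ≤ 8 contracted nodes,
every labeled tree (Prüfer sequences), every bond/merge assignment, and
every injective placement of ring substituents onto ring carbons, expands
each to an explicit graph and de-duplicates by canonical SMILES.  It shares
with the pipeline only the formula parser, the passive graph container and
the key function.  The default test suite sweeps 64 formulas covering
n_b ∈ {0,1,2} × n_n ∈ {0,1} — including instances that mix a biphenyl-type
benzene pair with a fused pair — and asserts both equal counts and equal
canonical-key sets; sweep sizes were chosen to keep the oracle side to a
couple of minutes of CPU.

## What the tests do and do not show

Reference per-formula counts (19 to ~2×10⁷ structures) and the worked
position-assignment example (36 normal trees: 16 asymmetric + 2×10
symmetric) are asserted end-to-end.  Desk-scale instances (≤ ~3.4×10⁵
structures, a few seconds to ~20 s each here) run in the default suite; the
three largest rows live in `tests_long/`, an explicit opt-in tier, because
they take minutes to an hour in an interpreted implementation.  The oracle
guarantees exactness only on small instances; for large ones correctness
rests on the published counts plus the fact that the same code path is
exercised at both scales.

## Parameters and conventions that matter

* **Label order** (`b > C > N > O > … > H`): any total order yields a valid
  canonical form; elements outside the default set are slotted between O and
  H by descending valence, overridable via config.  Counts are invariant to
  this choice; output order is not.
* **Valences** (C 4, N 3, O 2, H 1, b 6): multi-valent elements are modeled
  as distinct labels (e.g. a divalent carbon as its own label).
* **Maximum bond multiplicity 3**: standard chemistry; no quadruple bonds.
* **Merge matching**: at most one merge bond per benzene node — linear
  fusions beyond naphthalene (anthracene etc.) are out of scope.  A
  benzene–benzene edge not chosen as a merge bond is a biphenyl-type single
  bond.
* **Output order**: deterministic, implementation-defined (generation
  order); re-runs are byte-identical.

## Known limitations

No stereochemistry, no general polycyclics, no isotopes or formal charges
beyond user-declared labels, no ranking or drug-likeness filtering of the
output.  The oracle is exponential and guarded at 8 contracted nodes.
RDKit sanitization constrains expansion to chemically standard valences;
exotic user-defined labels enumerate and count correctly but may not
serialize to SMILES.
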