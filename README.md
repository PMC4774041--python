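# arenetree

Exhaustive, duplicate-free enumeration of **tree-like constitutional
isomers** whose only cycles are **benzene rings** and **naphthalene rings**.

Given a chemical formula (say `C8O3H10`), a number of benzene rings `n_b`
and a number of naphthalene rings `n_n`, `arenetree` generates every
non-isomorphic molecular graph with exactly that composition and ring
content — ortho/meta/para substitution patterns included — and can emit the
structures as SMILES or SDF, or just report the exact count.  Typical users
are people who need complete candidate sets: structure elucidation from a
known formula, chemical-space surveys, or building-block libraries for
virtual screening.

## The method in brief

A molecule is encoded as a *molecular tree*: each benzene ring is contracted
to a single node `b` of valence 6, and a naphthalene ring to two `b` nodes
joined by a *merge bond* (a double-weight edge standing for the two shared
carbons).  Hydrogens are implicit.  Enumeration then proceeds in three
stages, each emitting exactly one representative per isomorphism class:

1. **Skeletons** — all center-rooted, left-heavy node-labeled trees over the
   contracted node multiset (`num(b) = n_b + 2 n_n`,
   `num(C) = n_C − 6 n_b − 10 n_n`), siblings ordered by the multigraph
   order `≥_m`.
2. **Bonds** — `n_n` merge bonds placed on benzene–benzene edges (a
   matching), and the remaining increment budget
   `E = 1 + Σ_v (val(l(v)) − 2)/2` (summed over all nodes, implicit
   hydrogens included) distributed as double/triple bonds over edges not
   touching a ring.
3. **Carbon positions** — each benzene node receives a *carbon position
   list* `C_v`: which ring carbons (1..6, or 1..8 across a fused pair) its
   neighbors occupy, neighbors grouped into an *adjacent node list* `A_v` by
   subtree equivalence.  Normal-form conditions prune the ring symmetries:
   `C_v` must be minimal under the dihedral group of the hexagon (order 12),
   fused pairs at the root minimal under the naphthalene group (order 4),
   and *symmetric paths* — paths whose two halves carry mirror-equal
   subtrees — must be ordered under the assigned order `≥_C`.

The result is a bijection between emitted trees and molecules: expanding
every output yields pairwise non-isomorphic graphs, and every valid molecule
appears (both properties are enforced in the test suite by an independent
brute-force oracle on all small instances).

Kekulé alternation is not distinguished, stereoisomers are out of scope,
and tautomers are counted as distinct structures.

## Worked example

```sh
$ arenetree --formula C8H10 --benzene 1
Cc1ccccc1C
Cc1cccc(C)c1
Cc1ccc(C)cc1
CCc1ccccc1
```

Four isomers of C8H10 with one benzene ring: the three distinct ways of
placing two methyl groups on the ring (adjacent, one apart, opposite — the
dihedral symmetry collapses the other 12 raw position pairs) plus
ethylbenzene.  The same from Python:

```python
>>> from arenetree import EnumerationSpec, count_structures
>>> count_structures(EnumerationSpec.from_string("C8O3H10", n_b=1))
307
```

`arenetree --formula C12H12 --all-ring-combos` reports counts for every
feasible ring combination of a formula, and `arenetree selftest` runs the
small-instance oracle sweep.  Short narrative scripts live in `examples/`.

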