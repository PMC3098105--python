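# Methods

## The rDAG model and its path statistics

The ontology is a triple (T, Ξ, R): terms, the relation types
Ξ = {is_a, part_of}, and child→parent triples.  A virtual global root is
always materialised as the single parent of the aspect roots (biological
process, molecular function, cellular component), so `Depth(Root) = 0`,
every aspect root has depth 1, and two terms from different aspects share
no ancestor besides the root — their basis dot product is exactly 0.  The
two relation types are treated identically in every path computation; the
type is kept on the edge for downstream filtering only.  Other relation
types found in OBO input (`regulates` in particular) are dropped with a
logged count; obsolete terms are excluded and `alt_id` accessions resolve
to their canonical id.

Because terms may have several parents, a term has a *set* of root paths.
The quantities used by the measure are defined over that set:

* `Depth(t)`: edges on the **longest** root path.  Computed by dynamic
  programming over a topological order (children of the child→parent
  digraph processed after their parents), O(V+E) for the whole graph.
* `Ancestors(t)`: every member of any root path, including `t` and the
  root.  Reachability over parent edges.
* `LCAset(a, b)`: the common ancestors of maximal depth.  The depth value
  is unique; the set may contain several terms.
* `PL(t, s)`: for an ancestor `s` of `t`, the path length below `s` among
  root paths of `t` whose prefix up to `s` is a longest root path of `s`.
  Its minimum equals the shortest ascending parent-edge path from `t` to
  `s`, which is what the implementation computes (breadth-first ascent).
* `MinSPL(a, b)`: min over `LCAset` of the two shortest ascents.  When
  several LCAs minimise the sum the numeric value is unaffected; the
  reported `via` ancestor is the lexicographically smallest minimiser, a
  pure determinism choice.

The exhaustive definitions (explicit root-path enumeration) are exponential
in graph depth and live only in the test oracle
(`intelligo.synthetic.oracle_graph_stats`), guarded at 10^5 paths.  The
test suite proves the fast implementations equal the oracle exactly on 200
seeded random rDAGs and that the inequality
`Depth(a) + Depth(b) ≥ MinSPL(a,b) + 2·Depth(LCA)` holds on every pair,
with equality on trees.

## Weighting scheme

A vector coefficient is `w(g, t) · IAF(t)`.

* `w`: the greatest weight, under the active evidence-code list, among the
  codes linking gene and term.  All 17 codes (TAS, NAS, EXP, IDA, IPI,
  IMP, IGI, IEP, ISS, RCA, ISA, ISO, ISM, IGC, IC, ND, IEA) must be
  covered by a list.  Built-ins: `list1` (all 1.0), `list2` (TAS 1.0,
  NAS/IC 0.5, experimental 0.8, supervised-computational 0.6, ND 0,
  IEA 0.4), `list3` (= list2, IEA 0), `list4` (IEA 1.0, all else 0).
  Pairs whose retained weight is 0 are pruned; a gene pruned to nothing is
  a *missing value* downstream.
* `IAF(t) = log(G_tot / G_t)` in base 10.  The gene counts use **all**
  evidence codes regardless of the active list — only coefficients see the
  weights.  The corpus scope is one species and one GO aspect: `G_tot`
  counts genes with at least one annotation in the selected aspect; mixing
  aspects would count genes against axes that cannot appear in the vector
  space.  The log base is provably immaterial to the cosine (a global
  scalar cancels); base 10 matches common information-content practice.
  Both invariances (log base, global weight rescaling) are asserted
  numerically in the tests.

## The generalized cosine and its range

`sim(g, h) = g·h / (√(g·g)·√(h·h))` with
`g·h = Σ_ij α_i β_j (e_i·e_j)`.  The pairwise dot products lie in [0, 1],
but the implied Gram matrix is not guaranteed positive semi-definite, so
the full cosine is not provably ≤ 1.  Values are therefore reported
unclamped.  In practice none of the seeded random corpora exercised by the
test suite produced a value above 1 + 1e-9; self-similarity is asserted to
be 1 within 1e-9.  The orthogonal weighted cosine and SimGIC *are* bounded
by 1 (Cauchy–Schwarz; subset sums), and those two implementations strip
floating-point round-off at the bound.

Summation order inside one dot product is fixed (sorted term pairs), and
set-level means use exact float summation (`math.fsum`), so reruns and
argument-order swaps reproduce results bit for bit.

## Reference measures

* **Resnik/Lord**: term similarity is the IC of the LCA, with the maximum
  IC over multiple LCAs (the most informative common ancestor).  IC uses
  descendant-inclusive probabilities — a gene counts toward every ancestor
  of its terms — which is standard Resnik practice and deliberately
  distinct from the direct-count IAF.  Gene similarity is the mean over
  the n·m term pairs; values are normalised by the maximum over whatever
  collection is being evaluated, as a separate operation, so benchmark
  runs normalise over the whole collection.  An all-zero collection is
  left unscaled with a warning rather than divided by zero.
* **Al-Mubaid**: `exp(−f · mean MinSPL)` over the term-pair matrix,
  f = 0.2 by default (the value proposed by its authors), exposed as a
  parameter.
* **Weighted cosine**: orthogonal basis, coefficients are bare IAF values;
  only shared terms contribute to the dot product.
* **SimGIC**: annotation sets are extended with all ancestors (global root
  excluded, aspect roots retained), then IC-weighted Jaccard.  A union of
  zero total IC is undefined and yields MISSING with a warning.

## Benchmark statistics and missing values

Intra-set similarity is the mean over all n² ordered pairs **including the
diagonal**, exactly as the defining formula sums both indices
independently; `exclude_diagonal=True` provides the off-diagonal mean for
callers who prefer it.  Inter-set similarity is the mean over the n·m
cross pairs, so `inter(S, S) = intra(S)` by construction.  Discriminating
power is `(p−1)·intra(S_k) / Σ_{i≠k} inter(S_k, S_i)`; a zero denominator
raises a diagnostic error rather than returning infinity — it signals that
the measure cannot see the surrounding sets at all (this genuinely happens
for IC-based measures on fully branch-separated synthetic collections,
where every cross-branch LCA has IC 0).

A pair involving a gene with no usable annotation is MISSING: excluded
from numerator and denominator alike and counted per set, mirroring how
missing values are reported separately rather than scored 0.  The tests
assert conservation: the per-set count equals the number of ordered pairs
involving an empty-vector gene.

## Synthetic data

The generators are first-class, deterministic (one seeded NumPy stream per
call, no global state) and define the study conditions for all property
suites:

* `generate_rdag`: terms created in order, parents drawn only from earlier
  same-aspect terms — acyclic by construction; a second parent is added
  with probability `p_extra_parent` (0 yields a tree); depth capped at
  `max_depth_target`.  Oracle-equivalence suites use 12–15-term graphs
  with two aspects and `p_extra_parent` 0.35 over 200 seeds — small enough
  for exhaustive enumeration, large enough to exhibit multi-LCA and
  multi-depth cases.
* `generate_corpus`: each gene draws 2–4 terms of one aspect and an
  evidence code per record from a configurable mixture; the default is
  IEA-dominated (50%) with a substantial experimental/curated remainder,
  the regime real genome annotation sits in.  With `branch_assignment`,
  genes of a set draw terms only from their branch's descendants;
  `disjoint_branch_pair` picks the two largest disjoint same-aspect
  subtrees of a graph, and the resulting collections give discriminating
  power > 1 on every one of 50 seeds in the acceptance suite (20 genes,
  two sets, 30-term trees).
* `fixture_a`: the constant 10-term graph used by every worked example; it
  packs multiple root paths, a two-LCA pair, ancestor-descendant pairs and
  a cross-aspect pair into the smallest graph exhibiting them all.

What the synthetic data does **not** emulate: the size and term-frequency
skew of the real GO (tens of thousands of terms, heavy-tailed annotation
counts), inter-aspect annotation correlations, and curation biases between
species.  Passing suites therefore demonstrate correctness of the
computations and the contracts between them, not the field performance of
any measure on real annotation corpora.

## Numerical and design choices

* Depth, LCA and SPL are exact integer computations; no tolerances enter
  the graph layer.
* The pair-statistics cache stores exactly the values the direct route
  produces, plus a SHA-256 checksum of the edge set; loading against a
  different graph raises rather than silently reusing stale numbers.
  Similarities through the cache are asserted bit-identical to direct
  computation.
* NOT-qualified annotations are dropped with a count: a negated
  annotation is evidence of absence, not of function.
* Unknown evidence codes in input files skip the record with a warning;
  an evidence code missing from a user weight list is a configuration
  error (the built-ins cover all 17).
* The command-line layer is a thin wrapper; every computation is reachable
  as a library call with the same defaults.

## Known limitations

* Exhaustive verification is limited to small graphs by the exponential
  oracle; on real-GO-sized inputs correctness rests on the verified
  algorithms, not on re-enumeration.
* The cosine's upper bound is unproven (see above); downstream users who
  need a hard [0, 1] range should clamp explicitly.
* IC for Lord/SimGIC is computed from the loaded corpus only; there is no
  support for external, pre-published IC tables.
* Protein-level aggregation, GO-slim projection and cross-ontology
  mappings are out of scope.
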