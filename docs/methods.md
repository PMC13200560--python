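# Methods

## The model

A *characteristic* is a Boolean clinical variable ("photophobia",
"4 to 72 h").  A *disorder* is a negation-free Boolean formula over
characteristics, built from AND, OR and at-least-k-of-n connectives; an
at-least node's children are always plain variables, matching the way
the ICHD-3 phrases such criteria ("at least two of the following
four").  A *phenotype* is one conjunctive clause of the disorder's
disjunctive normal form: a complete, minimal set of characteristics
that satisfies the criteria.  The phenotype × characteristic 0/1 matrix
is the biadjacency matrix of a bipartite graph, and all downstream
analysis operates on that matrix.

There is deliberately no negation operator.  Negative clinical
statements are modelled as their own positive variables ("no
photophobia" is a column distinct from "photophobia"), because that is
how the classification itself treats them; the validator inventories
such present/absent pairs as informational output, and the diagnosis
engine warns — without blocking — when a response vector marks both
members of a pair present.

## Encoding conventions for the bundled ICHD-3 fixture

The bundled file `src/ichd_matrix/data/ichd3_primary.yaml` encodes the
primary headache disorders of the ICHD-3 down to the second
classification level, with the probable categories encoded as the
disjunction over dropping each lettered criterion in turn.
Complications of migraine, the episodic syndromes that may be
associated with migraine, and all secondary headaches are excluded, as
is the ubiquitous "not better accounted for by another diagnosis"
criterion (it would create a logical impasse and cannot be expressed
without negation).

Interpretation rules applied consistently:

- Discipline parlance stays one characteristic even when a connective
  is embedded in the phrase: "distinct and clearly remembered onset",
  "nausea and/or vomiting", "speech and/or language aura".
- Other "and/or" phrasings become OR.  A headache provoked by coughing
  AND by other Valsalva manoeuvres is simply a patient satisfying two
  cough-headache phenotypes at once, so encoding a "both" phenotype
  would be redundant.
- Overlapping time intervals are independent columns ("2 to 30 min"
  coexists with "15 to 180 min"); intervals are never decomposed.
- "Continuous" and "constant" are classification synonyms, resolved to
  "constant" at encoding time.  Canonicalization in code is purely
  typographic (lower-case, trimmed, internal whitespace collapsed) and
  never folds synonyms.
- The absence-of-autonomic-signs criteria of primary stabbing and
  hypnic headache are encoded as a disjunction over the individual
  negative characteristics (one negative per phenotype) rather than
  their conjunction.  This follows the published matrix structure of
  the classification's graph representation, where each stabbing/hypnic
  phenotype carries a single negative sign; it is a known semantic
  widening (a patient merely lacking lacrimation satisfies the
  criterion) and is flagged under limitations.
- Among the probable trigeminal autonomic cephalalgias, only probable
  cluster headache and probable hemicrania continua are encoded; the
  other probable TAC subforms are absent from the reference analyses
  this encoding was reconciled against.

Phenotype rows are named by the disorder slug plus a 1-based index in
canonical clause order (`ndph1`, `cm17`, …).  Probable-diagnosis slugs
start with `probable`, which is the row-label convention the basis
computation uses to drop them when asked.

## DNF expansion

Expansion returns the subsumption-free DNF: duplicates are merged and
any clause that is a superset of another is removed.  For the
negation-free fragment this is exactly the prime-implicant form, so
at-least-k expands to the k-element subsets only and no general Boolean
minimisation is needed.  AND combines child clause-sets by pairwise
union with incremental minimisation (keeping intermediate clause lists
minimal prevents exponential blow-up on the chronic-migraine criteria,
whose raw product would have ~17,500 clauses against 132 minimal ones).
Clause order is lexicographic over sorted label tuples: deterministic,
and invariant under reordering of OR children.  Because a row is a
set-valued phenotype, identical clauses arising through different
expansion paths are merged before numbering; row *sets* are therefore
reproducible even though any particular numbering convention is
arbitrary.

## Bipartite projection

Projection weights are exact integers computed sparsely as M·Mᵀ / Mᵀ·M
with the diagonal discarded; zero-weight pairs are absent edges, the
standard projection convention.  "Second highest weight" always means
the second largest *distinct* value together with all pairs attaining
it, not the second-ranked edge.  No statistical significance testing of
projection weights is performed (a random-graph null model is out of
scope).

## Markov clustering and parameter selection

The adjacency is the block matrix [[0, M], [Mᵀ, 0]] over phenotype
nodes (prefix `p:`) and characteristic nodes (prefix `c:`).  MCL
follows the standard loop: add self-loops (weight 1 — required for
convergence and the common reference default; the underlying
publication record is silent on the value), column-normalise, then
iterate expansion (matrix power e), inflation (elementwise power r,
renormalise) and pruning of entries below 1e-5 (renormalising again),
until the iterate changes by less than 1e-8 or 100 iterations elapse.
Clusters are the nonzero supports of attractor rows (nonzero diagonal);
identical clusters are merged, overlapping clusters are reported as-is,
and a node left uncovered by every attractor row becomes a singleton so
the clustering always covers the graph.  Non-convergence yields
best-effort clusters flagged as such.  All tolerances are fields of
`MCLParams` and are recorded with every result.

Parameters are selected in two stages: inflation is swept over
1.5–5.0 in steps of 0.1 at expansion 2, then expansion is swept over
the integers 2–9 at the selected inflation.  Each clustering is scored
with standard Newman–Girvan modularity on the unipartite view (not
Barber's bipartite modularity, matching the tooling convention this
package follows); overlapping nodes count toward their first-listed
cluster, ties in the argmax break toward the smaller parameter value.
The sweep bounds are a design choice — the grid end-points and step are
not dictated by anything in the classification — so the full Q-curve is
always reported alongside the argmax.

On the bundled encoding the selected optimum is inflation 2.0 /
expansion 2 (Q ≈ 0.49).  At high expansion the flow overshoots the
graph: 9-step expansion collapses the classification to 3 clusters at
inflation 1.5 and 5 at inflation 3.3.  The four nummular-headache
characteristics are connected by a logical AND and share no edge with
any other disorder, so they co-cluster at every parameter setting; this
makes nummular headache a convenient tracer for parameter effects, and
the acceptance script verifies the block stays intact across the whole
sensitivity grid.

## Exact row reduction

Gaussian elimination runs entirely in exact arithmetic: a
fraction-free integer scheme (cross-multiplication with per-row gcd
reduction) with rows normalised to leading ones only at the end, so no
floating-point epsilon can flip the rank.  Pivoting is deterministic:
first nonzero column left to right, first available row top to bottom.
Rank is invariant under row/column permutation, but pivot-column
*identity* depends on the declared column order, which is therefore
part of the result's contract (e.g. the NDPH direction is carried by
"constant" under the bundled column order; a different order could
elect "clearly remembered onset" instead).  On the bundled matrix the
basis for definitive diagnoses has 63 characteristics; including the
probable diagnoses, 73 of 103 columns are pivots.

## Diagnosis

`diagnose` computes M·v once and compares with the row sums; the
per-row score (M·v)ᵢ / rowsumᵢ is exposed for triage of near misses but
never participates in the decision.  Unanswered characteristics are
false — the formulation is strictly binary.  All satisfied phenotypes
and their disorders are reported, concurrent diagnoses included, since
removing the "not better accounted for" criterion removes any
precedence between disorders.  The row-sum rule is provably equivalent
to direct Boolean evaluation of each disorder's formula, and the test
suite checks this equivalence exhaustively over all response vectors on
generated criteria sets of up to 15 characteristics.

## What the synthetic generator emulates

The random criteria generator produces well-formed disorder formulas
with bounded variable budgets (so exhaustive truth-table oracles stay
at ≤ 2^15 evaluations), a configurable AND/OR mix and at-least-node
probability, and deterministic output per seed.  It emulates the
*structure* of criteria — nesting, connective mix, shared
characteristics between disorders — not their clinical content: labels
are abstract, negative-pair semantics are absent, and formula shapes
are not calibrated to the ICHD-3's.  Passing property tests on
generated criteria therefore demonstrates algebraic correctness
(DNF/truth-table equivalence, projection counting, the row-sum theorem,
rank agreement), not fidelity of any particular clinical encoding; the
bundled fixture's own tests carry that weight.

## Numerical and degenerate-input choices

- Matrix entries are uint8 0/1; readers reject non-binary cells with
  row/column coordinates and sniff comma vs semicolon delimiters and a
  BOM, since export dialects of spreadsheet tools vary.
- Empty criteria sets yield 0×0 matrices; empty edge files are written
  with valid headers.
- Modularity on an edgeless graph raises (undefined) rather than
  returning 0.
- Reconciliation between two matrices is label-based after
  canonicalization and permutation-invariant on both axes; cell
  mismatches are reported on the common sub-grid.

## Known limitations

- The bundled encoding is an interpretation.  Translation of
  criteria prose into logic involves editorial choices (documented
  above), and a differently reasonable encoder would produce a
  different matrix; counts that depend on the full row set (projection
  weight magnitudes, cluster counts, sweep optima) move with those
  choices even though structural findings (the dominance of the
  chronicity pair, the chronic-migraine frequency block, the isolation
  of nummular headache, the 63-dimensional definitive basis) are
  stable under the documented conventions.
- The OR-encoding of "no cranial autonomic symptoms" (stabbing/hypnic)
  widens the criteria semantics; diagnosis output for those two
  disorders should be read accordingly.
- MCL can produce overlapping clusters; modularity resolves overlaps
  deterministically but alternative resolutions would score slightly
  differently.
- No secondary headaches, no red-flag screening, no clinical decision
  support: the engine matches criteria and nothing else, and is not a
  substitute for clinical judgement.
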