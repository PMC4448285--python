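# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations of the pipeline, at the level of
detail a maintainer needs to change them safely.

## Inputs and data model

The pipeline consumes text that has already been tokenized, lemmatized,
POS-tagged and dependency-parsed; producing those annotations is an
external obligation (any standard NLP pipeline suffices) and the
parsed-corpus reader accepts any labeled dependency graph. Token
indices are 0-based and contiguous; all spans are half-open
`[start, end)`. Degenerate (disconnected) parses are legal input: path
finding reports "no path" for pairs in different components and the
pair is only counted in the diagnostics log.

HTML documents are reduced to heading/list structure. The flat heading
stream is rebuilt into a section tree — first `<h1>` as root, `<h2>`–`<h6>`
nested by level, each `<li>` attached to its nearest preceding heading —
so the heading path from title to list item is an ancestor walk. A
second `<h1>` is demoted to an opaque node: the document title is
assumed unique. Serializing the retained tree and re-parsing reproduces
it exactly, which the tests rely on.

## Entity matcher

Names and token windows (1–6 tokens; 6 covers the longest fixture
names without quadratic window blowup) are compared as sets of
character 3-grams over the lowercased, whitespace-normalized string,
padded with `n-1` boundary marks on both sides. Padding every string —
rather than only those shorter than `n` — keeps the gram universe
uniform and gives 1–2 character names non-empty sets; it slightly
raises similarity of strings sharing prefixes/suffixes, which the
configurable acceptance threshold absorbs.

MinHash signatures (default length 256) are computed by mixing a
per-function random seed into a 64-bit gram hash with a splitmix64
finalizer; banding (default 64 bands of 4 rows) gives candidate
retrieval with near-1 collision probability at Jaccard 0.7. The LSH
layer is only a pre-filter: every candidate is verified against the
exact Jaccard similarity, and the mention records that exact value, so
false positives below the threshold (default 0.7; the matcher threshold
is not prescribed anywhere and is exposed as configuration) are
impossible and only misses are stochastic. The hash seed (default 42)
fixes the index bit-for-bit.

Overlap resolution implements most-specific-type selection: among
mentions with an identical span, those whose deepest semantic type
(path length to the hierarchy root; unknown codes count as depth 0 with
a warning) is maximal are kept, ties keeping all. Spans strictly
contained in a surviving span are suppressed. There is no further
entity disambiguation — by design, the type signatures downstream are
the mechanism that prunes implausible readings.

## Pattern gathering

The mention head is the leftmost span token whose governor (if any)
lies outside the span. Shortest paths are computed by BFS on the
undirected dependency graph: direction is deliberately ignored because
natural extraction paths routinely run against edge direction. Among
equally short paths the lexicographically smallest index sequence is
chosen, making output deterministic. The path token set is closed over
`neg`/`amod`/`advmod` dependent edges; taking the fixpoint (modifiers
of modifiers included) makes expansion idempotent, and on typical
parses one step already is the fixpoint. Patterns store lemmas in
surface order with mention-internal tokens removed; an empty rendering
discards the pair. Entity tokens themselves are never part of the
stored pattern.

Arguments are recorded in surface order (left mention first). Swapped
argument extractions are a known, accepted error class; type signatures
catch the asymmetric cases downstream.

## Distant supervision

"Pattern q occurs in sentence s" is interpreted as subsequence
containment of q in some pattern gathered in s — this is what makes
mined subsequences usable as generalizations of over-specific phrases.
Confidence counts distinct sentences, so repeated occurrences within a
sentence do not inflate the statistic. `CX(R)` is implemented as the
complement of `SX(R)` within all seed pairs, which makes the
denominator identical across relations; when every seed pair belongs to
one relation, confidences over relations sum to 1 for any subsequence
with a non-zero denominator.

Defaults: minimum subsequence support 2 (the smallest value that
generalizes at all); seed-pattern selection strictly above 0.3.
Pattern-to-seed-pattern matching uses token-set Jaccard (duplicates
collapsed; multiplicity is not meaningful after subsequence
generalization) times confidence, ties broken by higher confidence,
then lexicographic relation id. Occurrences of one triple are merged
with noisy-or, `w = 1 - prod(1 - w_i)`: bounded in (0, 1], monotone in
added evidence, and treating supporting sentences as independent —
over-counts correlated evidence such as syndicated text, which desk
fixtures do not contain. Subsequence enumeration is exponential in
pattern length and therefore truncated at 20 tokens (with a warning);
gathered dependency-path patterns are far shorter in practice.

Generalization is realized purely via frequent subsequences; a
wildcard/POS-masking variant would need gathered POS context and is
out of scope.

## Consistency reasoning

Type signatures act as a pre-filter rather than as clauses: they are
hard constraints anyway, and pruning first shrinks the NP-hard
hypothesis space. An entity satisfies a signature side if any of its
types is the signature type or a descendant of it.

Clause encoding: soft unit per surviving candidate (weight = candidate
weight); hard `(~f | ~g)` per instantiated mutual exclusion; hard unit
per seed fact that is also a candidate (seeds are never injected as
facts on their own). The only exclusion shipped by default is
`sideEffect(x, y)` vs `treats(y, x)`; the constraint file is
user-extensible YAML. Two seed-pinned facts joined by an exclusion are
reported as infeasible at grounding time, naming the facts.

The solver runs dominating-unit-clause preprocessing to fixpoint (fix
any literal whose unit-clause weight is at least the total weight of
clauses containing its negation), then Johnson's greedy heuristic:
variables in descending order of incident soft weight (id as
tie-break), each assigned the sign with the larger expected satisfied
soft weight, where an open clause with `u` unassigned literals counts
`w(1 - 2^-u)`. Hard clauses are honored by unit propagation after every
assignment instead of by infinite weights inside the expectation:
infinite terms on both sides would make the comparison degenerate,
while propagation never violates a satisfiable hard clause of the
unit/binary form produced here and keeps the greedy score a pure
soft-weight expectation. Internally "hard" weighs total-soft-plus-one
in the DUC dominance test. The procedure is deterministic; with only
soft unit clauses and no hard clauses it is exactly optimal, and on
random small instances the tests verify at least half the exhaustive
optimum with zero hard-clause violations.

## Evaluation statistics

The Wilson score interval (two-sided, z from the standard normal
quantile) and Fleiss' kappa are computed via statsmodels behind this
package's interface; the tests check both against independent
closed-form transcriptions. Sequential evaluation consumes judgments
until the interval width drops below the target (defaults alpha 0.05,
width 0.05); an exhausted finite population is flagged as a census and
reports width 0 by convention. Kappa is undefined (an error) when
chance agreement equals 1.

## Synthetic fixtures

The generator emulates the statistical structure the confidence stage
assumes: per relation (defaults: all 13, with the reference seed-fact
counts summing to 467) it plants two pattern phrases, three sentences
pairing each phrase with distinct seed pairs of its relation (the
co-occurrence plan, realized exactly and audited by an independent
scan), and two harvest sentences per phrase with fresh type-consistent
pairs. Optional ingredients: noise sentences of junk tokens (default
rate 0), type-violating distractor sentences (for ablation tests),
surface perturbations at a stated edit rate (to exercise approximate
matching), synonym rows (rate 0.2) and near-miss names (rate 0.1).

The dependency skeleton is a chain from the left entity head through
the phrase tokens to the right entity head, entity-internal tokens
hanging off their heads — the simplest graph whose shortest path equals
the planted phrase. Generated words are unique *and* pairwise
dissimilar (trigram Jaccard below 0.5, except a near-miss against its
own source): without that margin, random 5–8 letter words collide above
the 0.7 match threshold often enough to cross entities. Phrase
vocabularies are disjoint from names and from other relations'
phrases, so pattern-to-relation attribution is unambiguous by
construction.

What passing on these fixtures does **not** show: robustness to real
parse errors, coreference, abbreviations, colloquial variants,
correlated duplicated text, or genuinely ambiguous patterns — the
documented error sources of dictionary-based extraction. The fixtures
measure that each stage implements its contract, not corpus-level
precision.

## Problem sizes

The default test and demonstration corpora use 13 relations, 467 seed
facts, roughly 130 planted sentences and a few hundred dictionary
rows; the oracle suites use 200 random trees (up to 15 tokens) and 200
random Max-Sat instances (up to 12 hypotheses, exhaustively solvable).
These sizes exercise every code path while keeping any single test in
seconds.

## Known limitations

- No NED beyond most-specific-type selection; no abbreviation
  expansion, spelling correction or coreference.
- Confidence treats the seed set as closed-world: a true pair absent
  from all seeds contributes nothing.
- The heading sequence of a DOM pattern is opaque text; headings are
  not themselves entity-recognized.
- The exclusion inventory ships with a single documented constraint;
  richer inventories must be supplied by configuration.
- `no_pattern_stats` approximates "keep all patterns" as
  confidence-1 acceptance of every mined subsequence that co-occurs at
  least once with a relation's seeds; this is an interpretation, not an
  identity.
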