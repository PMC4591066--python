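# Methods

## The model

`toolfinder` treats tool discovery as a two-channel matching problem
between an interpreted clinical question and a semantically annotated tool
repository.

A question is assumed to contain two contexts: sentences stating what the
user *has* (given data) and sentences stating what they *want* (the
research question). Concepts recognized in given-data sentences become
input terms and are matched against what a tool consumes; concepts in
question sentences become output terms and are matched against what a tool
produces. This input/output framing is what lets the engine distinguish
tools that answer the whole question (matched on both sides) from tools
usable only as one stage of a pipeline.

### Sentence partition

A sentence is classified as a question sentence when it contains one of
the desiderative markers `I would like`, `I want`, `I need`, a question
mark, or starts with an interrogative word; otherwise it is given data.
If no marker fires anywhere, the last sentence is taken as the question.
The marker list is a heuristic chosen to cover common phrasings of
clinical information needs; questions with several given-data sentences
partition correctly as long as the desiderative sentence is marked.

### Concept recognition and merging

Two recognizers run over within-sentence n-grams (n ≤ 5, runs never
starting or ending on a stop-word or punctuation):

* the **ontology recognizer** scores a candidate against every term of an
  OBO ontology by summing per-field weights over matched fields,
  `(id·10)+(name·10)+(synonym·6)+(subset·3)+(is_a·3)+(def·2)+(comment·1)`.
  A field matches when the normalized query occurs as a contiguous token
  run in the normalized field text; indicators are binary, so the score is
  a property of *which* fields match, biased by design toward id and name.
  Every term carries a `root_branch` (Data, Format, Operation, Topic,
  Identifier, Other) derived by transitive is_a traversal; if a term
  reaches several roots the branch is chosen by the fixed priority
  Data > Format > Operation > Topic > Identifier, with a logged warning.
* the **lexicon recognizer** is an exact dictionary lookup against a
  TSV lexicon of (surface, concept id, semantic types); lemma-level lookup
  is attempted only when the surface lookup fails. Its scores are
  configuration, not output of a model: 6 for a surface match, 4 for a
  lemma match, values chosen so that ontology scores (1..10) can fall on
  either side of them and both merge directions stay reachable. The
  recognizer is a pluggable interface: anything producing (concept id,
  semantic types, score) triples can stand behind it.

Overlapping annotations merge deterministically: on an identical span an
ontology term from the Data or Format branch always wins (the engine's
purpose is software discovery, so format concepts outrank medical
homonyms); otherwise the higher score wins, ties preferring the ontology
source. Remaining partial overlaps resolve longest-span-first, then
left-most. The output is a non-overlapping, span-sorted annotation set.

### Prime categories and patterns

Semantic types are coarsened by a bundled, user-overridable table into 27
prime categories — 23 consolidated from UMLS semantic types plus 4 from
the ontology branches. Types absent from the table fall back to the
generic `Biomedical` bucket with a warning. The 24 combined patterns
(e.g. *Drug for Disease*, *Patient took Drug for Disease*) ship as
packaged TSV data; user patterns append after the built-ins.

Pattern matching is deliberately permissive: slots bind to distinct
annotations of one sentence in any order, consecutive bound spans may be
separated by at most 8 tokens, and a template's connector literals are
optional evidence (they raise a confidence flag) rather than requirements.
This is the weakest semantics consistent with the observed behaviour that
*Drug for Disease* must fire on a sentence reading "lung cancer … treated
with carboplatin", where the categories appear in reverse order and no
literal "for" links them. When several combined patterns overlap on the
same annotations, the one binding more slots wins, then the lower pattern
id; annotations consumed by a combined pattern do not additionally emit
prime-category matches. Fired patterns annotate the focused query but do
not change tool scores.

## Scoring and ranking

With input terms *I*, output terms *O* and a tool's facet annotations, the
score is

    score = 1.0 · (in + out) + 0.25 · tags

where `in` counts appearances of terms of *I* among the tool's input-facet
concepts, `out` likewise for *O* on the output facet, and `tags` counts
appearances of any query term in the description facet (summary + tags).
An "appearance" is matched primarily by concept-id equality and secondarily
by normalized-surface equality — both channels are needed because query
terms and tool annotations may come from different vocabularies. Each
annotated occurrence on the tool side counts at most once.

Tools with score ≤ 1.0 are discarded (the threshold is exclusive: exactly
1.0 is dropped). Admitted tools matched on both sides form the unique
list; the rest the single list; both sort by score descending, then name.
Pipelines are ordered pairs (A, B) of distinct single-list tools where A
has input-side matches, B has output-side matches, and A's output formats
intersect B's input formats (compared case-insensitively); unique-list
tools never join pipelines, and chains are limited to two stages.

When the term channel admits no tool at all, the engine retries with the
semantic channel: prime-category equality instead of term equality, same
point values. This fallback is coarser and is flagged in the result.

## Evaluation

Precision = 100·tp/(tp+fp), recall = 100·tp/(tp+fn) against a gold set of
relevant tools; the best rank of a full solver is the 1-based position of
the first retrieved tool the gold standard marks as able to answer the
question alone. Printed percentages round half-away-from-zero to integers
(14.47 → 14, 17.17 → 17); unrounded values are kept alongside. The
free-text baseline feeds the whole question, minus stop-words, to the
repository's occurrence-count full-text ranking with no interpretation.

## Synthetic fixtures

The package is fully testable offline through generated fixtures:

* a 40-term mini-ontology with the five branch roots and planted terms
  (`VCF` under Format via a two-hop is_a chain, a `KEGG pathways`
  Operation term, two definitions sharing a unique token to exercise
  definition-level search);
* a 60-entry UMLS-style lexicon covering every concept the two bundled
  clinical questions need, plus filler biomedical vocabulary;
* a 30-tool repository in which eight planted tools are constructed
  backwards from target score decompositions — their input/output/summary
  fields carry literal query-term occurrences so that, against the bundled
  questions, they receive exactly the intended (in, out, tag) counts
  (4.75 = 3+1+3·0.25, 3.75, 2.25, a 1.0 threshold case, one linked
  pipeline pair, and a question with no possible pipeline);
* gold-standard TSVs per question.

Generation is deterministic (same seed ⇒ byte-identical files; the seed
shuffles only filler-tool order) and self-verifying: after writing, the
generator runs the real recognizer and scorer over the files and raises,
naming the case, if any planted count drifts. Problem sizes (30 tools, 40
terms, 60 lexicon entries) are desk-scale by design: large enough to give
every code path a target, small enough that the whole suite runs in
seconds.

What the fixtures do **not** emulate: real registry prose (summaries are
single clean sentences, so recognizer recall on messy descriptions is
untested), UMLS-scale ambiguity (one concept per surface, so word-sense
disambiguation never arises), and realistic gold-set sizes (fixture recall
numbers are not comparable to a production deployment). Passing tests
therefore certify the mechanics of interpretation, merging, scoring and
composition — not retrieval quality on real repositories.

## Numerical and design choices

* Field weights, point values (1.0 / 0.25) and the exclusive 1.0 threshold
  are configuration (`FieldWeights`, `ScoringConfig`) with the documented
  defaults.
* Term-index tie-breaks: score descending, term id ascending. List
  tie-breaks: score descending, tool name ascending. Pipeline ordering:
  combined score descending, then names.
* Degenerate inputs: empty/whitespace questions raise an empty-input
  error; a question with no recognizable concepts raises an empty-query
  error surfaced to the user; an empty search query returns an empty hit
  list; tools may have empty facet lists and simply score 0 there.
* The NLP chain is rule-based and English-only; its lemmatizer and tagger
  are adequate for short clinical questions but are not a general-purpose
  parser — no dependency structure, negation or temporality is extracted.

## Known limitations

* Pattern-match semantics (gap bound, optional connectors, unordered
  slots) are heuristic commitments; corpora with stricter syntax would
  support stricter rules.
* The lexicon score scale relative to ontology scores is a configured
  surrogate; a real concept-mapping service would bring its own scale and
  the merge rules would need recalibration.
* Pipelines are exactly two stages and chain only through declared format
  labels; semantic compatibility beyond format identity is not checked.
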