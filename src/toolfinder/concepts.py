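"""Concept recognition: map n-gram spans to ontology/lexicon concepts.

Two recognizers run over the n-gram candidates: the ontology recognizer
(field-weighted search over the bioinformatics ontology) and a pluggable
dictionary recognizer over a biomedical lexicon carrying UMLS-style
semantic types.  Overlapping results are merged by precedence rules:

1. on a span matched by both sources, the ontology term wins when it lies
   in the data/format branch (tool discovery favours software concepts);
2. otherwise the higher-scoring annotation wins;
3. remaining overlaps resolve longest-span-first, then left-most, then
   again by score.

The dictionary recognizer is a deliberate stand-in for a full biomedical
concept-mapping service: downstream logic only consumes (concept id,
semantic types, score) triples, so any recognizer producing those can be
plugged in.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Protocol

from .ontology import TermIndex, normalize
from .textproc import NGram

#: Lexicon surrogate scores: exact surface match vs lemma-level match.
#: Chosen so the higher-score merge rule is exercisable in both directions
#: against ontology field scores (which range 1..10); configuration, not
#: hard-coded behaviour.
LEXICON_SURFACE_SCORE = 6.0
LEXICON_LEMMA_SCORE = 4.0

FORMAT_BRANCHES = frozenset({"Data", "Format"})


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    concept_id: str
    preferred_name: str
    semantic_types: tuple[str, ...]


@dataclass(frozen=True)
class ConceptAnnotation:
    """A recognized span of the source text bound to one concept."""

    char_span: tuple[int, int]
    surface: str
    concept_id: str
    source: str                      # "EDAM" | "LEXICON"
    score: float
    semantic_types: tuple[str, ...]
    root_branch: str = ""            # ontology annotations only
    prime_category: str = ""         # filled by the pattern engine
    sentence_index: int = 0
    sentence_role: str = ""          # "GIVEN" | "QUESTION"

    def overlaps(self, other: "ConceptAnnotation") -> bool:
        return self.char_span[0] < other.char_span[1] \
            and other.char_span[0] < self.char_span[1]

    @property
    def length(self) -> int:
        return self.char_span[1] - self.char_span[0]


class Recognizer(Protocol):
    """Anything that turns n-grams into concept annotations."""

    def recognize(self, ngrams: list[NGram]) -> list[ConceptAnnotation]: ...


def load_lexicon(path: str | Path) -> dict[str, list[LexiconEntry]]:
    """Load a TSV lexicon (surface, concept_id, preferred_name,
    pipe-separated semantic_types) keyed by normalized surface."""
    table: dict[str, list[LexiconEntry]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            types = tuple(t.strip() for t in row["semantic_types"].split("|")
                          if t.strip())
            if not types:
                raise ValueError(
                    f"lexicon entry {row['surface']!r} has no semantic types")
            entry = LexiconEntry(
                surface=normalize(row["surface"]),
                concept_id=row["concept_id"],
                preferred_name=row["preferred_name"],
                semantic_types=types,
            )
            table.setdefault(entry.surface, [])
            if all(e.concept_id != entry.concept_id
                   for e in table[entry.surface]):
                table[entry.surface].append(entry)
    return table


class EdamRecognizer:
    """Ontology recognizer backed by the field-weighted term index."""

    def __init__(self, index: TermIndex):
        self.index = index

    def recognize(self, ngrams: list[NGram]) -> list[ConceptAnnotation]:
        out = []
        for ng in ngrams:
            hit = self.index.best(ng.text)
            if hit is None:
                continue
            branch = self.index.terms[hit.term_id].root_branch
            out.append(ConceptAnnotation(
                char_span=ng.char_span, surface=ng.text,
                concept_id=hit.term_id, source="EDAM", score=hit.score,
                semantic_types=(f"EDAM {branch}",), root_branch=branch,
                sentence_index=ng.sentence_index,
            ))
        return out


class LexiconRecognizer:
    """Exact dictionary lookup on surface form, falling back to lemmas."""

    def __init__(self, lexicon: dict[str, list[LexiconEntry]],
                 surface_score: float = LEXICON_SURFACE_SCORE,
                 lemma_score: float = LEXICON_LEMMA_SCORE):
        self.lexicon = lexicon
        self.surface_score = surface_score
        self.lemma_score = lemma_score

    def recognize(self, ngrams: list[NGram]) -> list[ConceptAnnotation]:
        out = []
        for ng in ngrams:
            entries = self.lexicon.get(normalize(ng.text))
            score = self.surface_score
            if not entries:  # lemma-level lookup only after surface fails
                entries = self.lexicon.get(normalize(ng.lemma_text))
                score = self.lemma_score
            if not entries:
                continue
            entry = max(entries, key=lambda e: e.concept_id)
            out.append(ConceptAnnotation(
                char_span=ng.char_span, surface=ng.text,
                concept_id=entry.concept_id, source="LEXICON", score=score,
                semantic_types=entry.semantic_types,
                sentence_index=ng.sentence_index,
            ))
        return out


def merge(edam_hits: Iterable[ConceptAnnotation],
          lexicon_hits: Iterable[ConceptAnnotation]) -> list[ConceptAnnotation]:
    """Merge the two recognizers' annotations into a non-overlapping set.

    Span-coincident candidates are reduced first (ontology data/format
    precedence, then higher score); partial overlaps are then resolved
    longest-span-first, left-most, highest score.  Output is sorted by
    span and deterministic.
    """
    by_span: dict[tuple[int, int], list[ConceptAnnotation]] = {}
    for ann in list(edam_hits) + list(lexicon_hits):
        by_span.setdefault(ann.char_span, []).append(ann)

    candidates = [resolve_coincident(group) for group in by_span.values()]
    # longest first, then left-most, then score desc, then source for ties
    candidates.sort(key=lambda a: (-a.length, a.char_span[0], -a.score,
                                   a.source, a.concept_id))
    kept: list[ConceptAnnotation] = []
    for ann in candidates:
        if not any(ann.overlaps(k) for k in kept):
            kept.append(ann)
    kept.sort(key=lambda a: a.char_span)
    return kept


def resolve_coincident(group: list[ConceptAnnotation]) -> ConceptAnnotation:
    """Pick one annotation among span-coincident candidates.

    Rule 1: an ontology annotation from the data/format branch always wins.
    Rule 2: otherwise the highest score wins (ties: EDAM first, then id).
    """
    fmt = [a for a in group
           if a.source == "EDAM" and a.root_branch in FORMAT_BRANCHES]
    pool = fmt if fmt else group
    return max(pool, key=lambda a: (a.score, a.source == "EDAM",
                                    a.concept_id))


def annotate_text(text: str, edam: Recognizer, lexicon: Recognizer,
                  n_max: int = 5) -> list[ConceptAnnotation]:
    """Convenience pipeline: analyze -> n-grams -> recognize both -> merge,
    attaching sentence roles from the question partition."""
    from .textproc import analyze, ngrams, partition_question

    tokens = analyze(text)
    grams = ngrams(tokens, n_max=n_max)
    merged = merge(edam.recognize(grams), lexicon.recognize(grams))
    part = partition_question(tokens)
    out = []
    for ann in merged:
        role = "QUESTION" if ann.sentence_index in part.question_sentences \
            else "GIVEN"
        out.append(replace(ann, sentence_role=role))
    return out
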