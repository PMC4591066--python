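"""Prime categories and combined semantic patterns.

Every recognized concept is coarsened into one of 27 *prime categories*:
23 consolidated from UMLS semantic types (Disease, Drug, Patient, ...) and
4 from the bioinformatics ontology branches (EDAM Data/Format, EDAM Topic,
EDAM Operation, EDAM Identifier).  On top of the prime categories sits a
registry of 24 *combined patterns* — templates such as "Drug for Disease"
whose firing carries clinical meaning (here, treatment).

Pattern-match semantics are deliberately loose: slots bind to distinct
annotations co-occurring in one sentence, in any order, with a bounded
token gap between consecutive bound spans; the literal connector words of
a template ("for", "took") are optional evidence that raises a confidence
flag, never a requirement.  This is a heuristic reading — the single
worked example available ("lung cancer ... treated with carboplatin"
firing "Drug for Disease") rules out strict order and mandatory
connectors, and nothing stricter is testable.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

from .concepts import ConceptAnnotation

log = logging.getLogger("toolfinder")

PRIME_CATEGORIES: tuple[str, ...] = (
    "Disease", "Drug", "Medical Procedure", "Tissue", "Biomedical", "Cell",
    "Organism Function", "Finding", "Body Part", "Gene", "Clinical Attribute",
    "Patient", "Diagnosis", "Age", "Molecular Sequence", "Device", "Symptom",
    "Virus", "Injury or Poisoning", "Vitamin", "Laboratory", "Food",
    "Temporal Concept",
    "EDAM Data/Format", "EDAM Topic", "EDAM Operation", "EDAM Identifier",
)

UMLS_CATEGORIES = PRIME_CATEGORIES[:23]
EDAM_CATEGORIES = PRIME_CATEGORIES[23:]

#: Generic bucket for semantic types absent from the category map.
FALLBACK_CATEGORY = "Biomedical"

#: Max tokens allowed between consecutive bound annotations of a pattern.
MAX_SLOT_GAP_TOKENS = 8


class UnknownCategoryError(ValueError):
    """A pattern file names a slot that is not a prime category."""


class MissingTypeError(ValueError):
    """An annotation carries no semantic types to categorize."""


@dataclass(frozen=True)
class Pattern:
    pattern_id: int
    label: str
    slots: tuple[str, ...]
    connectors: tuple[str, ...] = ()


@dataclass(frozen=True)
class PatternMatch:
    """A fired pattern; pattern_id 0 denotes a prime-category match."""

    pattern_id: int
    label: str
    bound: tuple[ConceptAnnotation, ...]
    sentence_index: int
    connector_evidence: bool = False

    @property
    def is_prime(self) -> bool:
        return self.pattern_id == 0


# ---------------------------------------------------------------------------
# Category map

def load_category_map(path: str | Path | None = None) -> dict[str, str]:
    """Semantic-type label -> prime category.  Default table is bundled;
    a user TSV (semantic_type, prime_category) replaces it."""
    if path is None:
        text = resources.files("toolfinder.data") \
            .joinpath("category_map.tsv").read_text()
        rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    table: dict[str, str] = {}
    for row in rows:
        cat = row["prime_category"]
        if cat not in PRIME_CATEGORIES:
            raise UnknownCategoryError(
                f"category map assigns unknown category {cat!r}")
        table[row["semantic_type"]] = cat
    return table


def map_category(semantic_types: list[str] | tuple[str, ...],
                 category_map: dict[str, str] | None = None) -> str:
    """First mapped semantic type (in lexicon order) decides the category;
    labels absent from the map fall back to the generic bucket."""
    if not semantic_types:
        raise MissingTypeError("annotation has no semantic types")
    if category_map is None:
        category_map = load_category_map()
    for st in semantic_types:
        if st in category_map:
            return category_map[st]
    log.warning("no category mapping for %s; using %s",
                semantic_types, FALLBACK_CATEGORY)
    return FALLBACK_CATEGORY


def categorize(annotations: list[ConceptAnnotation],
               category_map: dict[str, str] | None = None
               ) -> list[ConceptAnnotation]:
    """Return annotations with prime_category filled in."""
    if category_map is None:
        category_map = load_category_map()
    return [replace(a, prime_category=map_category(a.semantic_types,
                                                   category_map))
            for a in annotations]


# ---------------------------------------------------------------------------
# Pattern registry

def _parse_rows(rows: list[dict], start_id_check: bool) -> list[Pattern]:
    patterns = []
    for row in rows:
        slots = tuple(s.strip() for s in row["slots"].split("|") if s.strip())
        for s in slots:
            if s not in PRIME_CATEGORIES:
                raise UnknownCategoryError(f"unknown category in slot: {s!r}")
        conns = tuple(c.strip() for c in row.get("connectors", "").split("|")
                      if c.strip()) if row.get("connectors") else ()
        patterns.append(Pattern(pattern_id=int(row["pattern_id"]),
                                label=row["label"], slots=slots,
                                connectors=conns))
    return patterns


def load_registry(path: str | Path | None = None) -> list[Pattern]:
    """The 24 built-in combined patterns, plus user patterns appended from
    a TSV (pattern_id, label, slots, connectors).  Duplicate labels are
    rejected."""
    text = resources.files("toolfinder.data").joinpath("patterns.tsv").read_text()
    builtin = _parse_rows(list(csv.DictReader(text.splitlines(),
                                              delimiter="\t")), True)
    registry = list(builtin)
    if path is not None:
        with open(path, newline="") as fh:
            user = _parse_rows(list(csv.DictReader(fh, delimiter="\t")), False)
        labels = {p.label for p in registry}
        for p in user:
            if p.label in labels:
                raise ValueError(f"duplicate pattern label {p.label!r}")
            next_id = max(q.pattern_id for q in registry) + 1
            registry.append(replace(p, pattern_id=next_id))
            labels.add(p.label)
    return registry


# ---------------------------------------------------------------------------
# Matching

_WORD = re.compile(r"\S+")


def _token_gap(text: str, left: ConceptAnnotation,
               right: ConceptAnnotation) -> int:
    between = text[left.char_span[1]:right.char_span[0]]
    return len(_WORD.findall(between))


def _bind(pattern: Pattern, anns: list[ConceptAnnotation],
          text: str | None) -> tuple[ConceptAnnotation, ...] | None:
    """Greedy unordered binding of slots to distinct sentence annotations."""
    need: dict[str, int] = {}
    for s in pattern.slots:
        need[s] = need.get(s, 0) + 1
    chosen: list[ConceptAnnotation] = []
    for ann in anns:  # sentence order
        if need.get(ann.prime_category, 0) > 0:
            chosen.append(ann)
            need[ann.prime_category] -= 1
    if any(v > 0 for v in need.values()):
        return None
    if text is not None:
        for left, right in zip(chosen, chosen[1:]):
            if _token_gap(text, left, right) > MAX_SLOT_GAP_TOKENS:
                return None
    return tuple(chosen)


def match_patterns(annotations: list[ConceptAnnotation],
                   registry: list[Pattern] | None = None,
                   text: str | None = None) -> list[PatternMatch]:
    """Fire combined patterns per sentence, then emit prime-category
    matches for annotations not consumed by any combined pattern.

    Overlapping combined candidates are reduced by preferring more bound
    slots, then the lower pattern id.  Output order: sentence, then
    combined matches by pattern id, then prime matches in span order.
    """
    if registry is None:
        registry = load_registry()
    by_sent: dict[int, list[ConceptAnnotation]] = {}
    for a in sorted(annotations, key=lambda a: a.char_span):
        by_sent.setdefault(a.sentence_index, []).append(a)

    out: list[PatternMatch] = []
    for sent_idx, anns in sorted(by_sent.items()):
        candidates: list[PatternMatch] = []
        sent_text_lc = text.lower() if text else ""
        for pat in registry:
            bound = _bind(pat, anns, text)
            if bound is None:
                continue
            evidence = bool(pat.connectors) and all(
                c.lower() in sent_text_lc for c in pat.connectors)
            candidates.append(PatternMatch(
                pattern_id=pat.pattern_id, label=pat.label, bound=bound,
                sentence_index=sent_idx, connector_evidence=evidence))
        candidates.sort(key=lambda m: (-len(m.bound), m.pattern_id))
        kept: list[PatternMatch] = []
        used: set[tuple[int, int]] = set()
        for cand in candidates:
            spans = {a.char_span for a in cand.bound}
            if spans & used:
                continue
            kept.append(cand)
            used |= spans
        out.extend(sorted(kept, key=lambda m: m.pattern_id))
        for ann in anns:
            if ann.char_span not in used and ann.prime_category:
                out.append(PatternMatch(pattern_id=0, label=ann.prime_category,
                                        bound=(ann,), sentence_index=sent_idx))
    return out
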