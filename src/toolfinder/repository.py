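"""Flat-file tool repository with semantic annotations and three query
strategies: full text, tags, and parameters (input/output formats).

The original deployment kept tool records in a relational store with
full-text search; here records live in JSON (canonical) or TSV, and the
full-text strategy is occurrence-count ranking over name + summary + tags.
Each record is annotated by feeding its text fields to the concept
recognizers, yielding input / output / description concept lists that the
discovery engine scores against an interpreted question.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .concepts import ConceptAnnotation, Recognizer, merge
from .ontology import normalize
from .textproc import analyze, ngrams, stop_words, EmptyInputError

QUERY_MODES = ("full_text", "tags", "parameters")


class RepositoryError(ValueError):
    pass


@dataclass(frozen=True)
class ToolRecord:
    name: str
    summary: str = ""
    tags: tuple[str, ...] = ()
    link: str = ""
    input_formats: tuple[str, ...] = ()
    output_formats: tuple[str, ...] = ()
    category: str = ""


@dataclass(frozen=True)
class ToolAnnotation:
    """Concept annotations of one tool, split by facet.

    Occurrence counts matter downstream (the scorer pays per appearance),
    so every recognized occurrence is kept, not just distinct concepts.
    """

    tool_name: str
    input_concepts: tuple[ConceptAnnotation, ...] = ()
    output_concepts: tuple[ConceptAnnotation, ...] = ()
    description_concepts: tuple[ConceptAnnotation, ...] = ()


def _record_from_dict(d: dict) -> ToolRecord:
    if not d.get("name"):
        raise RepositoryError("tool record without a name")
    return ToolRecord(
        name=d["name"], summary=d.get("summary", ""),
        tags=tuple(d.get("tags", ())), link=d.get("link", ""),
        input_formats=tuple(d.get("input_formats", ())),
        output_formats=tuple(d.get("output_formats", ())),
        category=d.get("category", ""),
    )


class Repository:
    """An ordered, name-unique collection of tool records."""

    def __init__(self, records: list[ToolRecord]):
        self.records: dict[str, ToolRecord] = {}
        for rec in records:
            if rec.name in self.records:
                raise RepositoryError(f"duplicate tool name {rec.name!r}")
            self.records[rec.name] = rec
        self.annotations: dict[str, ToolAnnotation] = {}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> ToolRecord:
        return self.records[name]

    def annotate_all(self, edam: Recognizer, lexicon: Recognizer) -> None:
        for name, rec in self.records.items():
            self.annotations[name] = annotate_tool(rec, edam, lexicon)

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            [asdict(r) for r in self.records.values()], indent=1))


def save_annotated(repo: Repository, path: str | Path) -> None:
    """Persist records plus their facet annotations as one JSON document."""
    doc = {
        "records": [asdict(r) for r in repo.records.values()],
        "annotations": {name: asdict(ann)
                        for name, ann in repo.annotations.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _ann_from_dict(d: dict) -> ConceptAnnotation:
    d = dict(d)
    d["char_span"] = tuple(d["char_span"])
    d["semantic_types"] = tuple(d["semantic_types"])
    return ConceptAnnotation(**d)


def load_annotated(path: str | Path) -> Repository:
    """Load a document written by :func:`save_annotated`."""
    doc = json.loads(Path(path).read_text())
    repo = Repository([_record_from_dict(r) for r in doc["records"]])
    for name, ann in doc["annotations"].items():
        repo.annotations[name] = ToolAnnotation(
            tool_name=ann["tool_name"],
            input_concepts=tuple(_ann_from_dict(a)
                                 for a in ann["input_concepts"]),
            output_concepts=tuple(_ann_from_dict(a)
                                  for a in ann["output_concepts"]),
            description_concepts=tuple(_ann_from_dict(a)
                                       for a in ann["description_concepts"]),
        )
    return repo


def load_repository(path: str | Path) -> Repository:
    """Load a JSON array (canonical) or TSV of tool records.

    Duplicate names and records lacking a name are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".tsv":
        with open(path, newline="") as fh:
            rows = []
            for row in csv.DictReader(fh, delimiter="\t"):
                for k in ("tags", "input_formats", "output_formats"):
                    row[k] = [v.strip() for v in row.get(k, "").split("|")
                              if v.strip()]
                rows.append(row)
    else:
        rows = json.loads(path.read_text())
    return Repository([_record_from_dict(r) for r in rows])


def _recognize_free_text(text: str, edam: Recognizer, lexicon: Recognizer
                         ) -> tuple[ConceptAnnotation, ...]:
    if not text.strip():
        return ()
    toks = analyze(text)
    grams = ngrams(toks)
    return tuple(merge(edam.recognize(grams), lexicon.recognize(grams)))


def annotate_tool(record: ToolRecord, edam: Recognizer,
                  lexicon: Recognizer) -> ToolAnnotation:
    """Annotate one record facet by facet.

    Input/output concepts come from the format-label lists (labels are
    treated as text, so ontology format precedence types them naturally);
    description concepts from summary + tags.  Deterministic and
    idempotent for fixed recognizer data.
    """
    return ToolAnnotation(
        tool_name=record.name,
        input_concepts=_recognize_free_text(
            ". ".join(record.input_formats), edam, lexicon),
        output_concepts=_recognize_free_text(
            ". ".join(record.output_formats), edam, lexicon),
        description_concepts=_recognize_free_text(
            ". ".join([record.summary] + list(record.tags)) if
            (record.summary or record.tags) else "", edam, lexicon),
    )


def _count_occurrences(haystack: str, needle: str) -> int:
    """Non-overlapping occurrences of a normalized token run."""
    hay = normalize(haystack).split()
    ned = normalize(needle).split()
    if not ned:
        return 0
    count = i = 0
    while i <= len(hay) - len(ned):
        if hay[i:i + len(ned)] == ned:
            count += 1
            i += len(ned)
        else:
            i += 1
    return count


def query(repo: Repository, mode: str, terms: list[str]) -> list[str]:
    """Rank tool names by one of the three discovery strategies.

    full_text  — occurrence count of the terms over name + summary + tags;
    tags       — matching restricted to the tag list;
    parameters — matching restricted to input/output format labels.
    Ties break by name; zero-count tools are omitted.
    """
    if mode not in QUERY_MODES:
        raise RepositoryError(f"unknown query mode {mode!r}; "
                              f"expected one of {QUERY_MODES}")
    scored = []
    for name, rec in repo.records.items():
        if mode == "full_text":
            fields = [rec.name, rec.summary] + list(rec.tags)
        elif mode == "tags":
            fields = list(rec.tags)
        else:
            fields = list(rec.input_formats) + list(rec.output_formats)
        text = " . ".join(fields)
        count = sum(_count_occurrences(text, t) for t in terms)
        if count > 0:
            scored.append((-count, name))
    return [name for _, name in sorted(scored)]


def content_tokens(text: str) -> list[str]:
    """Non-stop-word, non-punctuation tokens of a free-text question."""
    stops = stop_words()
    try:
        toks = analyze(text)
    except EmptyInputError:
        return []
    return [t.text for t in toks
            if not t.is_punct and t.text.lower() not in stops]
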