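"""Field-weighted search over an OBO ontology of bioinformatics terms.

Every ontology term is flattened into seven searchable fields (id, name,
synonyms, subsets, is_a parent labels, definition, comment).  A query
scores against a term by summing, over the fields it matches, a per-field
weight.  The default weights — (10, 10, 6, 3, 3, 2, 1) — deliberately bias
ranking toward the id and the preferred name: an exact name hit always
outranks any hit confined to a definition or comment.

The index is a plain inverted token index persisted as a single JSON file,
so builds are reproducible without a search server.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet

log = logging.getLogger("toolfinder")

#: Root-branch priority used when a term reaches more than one root.
ROOT_PRIORITY = ["Data", "Format", "Operation", "Topic", "Identifier"]

#: Field order shared by FieldWeights and the match vector.
FIELDS = ("id", "name", "synonym", "subset", "is_a", "def", "comment")


class OboFormatError(ValueError):
    """Raised when the OBO file cannot be parsed; names the offending stanza."""


class OntologyCycleError(ValueError):
    """Raised when the is_a relation contains a cycle; carries the cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("cyclic is_a relation: " + " -> ".join(cycle + cycle[:1]))


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology entry with the seven weighted fields."""

    id: str
    name: str
    synonyms: tuple[str, ...] = ()
    subsets: tuple[str, ...] = ()
    is_a: tuple[str, ...] = ()
    definition: str = ""
    comment: str = ""
    root_branch: str = "Other"


@dataclass(frozen=True)
class FieldWeights:
    """Per-field weights of the term-scoring formula.

    Defaults implement (id*10)+(name*10)+(synonym*6)+(subset*3)+(is_a*3)
    +(def*2)+(comment*1).
    """

    id_w: float = 10.0
    name_w: float = 10.0
    synonym_w: float = 6.0
    subset_w: float = 3.0
    is_a_w: float = 3.0
    def_w: float = 2.0
    comment_w: float = 1.0

    def as_tuple(self) -> tuple[float, ...]:
        return (self.id_w, self.name_w, self.synonym_w, self.subset_w,
                self.is_a_w, self.def_w, self.comment_w)


@dataclass(frozen=True)
class TermHit:
    term_id: str
    score: float
    matched_fields: tuple[str, ...]


_PUNCT_EDGE = re.compile(r"^\W+|\W+$")


def normalize(text: str) -> str:
    """Lowercase, collapse whitespace, strip punctuation at token edges."""
    tokens = []
    for tok in text.lower().split():
        tok = _PUNCT_EDGE.sub("", tok)
        if tok:
            tokens.append(tok)
    return " ".join(tokens)


def _tokens(text: str) -> list[str]:
    return normalize(text).split()


def _contains_subsequence(haystack: list[str], needle: list[str]) -> bool:
    """True if needle occurs as a contiguous run inside haystack."""
    if not needle:
        return False
    n = len(needle)
    return any(haystack[i:i + n] == needle for i in range(len(haystack) - n + 1))


def _first(value) -> str:
    if isinstance(value, (list, tuple)):
        return str(value[0]) if value else ""
    return str(value) if value is not None else ""


_SYNONYM_TEXT = re.compile(r'"([^"]*)"')


def load_obo(path: str | Path) -> list[OntologyTerm]:
    """Parse an OBO 1.2 flat file into :class:`OntologyTerm` records.

    Obsolete terms are dropped.  Each surviving term is assigned a
    ``root_branch`` by transitive is_a traversal to a root term; when a term
    reaches several roots, :data:`ROOT_PRIORITY` breaks the tie (a warning
    is logged).  Raises :class:`OboFormatError` on unparseable input and
    :class:`OntologyCycleError` if is_a is cyclic.
    """
    path = Path(path)
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=False)
    except Exception as exc:  # obonet raises assorted ValueError subclasses
        raise OboFormatError(f"unparseable OBO file {path}: {exc}") from exc

    # obonet edges point child -> parent for is_a
    isa = nx.DiGraph()
    names: dict[str, str] = {}
    data_by_id: dict[str, dict] = {}
    for node, data in graph.nodes(data=True):
        if str(data.get("is_obsolete", "false")).lower() == "true":
            continue
        names[node] = data.get("name", "")
        data_by_id[node] = data
        isa.add_node(node)
    for node in data_by_id:
        for parent in data_by_id[node].get("is_a", []):
            if parent in data_by_id:
                isa.add_edge(node, parent)

    if not nx.is_directed_acyclic_graph(isa):
        cycle = [u for u, _ in nx.find_cycle(isa)]
        raise OntologyCycleError(cycle)

    roots = {n for n in isa.nodes if isa.out_degree(n) == 0}

    def branch_of(node: str) -> str:
        reachable = nx.descendants(isa, node) | {node}
        hit_roots = sorted(names.get(r, "") for r in (reachable & roots))
        known = [b for b in ROOT_PRIORITY if b in hit_roots]
        if len(known) > 1:
            log.warning("term %s reaches multiple roots %s; keeping %s",
                        node, known, known[0])
        if known:
            return known[0]
        return "Other"

    terms = []
    for node, data in sorted(data_by_id.items()):
        syns = tuple(_SYNONYM_TEXT.search(s).group(1)
                     for s in data.get("synonym", [])
                     if _SYNONYM_TEXT.search(s))
        definition = ""
        raw_def = data.get("def", "")
        m = _SYNONYM_TEXT.search(_first(raw_def))
        definition = m.group(1) if m else _first(raw_def)
        terms.append(OntologyTerm(
            id=node,
            name=data.get("name", ""),
            synonyms=syns,
            subsets=tuple(data.get("subset", [])),
            is_a=tuple(p for p in data.get("is_a", []) if p in data_by_id),
            definition=definition,
            comment=_first(data.get("comment", "")),
            root_branch=branch_of(node),
        ))
    return terms


def _field_texts(term: OntologyTerm, parent_names: dict[str, str] | None = None
                 ) -> dict[str, list[str]]:
    """The searchable text(s) behind each of the seven fields."""
    parents = [parent_names.get(p, p) if parent_names else p for p in term.is_a]
    return {
        "id": [term.id],
        "name": [term.name],
        "synonym": list(term.synonyms),
        "subset": list(term.subsets),
        "is_a": parents,
        "def": [term.definition],
        "comment": [term.comment],
    }


def score_term(query: str, term: OntologyTerm, weights: FieldWeights = FieldWeights(),
               parent_names: dict[str, str] | None = None) -> TermHit:
    """Score a normalized query against one term.

    A field matches when the query's token sequence occurs contiguously in
    the field's normalized text; each matched field contributes its weight
    once (binary indicator, not occurrence counts).
    """
    q = _tokens(query)
    matched: list[str] = []
    score = 0.0
    for fname, w in zip(FIELDS, weights.as_tuple()):
        texts = _field_texts(term, parent_names)[fname]
        if any(_contains_subsequence(_tokens(t), q) for t in texts if t):
            matched.append(fname)
            score += w
    return TermHit(term_id=term.id, score=score, matched_fields=tuple(matched))


class TermIndex:
    """Inverted token index over ontology terms, JSON-persistable."""

    def __init__(self, terms: Iterable[OntologyTerm],
                 weights: FieldWeights = FieldWeights()):
        self.terms: dict[str, OntologyTerm] = {t.id: t for t in terms}
        self.weights = weights
        self.parent_names = {tid: t.name for tid, t in self.terms.items()}
        self._postings: dict[str, set[str]] = {}
        for tid, term in self.terms.items():
            for texts in _field_texts(term, self.parent_names).values():
                for text in texts:
                    for tok in _tokens(text):
                        self._postings.setdefault(tok, set()).add(tid)

    def search(self, query: str, top_k: int = 20) -> list[TermHit]:
        """Ranked hits (score desc, id asc); only scores > 0; at most top_k."""
        qtoks = _tokens(query)
        if not qtoks:
            return []
        candidates: set[str] = set()
        for tok in qtoks:
            candidates |= self._postings.get(tok, set())
        hits = []
        for tid in candidates:
            hit = score_term(query, self.terms[tid], self.weights,
                             self.parent_names)
            if hit.score > 0:
                hits.append(hit)
        hits.sort(key=lambda h: (-h.score, h.term_id))
        return hits[:top_k]

    def best(self, query: str) -> TermHit | None:
        hits = self.search(query, top_k=1)
        return hits[0] if hits else None

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "weights": asdict(self.weights),
            "terms": [asdict(t) for t in self.terms.values()],
            "postings": {tok: sorted(tids) for tok, tids
                         in sorted(self._postings.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=0, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "TermIndex":
        payload = json.loads(Path(path).read_text())
        terms = [OntologyTerm(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in t.items()})
                 for t in payload["terms"]]
        return cls(terms, FieldWeights(**payload["weights"]))
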