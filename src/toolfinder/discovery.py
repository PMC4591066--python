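"""Question interpretation, tool scoring, ranking and pipeline composition.

The interpreted question yields two focused query channels: concepts from
*given-data* sentences become input terms (matched against what a tool
consumes) and concepts from *question* sentences become output terms
(matched against what a tool produces).  A second, semantic channel keeps
only the prime categories of those terms and is used as a fallback when
the term channel admits nothing.

Scoring follows fixed point rules:

* one point for each appearance of a query term in the tool's input or
  output description;
* a quarter point for each appearance in the functional, textual
  description (summary + tags);
* tools scoring one point or less are dropped.

Tools matching the given side in their inputs AND the question side in
their outputs can answer the question alone (*unique list*); the rest form
the *single list*, and pairs of single-list tools whose data formats chain
(output formats of a given-side solver intersect input formats of a
question-side solver) are proposed as two-stage pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .concepts import ConceptAnnotation
from .ontology import normalize
from .patterns import PatternMatch
from .repository import Repository, ToolAnnotation
from .textproc import QuestionPartition


class EmptyQueryError(ValueError):
    """The question yielded no recognizable concepts."""


@dataclass(frozen=True)
class QueryTerm:
    concept_id: str
    surface: str
    prime_category: str

    @property
    def norm_surface(self) -> str:
        return normalize(self.surface)


@dataclass(frozen=True)
class FocusedQuery:
    input_terms: tuple[QueryTerm, ...]
    output_terms: tuple[QueryTerm, ...]
    semantic_query: tuple[str, ...]          # prime categories, both sides
    fired_patterns: tuple[PatternMatch, ...] = ()


@dataclass(frozen=True)
class ScoringConfig:
    """Point rules of the ranker; defaults are the published rules."""

    io_point: float = 1.0
    tag_point: float = 0.25
    min_score_exclusive: float = 1.0


@dataclass(frozen=True)
class ScoredTool:
    tool_name: str
    in_matches: int
    out_matches: int
    tag_matches: int
    score: float
    in_surfaces: tuple[str, ...] = ()
    out_surfaces: tuple[str, ...] = ()
    tag_surfaces: tuple[str, ...] = ()

    @property
    def is_unique(self) -> bool:
        """Can individually answer: matched on both the input side and the
        output side."""
        return self.in_matches >= 1 and self.out_matches >= 1

    def decomposition(self) -> str:
        """Human-readable score breakdown, e.g. ``4.75 = 3 (in) + 1 (out)
        + 0.75 (tag)`` or ``3 (in)`` when a single whole-point part equals
        the score."""
        parts = []
        if self.in_matches:
            parts.append(f"{self.in_matches} (in)")
        if self.out_matches:
            parts.append(f"{self.out_matches} (out)")
        if self.tag_matches:
            parts.append(f"{self.tag_matches}*0.25 (tag)")
        score = f"{self.score:g}"
        if not parts:
            return score
        if len(parts) == 1 and not self.tag_matches:
            return parts[0]
        return f"{score} = " + " + ".join(parts)


@dataclass(frozen=True)
class ToolPipeline:
    first_tool: str
    second_tool: str
    linking_formats: tuple[str, ...]
    combined_score: float


def build_query(partition: QuestionPartition,
                annotations: list[ConceptAnnotation],
                patterns: tuple[PatternMatch, ...] | list[PatternMatch] = ()
                ) -> FocusedQuery:
    """Split the merged annotations into input / output query terms by
    sentence role and collect the semantic (category) channel."""
    if not annotations:
        raise EmptyQueryError("no recognizable concepts in the question")
    inputs, outputs = [], []
    for ann in annotations:
        term = QueryTerm(concept_id=ann.concept_id, surface=ann.surface,
                         prime_category=ann.prime_category)
        if ann.sentence_role == "QUESTION" or (
                not ann.sentence_role and
                ann.sentence_index in partition.question_sentences):
            outputs.append(term)
        else:
            inputs.append(term)
    return FocusedQuery(
        input_terms=tuple(inputs), output_terms=tuple(outputs),
        semantic_query=tuple(t.prime_category for t in inputs + outputs),
        fired_patterns=tuple(patterns),
    )


def _count_term(term: QueryTerm, concepts: tuple[ConceptAnnotation, ...],
                by_category: bool = False) -> tuple[int, list[str]]:
    """Appearances of one query term in a facet's concept list.

    Concept-id equality is the primary channel; normalized-surface
    equality is the fallback for concepts from different vocabularies.
    Each annotated occurrence counts once.
    """
    count = 0
    surfaces = []
    for c in concepts:
        if by_category:
            hit = bool(term.prime_category) \
                and c.prime_category == term.prime_category
        else:
            hit = (term.concept_id == c.concept_id
                   or term.norm_surface == normalize(c.surface))
        if hit:
            count += 1
            surfaces.append(c.surface)
    return count, surfaces


def _count_side(terms: tuple[QueryTerm, ...],
                concepts: tuple[ConceptAnnotation, ...],
                by_category: bool) -> tuple[int, list[str]]:
    total, surfaces = 0, []
    counted: set[int] = set()
    for term in terms:
        for i, c in enumerate(concepts):
            if i in counted:
                continue
            n, _ = _count_term(term, (c,), by_category)
            if n:
                counted.add(i)
                total += 1
                surfaces.append(c.surface)
    return total, surfaces


def score_tool(query: FocusedQuery, annotation: ToolAnnotation,
               cfg: ScoringConfig = ScoringConfig(),
               by_category: bool = False) -> ScoredTool:
    """Score one tool against the focused query.

    ``by_category`` switches to the semantic channel (prime-category
    matching with the same point values)."""
    in_n, in_s = _count_side(query.input_terms, annotation.input_concepts,
                             by_category)
    out_n, out_s = _count_side(query.output_terms, annotation.output_concepts,
                               by_category)
    all_terms = tuple(query.input_terms) + tuple(query.output_terms)
    tag_n, tag_s = _count_side(all_terms, annotation.description_concepts,
                               by_category)
    score = cfg.io_point * (in_n + out_n) + cfg.tag_point * tag_n
    return ScoredTool(tool_name=annotation.tool_name, in_matches=in_n,
                      out_matches=out_n, tag_matches=tag_n, score=score,
                      in_surfaces=tuple(in_s), out_surfaces=tuple(out_s),
                      tag_surfaces=tuple(tag_s))


def rank_and_partition(scored: list[ScoredTool],
                       cfg: ScoringConfig = ScoringConfig()
                       ) -> tuple[list[ScoredTool], list[ScoredTool]]:
    """Drop tools at or below the score threshold, then split into the
    unique list (solve-alone tools) and the single list, each sorted by
    score descending then name."""
    admitted = [t for t in scored if t.score > cfg.min_score_exclusive]
    key = lambda t: (-t.score, t.tool_name)
    unique = sorted((t for t in admitted if t.is_unique), key=key)
    single = sorted((t for t in admitted if not t.is_unique), key=key)
    return unique, single


def compose_pipelines(single: list[ScoredTool], repo: Repository
                      ) -> list[ToolPipeline]:
    """Two-stage pipelines: a given-side solver (input matches) chained to
    a question-side solver (output matches) through at least one shared
    data format, ordered by combined score descending."""
    given_solvers = [t for t in single if t.in_matches >= 1]
    question_solvers = [t for t in single if t.out_matches >= 1]
    out = []
    for a in given_solvers:
        for b in question_solvers:
            if a.tool_name == b.tool_name:
                continue
            fmts_a = {normalize(f): f for f in
                      repo[a.tool_name].output_formats}
            fmts_b = {normalize(f) for f in repo[b.tool_name].input_formats}
            shared = sorted(fmts_a[k] for k in fmts_a.keys() & fmts_b)
            if shared:
                out.append(ToolPipeline(
                    first_tool=a.tool_name, second_tool=b.tool_name,
                    linking_formats=tuple(shared),
                    combined_score=a.score + b.score))
    out.sort(key=lambda p: (-p.combined_score, p.first_tool, p.second_tool))
    return out


@dataclass(frozen=True)
class DiscoveryResult:
    query: FocusedQuery
    unique: tuple[ScoredTool, ...]
    single: tuple[ScoredTool, ...]
    pipelines: tuple[ToolPipeline, ...]
    used_semantic_fallback: bool = False

    def all_retrieved(self) -> list[str]:
        """Ranked tool names across all three sections (unique, pipeline
        members in order, then single), duplicate-free."""
        names: list[str] = []
        for t in self.unique:
            names.append(t.tool_name)
        for p in self.pipelines:
            for n in (p.first_tool, p.second_tool):
                if n not in names:
                    names.append(n)
        for t in self.single:
            if t.tool_name not in names:
                names.append(t.tool_name)
        return names


def discover(query: FocusedQuery, repo: Repository,
             cfg: ScoringConfig = ScoringConfig()) -> DiscoveryResult:
    """Run the full term-channel discovery; if it admits no tool, retry on
    the semantic (prime-category) channel with the same point rules."""
    if not repo.annotations:
        raise ValueError("repository is not annotated")

    def run(by_category: bool):
        scored = [score_tool(query, ann, cfg, by_category)
                  for ann in repo.annotations.values()]
        unique, single = rank_and_partition(scored, cfg)
        return unique, single

    fallback = False
    unique, single = run(False)
    if not unique and not single:
        unique, single = run(True)
        fallback = bool(unique or single)
    pipelines = compose_pipelines(single, repo)
    return DiscoveryResult(query=query, unique=tuple(unique),
                           single=tuple(single), pipelines=tuple(pipelines),
                           used_semantic_fallback=fallback)
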