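"""toolfinder: semantic discovery of bioinformatics tools from clinical
questions.

A free-text clinical question is interpreted into ontology-anchored input
and output terms, matched against a semantically annotated tool
repository, and answered with ranked single tools and two-stage tool
pipelines.
"""

from .ontology import (FieldWeights, OntologyTerm, TermHit, TermIndex,
                       load_obo, normalize, score_term)
from .textproc import (NGram, QuestionPartition, Token, analyze, ngrams,
                       partition_question, stop_words)
from .concepts import (ConceptAnnotation, EdamRecognizer, LexiconEntry,
                       LexiconRecognizer, annotate_text, load_lexicon, merge)
from .patterns import (EDAM_CATEGORIES, PRIME_CATEGORIES, UMLS_CATEGORIES,
                       Pattern, PatternMatch, categorize, load_category_map,
                       load_registry, map_category, match_patterns)
from .repository import (Repository, ToolAnnotation, ToolRecord,
                         annotate_tool, load_annotated, load_repository,
                         query, save_annotated)
from .discovery import (DiscoveryResult, FocusedQuery, ScoredTool,
                        ScoringConfig, ToolPipeline, build_query,
                        compose_pipelines, discover, rank_and_partition,
                        score_tool)
from .evaluation import (EvalResult, GoldStandard, evaluate, load_gold,
                         round_half_away, run_baseline)
from .fixtures import (FixtureSpec, PlantedCase, QUESTION_1, QUESTION_2,
                       make_lexicon, make_mini_ontology, make_tool_repo,
                       write_fixtures)

__version__ = "0.1.0"


def interpret(text: str, index: TermIndex,
              lexicon: dict[str, list[LexiconEntry]],
              n_max: int = 5) -> FocusedQuery:
    """Full interpretation chain: NLP analysis, concept recognition and
    merging, categorization, pattern matching, focused-query assembly."""
    edam = EdamRecognizer(index)
    lex = LexiconRecognizer(lexicon)
    anns = categorize(annotate_text(text, edam, lex, n_max=n_max))
    fired = tuple(match_patterns(anns, text=text))
    part = partition_question(analyze(text))
    return build_query(part, anns, fired)
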