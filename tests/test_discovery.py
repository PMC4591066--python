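"""Focused queries, the point-rule scorer, list partition and pipelines."""

import pytest

from toolfinder import QUESTION_1, QUESTION_2, interpret
from toolfinder.concepts import ConceptAnnotation
from toolfinder.discovery import (EmptyQueryError, FocusedQuery, QueryTerm,
                                  ScoredTool, ScoringConfig, build_query,
                                  compose_pipelines, discover,
                                  rank_and_partition, score_tool)
from toolfinder.ontology import normalize
from toolfinder.repository import Repository, ToolAnnotation, ToolRecord
from toolfinder.textproc import QuestionPartition


def test_question1_query_terms(index, lexicon):
    q = interpret(QUESTION_1, index, lexicon)
    ins = {normalize(t.surface) for t in q.input_terms}
    outs = {normalize(t.surface) for t in q.output_terms}
    assert {"lung cancer", "carboplatin", "adverse effects"} <= ins
    assert {"literature", "drug"} <= outs


def test_question2_query_terms(index, lexicon):
    q = interpret(QUESTION_2, index, lexicon)
    ins = {normalize(t.surface) for t in q.input_terms}
    outs = {normalize(t.surface) for t in q.output_terms}
    assert "mirna" in ins
    assert {"gene expression", "kegg pathways"} <= outs


def test_question_only_input_empty_is_fine(index, lexicon):
    q = interpret("I want to find literature about a drug.", index, lexicon)
    assert q.input_terms == ()
    assert len(q.output_terms) >= 2


def test_no_concepts_raises_empty_query():
    part = QuestionPartition((), (0,))
    with pytest.raises(EmptyQueryError):
        build_query(part, [])


def _concept(surface, cid, role="", sent=0, span=(0, 1)):
    return ConceptAnnotation(char_span=span, surface=surface, concept_id=cid,
                             source="LEXICON", score=6.0,
                             semantic_types=("x",), sentence_role=role,
                             sentence_index=sent)


def _brute_count(terms, concepts):
    """Independent appearance counter: each tool-side occurrence matched
    by any query term (concept id or normalized surface) counts once."""
    total = 0
    for c in concepts:
        if any(t.concept_id == c.concept_id
               or normalize(t.surface) == normalize(c.surface)
               for t in terms):
            total += 1
    return total


@pytest.mark.parametrize("tool", ["OncoStat API", "TumorAtlas API",
                                  "PharmLex API", "MicroRNA PathFinder",
                                  "LitMiner API", "VarScope"])
def test_score_decomposition_matches_brute_force(tool, index, lexicon, repo):
    """score = 1.0*(in+out) + 0.25*tags, with counts agreeing with an
    independent term counter, on every planted and one inert fixture."""
    for question in (QUESTION_1, QUESTION_2):
        q = interpret(question, index, lexicon)
        ann = repo.annotations[tool]
        st = score_tool(q, ann)
        assert st.in_matches == _brute_count(q.input_terms,
                                             ann.input_concepts)
        assert st.out_matches == _brute_count(q.output_terms,
                                              ann.output_concepts)
        all_terms = q.input_terms + q.output_terms
        assert st.tag_matches == _brute_count(all_terms,
                                              ann.description_concepts)
        assert st.score == pytest.approx(
            1.0 * (st.in_matches + st.out_matches) + 0.25 * st.tag_matches)


def test_zero_appearances_zero_score(index, lexicon, repo):
    q = interpret(QUESTION_1, index, lexicon)
    st = score_tool(q, repo.annotations["TreeCraft"])
    assert st.score == 0.0


def _scored(name, score, in_m=0, out_m=0, tag_m=0):
    return ScoredTool(tool_name=name, in_matches=in_m, out_matches=out_m,
                      tag_matches=tag_m, score=score)


def test_threshold_drops_score_at_or_below_one():
    scored = [_scored("A", 4.75, in_m=3, out_m=1, tag_m=3),
              _scored("B", 4.0, in_m=3, out_m=1),
              _scored("C", 4.0, in_m=1, out_m=3),
              _scored("D", 1.0, in_m=1),
              _scored("E", 0.5, tag_m=2)]
    unique, single = rank_and_partition(scored)
    names = {t.tool_name for t in unique + single}
    assert names == {"A", "B", "C"}


def test_unique_list_ordering_score_then_name():
    scored = [_scored("Zeta", 4.0, in_m=3, out_m=1),
              _scored("Alpha", 4.0, in_m=1, out_m=3),
              _scored("Top", 4.75, in_m=3, out_m=1, tag_m=3)]
    unique, single = rank_and_partition(scored)
    assert [t.tool_name for t in unique] == ["Top", "Alpha", "Zeta"]
    assert single == []


def test_unique_requires_both_sides():
    scored = [_scored("InOnly", 3.0, in_m=3), _scored("OutOnly", 3.0,
                                                      out_m=3)]
    unique, single = rank_and_partition(scored)
    assert unique == []
    assert {t.tool_name for t in single} == {"InOnly", "OutOnly"}


def test_question1_lists(q1_result):
    assert [t.tool_name for t in q1_result.unique] == ["OncoStat API"]
    assert q1_result.unique[0].decomposition() == \
        "4.75 = 3 (in) + 1 (out) + 3*0.25 (tag)"
    singles = [t.tool_name for t in q1_result.single]
    assert singles[0] == "TumorAtlas API"
    assert "ThresholdCase API" not in singles


def test_question2_lists(q2_result):
    assert [t.tool_name for t in q2_result.unique] == ["MicroRNA PathFinder"]
    assert q2_result.unique[0].decomposition() == "3 = 1 (in) + 2 (out)"
    assert q2_result.pipelines == ()


def test_pipeline_composition_shared_format():
    repo = Repository([
        ToolRecord(name="A", output_formats=("TSV",)),
        ToolRecord(name="B", input_formats=("TSV", "CSV")),
    ])
    single = [_scored("A", 2.0, in_m=2), _scored("B", 2.0, out_m=2)]
    pipes = compose_pipelines(single, repo)
    assert len(pipes) == 1
    assert (pipes[0].first_tool, pipes[0].second_tool) == ("A", "B")
    assert pipes[0].linking_formats == ("TSV",)


def test_pipeline_requires_direction_and_distinct_tools():
    repo = Repository([
        ToolRecord(name="A", output_formats=("TSV",),
                   input_formats=("TSV",)),
    ])
    single = [_scored("A", 2.0, in_m=1, out_m=0)]
    assert compose_pipelines(single, repo) == []


def test_question1_pipeline_is_sound(q1_result, repo):
    """The planted pipeline's linking format must be verifiable from the
    raw repository records alone."""
    assert len(q1_result.pipelines) == 1
    p = q1_result.pipelines[0]
    first = repo[p.first_tool]
    second = repo[p.second_tool]
    for fmt in p.linking_formats:
        assert fmt in first.output_formats
        assert fmt in second.input_formats
    unique_names = {t.tool_name for t in q1_result.unique}
    assert unique_names.isdisjoint({p.first_tool, p.second_tool})


def test_semantic_fallback_when_terms_miss():
    """If no tool matches at term level, prime-category matching with the
    same points takes over."""
    ann = ToolAnnotation(
        tool_name="CatTool",
        input_concepts=(
            ConceptAnnotation((0, 7), "aspirin", "C-OTHER", "LEXICON", 6.0,
                              ("x",), prime_category="Drug"),),
        output_concepts=(
            ConceptAnnotation((0, 5), "fever", "C-OTHER2", "LEXICON", 6.0,
                              ("x",), prime_category="Symptom"),))
    repo = Repository([ToolRecord(name="CatTool")])
    repo.annotations["CatTool"] = ann
    q = FocusedQuery(
        input_terms=(QueryTerm("C-A", "carboplatin", "Drug"),),
        output_terms=(QueryTerm("C-B", "headache", "Symptom"),),
        semantic_query=("Drug", "Symptom"))
    res = discover(q, repo)
    assert res.used_semantic_fallback
    assert [t.tool_name for t in res.unique] == ["CatTool"]
    assert res.unique[0].score == 2.0


def test_all_retrieved_duplicate_free(q1_result):
    names = q1_result.all_retrieved()
    assert len(names) == len(set(names))
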