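"""Concept recognizers and the annotation merge rules."""

import itertools

import pytest

from toolfinder.concepts import (ConceptAnnotation, EdamRecognizer,
                                 LexiconRecognizer, annotate_text,
                                 load_lexicon, merge, resolve_coincident,
                                 FORMAT_BRANCHES)
from toolfinder.fixtures import QUESTION_1
from toolfinder.ontology import normalize
from toolfinder.textproc import analyze, ngrams


def _grams(text):
    return ngrams(analyze(text))


def test_edam_recognizer_types_by_root_branch(index):
    anns = EdamRecognizer(index).recognize(_grams("VCF"))
    assert len(anns) == 1
    ann = anns[0]
    assert ann.source == "EDAM"
    assert ann.root_branch == "Format"
    assert ann.semantic_types == ("EDAM Format",)
    assert ann.score == 10  # name match


def test_edam_no_hit_no_annotation(index):
    assert EdamRecognizer(index).recognize(_grams("zebrafish dance")) == []


def test_edam_same_term_two_spans(index):
    anns = EdamRecognizer(index).recognize(_grams("VCF then VCF"))
    vcf = [a for a in anns if normalize(a.surface) == "vcf"]
    assert len(vcf) == 2
    assert vcf[0].concept_id == vcf[1].concept_id
    assert vcf[0].char_span != vcf[1].char_span


def test_lexicon_recognizer_semantic_types(lexicon):
    anns = LexiconRecognizer(lexicon).recognize(_grams("carboplatin"))
    assert len(anns) == 1
    assert "Pharmacologic Substance" in anns[0].semantic_types
    assert anns[0].source == "LEXICON"


def test_lexicon_bigram_single_annotation(lexicon):
    anns = LexiconRecognizer(lexicon).recognize(_grams("lung cancer data"))
    surfaces = [normalize(a.surface) for a in anns]
    assert "lung cancer" in surfaces


def test_lexicon_lemma_fallback_scores_lower(lexicon):
    rec = LexiconRecognizer(lexicon)
    exact = rec.recognize(_grams("patient"))
    lemma = rec.recognize(_grams("patients"))
    assert exact[0].score == 6.0
    assert lemma[0].score == 4.0
    assert exact[0].concept_id == lemma[0].concept_id


def _edam_ann(span, branch, score, cid="E:1"):
    return ConceptAnnotation(char_span=span, surface="x", concept_id=cid,
                             source="EDAM", score=score,
                             semantic_types=(f"EDAM {branch}",),
                             root_branch=branch)


def _lex_ann(span, score, cid="L:1"):
    return ConceptAnnotation(char_span=span, surface="x", concept_id=cid,
                             source="LEXICON", score=score,
                             semantic_types=("Finding",))


def test_merge_rule1_format_precedence():
    """An ontology data/format term beats a lexicon entry on the same span
    regardless of scores."""
    for branch in ("Data", "Format"):
        kept = merge([_edam_ann((0, 3), branch, 2.0)],
                     [_lex_ann((0, 3), 6.0)])
        assert [a.source for a in kept] == ["EDAM"]


def test_merge_rule2_higher_score_wins():
    kept = merge([_edam_ann((0, 3), "Topic", 2.0)], [_lex_ann((0, 3), 6.0)])
    assert [a.source for a in kept] == ["LEXICON"]
    kept = merge([_edam_ann((0, 3), "Operation", 10.0)],
                 [_lex_ann((0, 3), 6.0)])
    assert [a.source for a in kept] == ["EDAM"]


def test_merge_rules_exhaustive_pairs():
    """Brute-force oracle over span-coincident candidate pairs: every
    (branch, edam score, lexicon score) combination resolves per rules
    1 and 2."""
    branches = ["Data", "Format", "Operation", "Topic", "Identifier"]
    scores = [1.0, 2.0, 4.0, 6.0, 10.0]
    for branch, es, ls in itertools.product(branches, scores, scores):
        e, l = _edam_ann((0, 5), branch, es), _lex_ann((0, 5), ls)
        winner = resolve_coincident([e, l])
        if branch in FORMAT_BRANCHES:
            expected = e                       # rule 1
        elif es != ls:
            expected = e if es > ls else l     # rule 2
        else:
            expected = e                       # tie: ontology preferred
        assert winner is expected, (branch, es, ls)


def test_merge_rule1_on_fixture_vcf(index, lexicon):
    """The fixture lexicon also carries 'vcf'; on the same span the
    ontology Format term must win."""
    grams = _grams("VCF")
    kept = merge(EdamRecognizer(index).recognize(grams),
                 LexiconRecognizer(lexicon).recognize(grams))
    assert len(kept) == 1
    assert kept[0].source == "EDAM" and kept[0].root_branch == "Format"


def test_merge_nested_spans_longest_wins(lexicon):
    """'cancer' and 'lung' both have lexicon entries but are swallowed by
    the longer 'lung cancer' span."""
    grams = _grams("lung cancer")
    kept = merge([], LexiconRecognizer(lexicon).recognize(grams))
    assert [normalize(a.surface) for a in kept] == ["lung cancer"]
    # brute-force check: the kept set is the unique maximal non-overlapping
    # selection preferring longer spans
    candidates = LexiconRecognizer(lexicon).recognize(grams)
    assert max(a.length for a in candidates) == kept[0].length


def test_merged_annotations_never_overlap(index, lexicon):
    anns = annotate_text(QUESTION_1, EdamRecognizer(index),
                         LexiconRecognizer(lexicon))
    for a, b in itertools.combinations(anns, 2):
        assert not a.overlaps(b)


def test_merge_deterministic(index, lexicon):
    runs = [annotate_text(QUESTION_1, EdamRecognizer(index),
                          LexiconRecognizer(lexicon)) for _ in range(2)]
    assert runs[0] == runs[1]


def test_question1_sentence_roles(index, lexicon):
    anns = annotate_text(QUESTION_1, EdamRecognizer(index),
                         LexiconRecognizer(lexicon))
    roles = {normalize(a.surface): a.sentence_role for a in anns}
    assert roles["carboplatin"] == "GIVEN"
    assert roles["lung cancer"] == "GIVEN"
    assert roles["literature"] == "QUESTION"
    assert roles["drug"] == "QUESTION"


def test_load_lexicon_rejects_missing_types(tmp_path):
    p = tmp_path / "lex.tsv"
    p.write_text("surface\tconcept_id\tpreferred_name\tsemantic_types\n"
                 "thing\tC1\tThing\t\n")
    with pytest.raises(ValueError):
        load_lexicon(p)
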