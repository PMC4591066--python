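"""Ontology loading, the field-weight formula, and index search."""

import pytest

from toolfinder.ontology import (FieldWeights, OntologyCycleError,
                                 OntologyTerm, TermIndex, load_obo, normalize,
                                 score_term)

# Independent per-field oracle: a field matches when the normalized query
# token run occurs contiguously in the field's normalized token list.


def _oracle_score(query, term, weights=FieldWeights(), parent_names=None):
    def toks(s):
        return normalize(s).split()

    def hit(texts):
        q = toks(query)
        for text in texts:
            h = toks(text)
            if q and any(h[i:i + len(q)] == q
                         for i in range(len(h) - len(q) + 1)):
                return True
        return False

    parents = [parent_names.get(p, p) if parent_names else p
               for p in term.is_a]
    fields = [([term.id], weights.id_w), ([term.name], weights.name_w),
              (list(term.synonyms), weights.synonym_w),
              (list(term.subsets), weights.subset_w),
              (parents, weights.is_a_w), ([term.definition], weights.def_w),
              ([term.comment], weights.comment_w)]
    return sum(w for texts, w in fields if hit(texts))


def test_fixture_roundtrip(fxdir):
    terms = load_obo(fxdir / "mini.obo")
    assert len(terms) == 40
    assert all(t.id and t.name for t in terms)


def test_obsolete_terms_excluded(tmp_path):
    obo = ("format-version: 1.2\n\n[Term]\nid: X:1\nname: alive\n\n"
           "[Term]\nid: X:2\nname: dead\nis_obsolete: true\n")
    p = tmp_path / "t.obo"
    p.write_text(obo)
    terms = load_obo(p)
    assert [t.name for t in terms] == ["alive"]


def test_root_branch_by_isa_traversal(fxdir):
    terms = {t.name: t for t in load_obo(fxdir / "mini.obo")}
    # VCF -> Text format -> Format: two-hop chain to the Format root
    assert terms["VCF"].root_branch == "Format"
    assert terms["Text format"].root_branch == "Format"
    assert terms["Expression matrix"].root_branch == "Data"
    assert terms["KEGG pathways"].root_branch == "Operation"
    assert terms["Format"].root_branch == "Format"


def test_cyclic_isa_raises(tmp_path):
    obo = ("format-version: 1.2\n\n[Term]\nid: X:1\nname: a\nis_a: X:2\n\n"
           "[Term]\nid: X:2\nname: b\nis_a: X:1\n")
    p = tmp_path / "c.obo"
    p.write_text(obo)
    with pytest.raises(OntologyCycleError):
        load_obo(p)


@pytest.mark.parametrize("fields,query,expected", [
    # single name match x weight 10
    (dict(name="KEGG pathways"), "kegg pathways", 10),
    # name + synonym + definition = 10 + 6 + 2
    (dict(name="alpha beta", synonyms=("alpha beta gamma",),
          definition="the alpha beta entity"), "alpha beta", 18),
    # comment-only match x weight 1
    (dict(name="something", comment="mentions delta here"), "delta", 1),
    # nothing matches
    (dict(name="something"), "zeta", 0),
])
def test_score_term_examples(fields, query, expected):
    term = OntologyTerm(id="X:1", **fields)
    hit = score_term(query, term)
    assert hit.score == expected
    assert hit.score == _oracle_score(query, term)


def test_weight_formula_oracle_all_pairs(fxdir, index):
    """score_term agrees with an independent brute-force per-field tally
    for every (query, term) pair over the fixture ontology."""
    terms = load_obo(fxdir / "mini.obo")
    queries = set()
    for t in terms:
        queries.add(t.name)
        queries.update(t.synonyms)
        queries.update(normalize(t.definition).split()[:3])
    queries.update(["reproducible", "kegg", "variant", "no-such-token"])
    for q in sorted(queries):
        if not normalize(q):
            continue
        for t in terms:
            got = score_term(q, t, parent_names=index.parent_names).score
            want = _oracle_score(q, t, parent_names=index.parent_names)
            assert got == want, (q, t.id)


def test_monotonicity_adding_matched_field():
    base = OntologyTerm(id="X:1", name="omega")
    richer = OntologyTerm(id="X:1", name="omega", synonyms=("omega",),
                          definition="omega", comment="omega")
    assert score_term("omega", richer).score >= score_term("omega", base).score


def test_name_bias_outranks_low_weight_fields():
    """A name-only match always outranks any single match among subset,
    is_a, definition and comment."""
    name_only = OntologyTerm(id="X:1", name="target phrase")
    others = [OntologyTerm(id="X:2", subsets=("target phrase",), name="n"),
              OntologyTerm(id="X:3", is_a=("target phrase",), name="n"),
              OntologyTerm(id="X:4", definition="target phrase", name="n"),
              OntologyTerm(id="X:5", comment="target phrase", name="n")]
    top = score_term("target phrase", name_only).score
    for other in others:
        assert top > score_term("target phrase", other).score


def test_search_unique_name_first(index):
    hits = index.search("carboplatin vcf variant call format")
    # not asserting on this composite; unique-name query instead:
    hits = index.search("Newick")
    assert hits and index.terms[hits[0].term_id].name == "Newick"


def test_search_definition_only_matches_tie_by_id(index):
    """'reproducible' occurs only in the TSV and CSV definitions."""
    hits = index.search("reproducible")
    assert len(hits) == 2
    assert all(h.score == 2 for h in hits)
    assert [h.term_id for h in hits] == sorted(h.term_id for h in hits)
    assert {index.terms[h.term_id].name for h in hits} == {"TSV", "CSV"}


def test_search_no_hit_and_empty_query(index):
    assert index.search("qqqxyzzy") == []
    assert index.search("") == []
    assert index.search("   .,;") == []


def test_search_respects_top_k_and_ordering(index):
    hits = index.search("format", top_k=3)
    assert len(hits) == 3
    scores = [h.score for h in hits]
    assert scores == sorted(scores, reverse=True)
    assert all(h.score > 0 for h in hits)


def test_index_json_roundtrip(tmp_path, index):
    p = tmp_path / "index.json"
    index.save(p)
    loaded = TermIndex.load(p)
    for q in ("VCF", "reproducible", "kegg pathways"):
        assert [(h.term_id, h.score) for h in loaded.search(q)] == \
               [(h.term_id, h.score) for h in index.search(q)]
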