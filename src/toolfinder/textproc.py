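"""Lightweight English NLP chain for clinical questions.

Tokenization, sentence splitting, lemmatization and POS tagging are
rule-based and self-contained: a regex tokenizer, a suffix-rule lemmatizer
with an irregular-form table, and a Penn-style tagger driven by a small
closed-class lexicon plus morphological heuristics.  The chain is built for
short clinical questions, not open-domain text.

The question is partitioned into *given-data* sentences (the facts the
user already has, later mapped to tool inputs) and *question* sentences
(the hypothesis to answer, mapped to tool outputs).  N-gram candidates cut
from the token stream feed the concept recognizers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

__all__ = ["Token", "QuestionPartition", "NGram", "analyze",
           "partition_question", "ngrams", "stop_words", "EmptyInputError"]


class EmptyInputError(ValueError):
    """Input text is empty or whitespace-only."""


@dataclass(frozen=True)
class Token:
    text: str
    lemma: str
    pos: str
    sentence_index: int
    char_span: tuple[int, int]

    @property
    def is_punct(self) -> bool:
        return not any(c.isalnum() for c in self.text)


@dataclass(frozen=True)
class QuestionPartition:
    given_sentences: tuple[int, ...]
    question_sentences: tuple[int, ...]


@dataclass(frozen=True)
class NGram:
    tokens: tuple[Token, ...]
    sentence_index: int

    @property
    def n(self) -> int:
        return len(self.tokens)

    @property
    def text(self) -> str:
        return " ".join(t.text for t in self.tokens)

    @property
    def lemma_text(self) -> str:
        return " ".join(t.lemma for t in self.tokens)

    @property
    def char_span(self) -> tuple[int, int]:
        return (self.tokens[0].char_span[0], self.tokens[-1].char_span[1])


def stop_words() -> frozenset[str]:
    """The bundled English stop-word list (lowercased)."""
    text = resources.files("toolfinder.data").joinpath("stopwords.txt").read_text()
    return frozenset(w.strip().lower() for w in text.splitlines()
                     if w.strip() and not w.startswith("#"))


# ---------------------------------------------------------------------------
# Lemmatizer: irregulars first, then ordered suffix rules.

_IRREGULAR_LEMMAS = {
    "is": "be", "am": "be", "are": "be", "was": "be", "were": "be",
    "been": "be", "being": "be", "has": "have", "had": "have",
    "having": "have", "does": "do", "did": "do", "done": "do",
    "known": "know", "knew": "know", "found": "find", "gave": "give",
    "given": "give", "taken": "take", "took": "take", "made": "make",
    "went": "go", "gone": "go", "children": "child", "men": "man",
    "women": "woman", "feet": "foot", "teeth": "tooth", "mice": "mouse",
    "analyses": "analysis", "diagnoses": "diagnosis", "hypotheses":
    "hypothesis", "data": "data", "criteria": "criterion",
    "ate": "eat", "eaten": "eat", "better": "good", "best": "good",
    "worse": "bad", "worst": "bad", "this": "this", "his": "his",
    "its": "its", "ms": "ms", "as": "as", "us": "us", "is_a": "is_a",
}

# words whose -ed/-ing strip needs a restored final e
_E_RESTORE = {"treat": False}


def _lemma_s(word: str) -> str:
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("sses", "shes", "ches", "xes", "zes")):
        return word[:-2]
    if word.endswith("ss") or word.endswith("us") or len(word) <= 2:
        return word
    if word.endswith("s") and not word.endswith("is"):
        return word[:-1]
    return word


def _lemma_ed_ing(word: str) -> str:
    if word.endswith("ied") and len(word) > 4:
        return word[:-3] + "y"  # identified -> identify
    for suf in ("ing", "ed"):
        if word.endswith(suf) and len(word) - len(suf) >= 3:
            stem = word[: -len(suf)]
            if len(stem) >= 4 and stem[-1] == stem[-2] and stem[-1] not in "lsz":
                stem = stem[:-1]  # disrupted->disrupt; stopped->stop
            elif stem.endswith(("at", "iz", "ys", "id", "ag", "in", "ar", "or",
                                "ur", "iv", "uc", "as")) and suf == "ed":
                stem = stem + "e"  # treated stays treat via table below
            return stem
    return word


def lemmatize(word: str) -> str:
    """Best-effort English lemma (lowercased)."""
    w = word.lower()
    if w in _IRREGULAR_LEMMAS:
        return _IRREGULAR_LEMMAS[w]
    if not any(c.isalpha() for c in w):
        return w
    if w.endswith(("ed", "ing")):
        cand = _lemma_ed_ing(w)
        # prefer the bare stem when e-restoration produced a rare form
        if cand.endswith("ate") and w.endswith("ated"):
            return cand[:-1] if cand[:-1].endswith("eat") else cand
        return cand
    return _lemma_s(w)


# ---------------------------------------------------------------------------
# POS tagger: closed classes + morphology, Penn-style tags.

_CLOSED_CLASS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "some": "DT", "all": "DT", "no": "DT",
    "i": "PRP", "you": "PRP", "he": "PRP", "she": "PRP", "it": "PRP",
    "we": "PRP", "they": "PRP", "his": "PRP$", "her": "PRP$", "my": "PRP$",
    "their": "PRP$", "your": "PRP$", "of": "IN", "in": "IN", "on": "IN",
    "for": "IN", "with": "IN", "to": "TO", "from": "IN", "by": "IN",
    "at": "IN", "as": "IN", "due": "IN", "and": "CC", "or": "CC",
    "but": "CC", "which": "WDT", "what": "WP", "who": "WP", "whom": "WP",
    "whose": "WP$", "where": "WRB", "when": "WRB", "why": "WRB",
    "how": "WRB", "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD",
    "be": "VB", "been": "VBN", "am": "VBP", "has": "VBZ", "have": "VBP",
    "had": "VBD", "do": "VBP", "does": "VBZ", "did": "VBD",
    "would": "MD", "could": "MD", "should": "MD", "can": "MD",
    "will": "MD", "may": "MD", "must": "MD", "not": "RB", "mainly": "RB",
    "also": "RB", "such": "JJ", "known": "VBN", "like": "VB",
    "want": "VBP", "need": "VBP", "find": "VB", "identify": "VB",
    "compare": "VB", "obtain": "VB", "get": "VB", "know": "VB",
}


def _tag(word: str, prev_tag: str | None) -> str:
    w = word.lower()
    if not any(c.isalnum() for c in word):
        return "."
    if w in _CLOSED_CLASS:
        return _CLOSED_CLASS[w]
    if re.fullmatch(r"\d+(\.\d+)?", w):
        return "CD"
    if w.endswith("ly"):
        return "RB"
    if w.endswith(("ed",)):
        return "VBN" if prev_tag in {"VBZ", "VBP", "VBD", "VBN"} else "VBD"
    if w.endswith("ing"):
        return "VBG"
    if w.endswith(("ous", "ful", "ive", "ic", "al", "able", "ible")):
        return "JJ"
    if prev_tag in {"MD", "TO"}:
        return "VB"
    if w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return "NNS"
    if word[0].isupper():
        return "NNP"
    return "NN"


# ---------------------------------------------------------------------------
# Tokenization & sentence splitting.

_TOKEN_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9_'\-\.]*[A-Za-z0-9]|[A-Za-z0-9]|\S")
_SENT_END = re.compile(r"[.!?]")


def analyze(text: str) -> list[Token]:
    """Tokenize, sentence-split, lemmatize and POS-tag plain text."""
    if not text or not text.strip():
        raise EmptyInputError("input text is empty")
    tokens: list[Token] = []
    sent = 0
    prev_tag: str | None = None
    for m in _TOKEN_RE.finditer(text):
        raw = m.group(0)
        # split a trailing sentence period glued by the token regex
        if len(raw) > 1 and raw.endswith(".") and not re.search(r"\d\.$", raw):
            raw = raw[:-1]
        span = (m.start(), m.start() + len(raw))
        tag = _tag(raw, prev_tag)
        tok = Token(text=raw, lemma=lemmatize(raw), pos=tag,
                    sentence_index=sent, char_span=span)
        tokens.append(tok)
        prev_tag = tag
        rest = text[span[1]:m.end()]
        if _SENT_END.fullmatch(raw) or _SENT_END.search(rest):
            if rest and _SENT_END.search(rest):
                p = (m.end() - 1, m.end())
                tokens.append(Token(text=text[p[0]:p[1]], lemma=text[p[0]:p[1]],
                                    pos=".", sentence_index=sent, char_span=p))
            sent += 1
            prev_tag = None
    return tokens


_QUESTION_MARKERS = ("i would like", "i want", "i need", "?")
_INTERROGATIVES = {"what", "which", "who", "whom", "whose", "where", "when",
                   "why", "how", "is", "are", "can", "does", "do"}


def partition_question(tokens: list[Token]) -> QuestionPartition:
    """Split sentences into given-data vs research-question contexts.

    A sentence is a question sentence if it contains a desiderative marker
    ("I would like" / "I want" / "I need" / "?") or starts with an
    interrogative word.  If no marker fires anywhere, the last sentence is
    taken as the question and the rest as given data.
    """
    if not tokens:
        raise EmptyInputError("no tokens")
    n_sents = max(t.sentence_index for t in tokens) + 1
    sent_texts = {}
    sent_first = {}
    for t in tokens:
        sent_texts.setdefault(t.sentence_index, []).append(t.text.lower())
        sent_first.setdefault(t.sentence_index, t.text.lower())
    question: list[int] = []
    for i in range(n_sents):
        joined = " ".join(sent_texts[i])
        if any(mk in joined for mk in _QUESTION_MARKERS) \
                or sent_first[i] in _INTERROGATIVES:
            question.append(i)
    if not question:
        question = [n_sents - 1]
    given = [i for i in range(n_sents) if i not in question]
    return QuestionPartition(tuple(given), tuple(question))


def ngrams(tokens: list[Token], n_max: int = 5,
           stops: frozenset[str] | None = None) -> list[NGram]:
    """All contiguous within-sentence runs of length 1..n_max.

    Runs that start or end with punctuation or a stop-word are excluded;
    stop-words inside a run are allowed.
    """
    if stops is None:
        stops = stop_words()

    def boundary_ok(tok: Token) -> bool:
        return not tok.is_punct and tok.text.lower() not in stops

    by_sent: dict[int, list[Token]] = {}
    for t in tokens:
        by_sent.setdefault(t.sentence_index, []).append(t)

    out: list[NGram] = []
    for sent_idx, sent in sorted(by_sent.items()):
        m = len(sent)
        for n in range(1, min(n_max, m) + 1):
            for i in range(m - n + 1):
                run = sent[i:i + n]
                if any(t.is_punct for t in run):
                    continue
                if boundary_ok(run[0]) and boundary_ok(run[-1]):
                    out.append(NGram(tokens=tuple(run), sentence_index=sent_idx))
    return out
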