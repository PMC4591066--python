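"""Precision / recall / best-rank evaluation against an expert gold
standard, plus the free-text retrieval baseline.

Precision is the fraction of retrieved tools that are relevant; recall the
fraction of relevant tools that are retrieved.  Percentages are reported
both unrounded and rounded to integers with half-away-from-zero rounding
(so 100*11/76 = 14.47 prints as 14 and 100*17/99 = 17.17 as 17).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

from .repository import Repository, content_tokens, query


class GoldStandardError(ValueError):
    pass


@dataclass(frozen=True)
class GoldStandard:
    question_id: str
    relevant_tools: frozenset[str]
    full_solvers: frozenset[str]

    def __post_init__(self):
        if not self.full_solvers <= self.relevant_tools:
            raise GoldStandardError("full_solvers must be a subset of "
                                    "relevant_tools")


@dataclass(frozen=True)
class EvalResult:
    retrieved: int
    tp: int
    fp: int
    fn: int
    precision: float             # unrounded percentage
    recall: float                # unrounded percentage
    precision_pct: int           # rounded, half away from zero
    recall_pct: int
    best_rank_full_solver: int | None


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def load_gold(path: str | Path) -> GoldStandard:
    """TSV with columns tool_name, full_solver (yes/no); question id from
    the file stem."""
    path = Path(path)
    relevant, solvers = set(), set()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            relevant.add(row["tool_name"])
            if row.get("full_solver", "").strip().lower() in {"yes", "true",
                                                              "1"}:
                solvers.add(row["tool_name"])
    return GoldStandard(question_id=path.stem,
                        relevant_tools=frozenset(relevant),
                        full_solvers=frozenset(solvers))


def evaluate(retrieved_ranked: list[str], gold: GoldStandard) -> EvalResult:
    """Counts, rates and best full-solver rank for a ranked retrieval."""
    if not gold.relevant_tools:
        raise GoldStandardError(f"gold standard {gold.question_id!r} is empty")
    if len(set(retrieved_ranked)) != len(retrieved_ranked):
        raise ValueError("retrieved list contains duplicates")
    retrieved = set(retrieved_ranked)
    tp = len(retrieved & gold.relevant_tools)
    fp = len(retrieved - gold.relevant_tools)
    fn = len(gold.relevant_tools - retrieved)
    precision = 100.0 * tp / (tp + fp) if retrieved else 0.0
    recall = 100.0 * tp / (tp + fn)
    best = next((i for i, name in enumerate(retrieved_ranked, start=1)
                 if name in gold.full_solvers), None)
    return EvalResult(retrieved=len(retrieved_ranked), tp=tp, fp=fp, fn=fn,
                      precision=precision, recall=recall,
                      precision_pct=round_half_away(precision),
                      recall_pct=round_half_away(recall),
                      best_rank_full_solver=best)


def run_baseline(question_text: str, repo: Repository) -> list[str]:
    """Free-text baseline: the whole question, uninterpreted, as a bag of
    content tokens against the repository's full-text strategy."""
    tokens = content_tokens(question_text)
    if not tokens:
        return []
    return query(repo, "full_text", tokens)
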