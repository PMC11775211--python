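"""Patient cases and ranked disease predictions shared by all diagnostic methods.

Ranks use competition ("min-rank") semantics: tied scores share the smallest
rank of the tie group, and the display order within a tie group is by
lexicographic primary disease code so outputs are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .ontology import TermID

__all__ = [
    "PatientCase",
    "RankedPrediction",
    "rank_scores",
    "read_cases_jsonl",
    "write_cases_jsonl",
    "read_cases_tsv",
    "write_predictions_tsv",
]


@dataclass
class PatientCase:
    """A query phenotype set Q with (optionally) known true diagnosis codes."""

    case_id: str
    query: set[TermID]
    true_codes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.query:
            raise ValueError(f"case {self.case_id}: query must be non-empty")


@dataclass
class RankedPrediction:
    """A total ordering of KB diseases: (codes, score, rank) rows.

    Scores are non-increasing down the list; ranks start at 1; tied scores
    share a min-rank.
    """

    entries: list[tuple[frozenset, float, int]]
    method: str
    tie_policy: str = "min-rank"

    def rank_of(self, codes: set[str] | str) -> int | None:
        """Rank of the first entry intersecting ``codes``; None if absent."""
        want = {codes} if isinstance(codes, str) else set(codes)
        for entry_codes, _, rank in self.entries:
            if entry_codes & want:
                return rank
        return None

    @property
    def n_diseases(self) -> int:
        return len(self.entries)

    def ranks_by_primary_code(self) -> dict[str, int]:
        return {min(c): r for c, _, r in self.entries}


def rank_scores(
    scored: Iterable[tuple[set[str] | frozenset, float]],
    method: str,
    descending: bool = True,
) -> RankedPrediction:
    """Order (codes, score) pairs into a :class:`RankedPrediction`.

    ``descending=True`` means larger score is better (similarity methods);
    ``descending=False`` means smaller is better (CNB complement scores,
    ensemble Z/p values).  Stored scores are as given; only ordering flips.
    """
    items = [(frozenset(c), float(s)) for c, s in scored]
    sign = -1.0 if descending else 1.0
    items.sort(key=lambda cs: (sign * cs[1], min(cs[0])))
    entries: list[tuple[frozenset, float, int]] = []
    prev_score: float | None = None
    prev_rank = 1
    for i, (codes, score) in enumerate(items, start=1):
        rank = prev_rank if (prev_score is not None and score == prev_score) else i
        entries.append((codes, score, rank))
        prev_score, prev_rank = score, rank
    return RankedPrediction(entries=entries, method=method)


# -- I/O -------------------------------------------------------------------


def read_cases_jsonl(path) -> list[PatientCase]:
    """Read cases from JSON lines: {"case_id", "terms": [...], "diagnosis": [...]}."""
    cases: list[PatientCase] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            cases.append(
                PatientCase(
                    case_id=str(rec["case_id"]),
                    query=set(rec["terms"]),
                    true_codes=set(rec.get("diagnosis", [])),
                )
            )
    return cases


def write_cases_jsonl(cases: Sequence[PatientCase], path) -> None:
    with open(path, "w") as fh:
        for c in cases:
            fh.write(
                json.dumps(
                    {
                        "case_id": c.case_id,
                        "terms": sorted(c.query),
                        "diagnosis": sorted(c.true_codes),
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_cases_tsv(path) -> list[PatientCase]:
    """Two-column TSV loader: case_id <tab> space-or-semicolon-separated terms."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, header=None,
                     names=["case_id", "terms"])
    cases = []
    for _, row in df.iterrows():
        terms = {t for t in row["terms"].replace(";", " ").split() if t}
        cases.append(PatientCase(case_id=row["case_id"], query=terms))
    return cases


def write_predictions_tsv(
    predictions: dict[str, RankedPrediction], path, source: str | None = None
) -> None:
    """Write per-case predictions as TSV (case_id, rank, codes, score, method)."""
    rows = []
    for case_id, pred in predictions.items():
        for codes, score, rank in pred.entries:
            row = {
                "case_id": case_id,
                "rank": rank,
                "disease": ";".join(sorted(codes)),
                "score": score,
                "method": pred.method,
            }
            if source is not None:
                row["source"] = source
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
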