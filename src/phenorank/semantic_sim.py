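"""Semantic similarity between a query phenotype set and disease annotations.

The flagship measure, ICTO, sums the information content of the query terms
that fall inside the disease's annotation closure (one-sided), symmetrized
by averaging both directions.  Because only terms *inside* the closure
contribute, the one-sided score is insensitive to noise phenotypes the
disease does not annotate — the property that makes it robust on real
patients, whose records carry many phenotypes unrelated to the diagnosis.

Also provided are the standard ontology-similarity baselines: the set-based
SimGIC / SimUI / term-overlap / cosine measures over closures, and the
pairwise IC-based Resnik / Lin / Jiang-Conrath / minIC measures aggregated
by symmetric best-match average over the most-informative common ancestor
(MICA).
"""

from __future__ import annotations

import math
from typing import Callable

from .knowledgebase import KnowledgeBase
from .ontology import ICTable, Ontology, TermID
from .ranking import PatientCase, RankedPrediction, rank_scores

__all__ = [
    "icto_one_sided",
    "icto_symmetric",
    "baseline_similarity",
    "rank_diseases_by_similarity",
    "SET_MEASURES",
    "PAIRWISE_MEASURES",
]

SET_MEASURES = ("simgic", "simui", "term_overlap", "cosine")
PAIRWISE_MEASURES = ("resnik", "lin", "jc", "min_ic")


def icto_one_sided(
    q: set[TermID], h: set[TermID], ic: ICTable, o: Ontology
) -> float:
    """Sum of IC(t) over t in Q ∩ A(H): how much of the query the disease explains."""
    ah = o.annotation_closure(h)
    # sorted so the float sum is independent of set iteration order: adding
    # out-of-closure terms to q then provably never changes the score
    return sum(ic.get(t) for t in sorted(q) if t in ah)


def icto_symmetric(
    q: set[TermID], h: set[TermID], ic: ICTable, o: Ontology
) -> float:
    """Average of the two one-sided ICTO scores."""
    return 0.5 * (icto_one_sided(q, h, ic, o) + icto_one_sided(h, q, ic, o))


# -- pairwise IC measures --------------------------------------------------


def _mica_ic(a: TermID, b: TermID, ic: ICTable, o: Ontology) -> float:
    """IC of the most informative common ancestor (terms included)."""
    common = o.ancestors(a, include_self=True) & o.ancestors(b, include_self=True)
    return max((ic.get(t) for t in common), default=0.0)


def _pair_resnik(a, b, ic, o):
    return _mica_ic(a, b, ic, o)


def _pair_lin(a, b, ic, o):
    if a == b:
        return 1.0
    denom = ic.get(a) + ic.get(b)
    return 2.0 * _mica_ic(a, b, ic, o) / denom if denom > 0 else 0.0


def _pair_jc(a, b, ic, o):
    # Similarity form of the Jiang-Conrath distance: 1 / (1 + d_JC)
    d = ic.get(a) + ic.get(b) - 2.0 * _mica_ic(a, b, ic, o)
    return 1.0 / (1.0 + d)


def _pair_min_ic(a, b, ic, o):
    # MICA IC normalized by the less informative of the two terms (identical
    # terms score 1 by convention); a literal minimum over common ancestors
    # would always hit the zero-IC root
    if a == b:
        return 1.0
    denom = min(ic.get(a), ic.get(b))
    return _mica_ic(a, b, ic, o) / denom if denom > 0 else 0.0


_PAIR_FNS: dict[str, Callable] = {
    "resnik": _pair_resnik,
    "lin": _pair_lin,
    "jc": _pair_jc,
    "min_ic": _pair_min_ic,
}


def _best_match_average(
    q: set[TermID], h: set[TermID], pair_fn: Callable, ic: ICTable, o: Ontology
) -> float:
    """Symmetric best-match average: mean over each side of max pair score."""
    if not q or not h:
        return 0.0
    fwd = sum(max(pair_fn(a, b, ic, o) for b in h) for a in q) / len(q)
    rev = sum(max(pair_fn(b, a, ic, o) for a in q) for b in h) / len(h)
    return 0.5 * (fwd + rev)


def baseline_similarity(
    measure: str,
    q: set[TermID],
    h: set[TermID],
    ic: ICTable,
    o: Ontology,
) -> float:
    """One of the standard similarity measures between Q and H.

    Set-based measures operate on the annotation closures A(Q) and A(H);
    pairwise IC measures operate on the raw term sets with best-match
    average aggregation.
    """
    if measure in _PAIR_FNS:
        return _best_match_average(q, h, _PAIR_FNS[measure], ic, o)
    if measure not in SET_MEASURES:
        raise ValueError(f"unknown similarity measure {measure!r}")
    aq, ah = o.annotation_closure(q), o.annotation_closure(h)
    inter, union = aq & ah, aq | ah
    if measure == "simgic":
        denom = sum(ic.get(t) for t in union)
        return sum(ic.get(t) for t in inter) / denom if denom > 0 else 0.0
    if measure == "simui":
        return len(inter) / len(union) if union else 0.0
    if measure == "term_overlap":
        m = min(len(aq), len(ah))
        return len(inter) / m if m else 0.0
    # cosine over binary closure indicators
    denom = math.sqrt(len(aq) * len(ah))
    return len(inter) / denom if denom > 0 else 0.0


def rank_diseases_by_similarity(
    case: PatientCase,
    kb: KnowledgeBase,
    ic: ICTable,
    o: Ontology,
    method: str = "icto",
) -> RankedPrediction:
    """Score every KB disease against the case query and rank descending.

    ``method`` is ``icto`` (symmetric), ``icto_one_sided``, or any baseline
    measure name.
    """
    if not kb.diseases:
        raise ValueError("empty knowledge base")
    if method == "icto":
        score = lambda h: icto_symmetric(case.query, h, ic, o)  # noqa: E731
    elif method == "icto_one_sided":
        score = lambda h: icto_one_sided(case.query, h, ic, o)  # noqa: E731
    elif method in SET_MEASURES or method in PAIRWISE_MEASURES:
        score = lambda h: baseline_similarity(method, case.query, h, ic, o)  # noqa: E731
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    scored = [(e.codes, score(e.terms)) for e in kb.diseases]
    return rank_scores(scored, method=method, descending=True)
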