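"""PPO: a naive-Bayes disease model with probability propagation in the ontology.

Each disease d_k defines per-term conditional probabilities P(t|d_k):

* directly annotated terms use the knowledge-base frequency p_tk, or a
  default probability ``dp`` when the frequency is unknown;
* un-annotated ancestors of annotated terms receive a probability propagated
  bottom-up from their children inside the closure, by one of three rules —
  ``f_max`` (most informative child), ``f_ind`` (children as independent
  evidence, 1 - prod(1 - p)), or ``f_sum`` (additive, capped at 1);
* all other terms fall back to the background probability P(t).

A case is scored by sum over query terms of ln P(t|d_k) (uniform disease
prior), and diseases are ranked by descending score.  The model extends to
gene evidence G by adding sum over g of ln P(g|d_k) under the same
conditional-independence assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .knowledgebase import DiseaseEntry, KnowledgeBase
from .ontology import ICTable, Ontology, TermID
from .ranking import PatientCase, RankedPrediction, rank_scores

__all__ = [
    "PPOParams",
    "PropagatedProfile",
    "GeneEvidence",
    "propagate",
    "score_case",
    "score_case_with_genes",
]

PROPAGATION_RULES = ("f_max", "f_ind", "f_sum")


@dataclass(frozen=True)
class PPOParams:
    """Default probability for unknown frequencies and the propagation rule."""

    dp: float = 0.5
    propagation: str = "f_ind"

    def __post_init__(self) -> None:
        if not (0.0 < self.dp < 1.0):
            raise ValueError(f"dp must lie in (0,1), got {self.dp}")
        if self.propagation not in PROPAGATION_RULES:
            raise ValueError(f"unknown propagation rule {self.propagation!r}")


@dataclass
class PropagatedProfile:
    """P(t|d_k) for every term in the disease's annotation closure."""

    disease: frozenset
    cond_prob: dict[TermID, float]


@dataclass
class GeneEvidence:
    """Candidate disease genes and per-(gene, disease) probabilities.

    Pairs absent from ``gene_prob`` fall back to ``background``.
    """

    genes: set[str]
    gene_prob: dict[tuple[str, str], float] = field(default_factory=dict)
    background: float = 1e-3

    def prob(self, gene: str, disease_codes: frozenset) -> float:
        for code in disease_codes:
            if (gene, code) in self.gene_prob:
                return self.gene_prob[(gene, code)]
        return self.background


def _combine(rule: str, child_probs: list[float]) -> float:
    if len(child_probs) == 1:
        return child_probs[0]  # all three rules coincide on a single child
    if rule == "f_max":
        return max(child_probs)
    if rule == "f_ind":
        prod = 1.0
        for p in child_probs:
            prod *= 1.0 - p
        return 1.0 - prod
    return min(1.0, sum(child_probs))


def propagate(
    disease: DiseaseEntry, o: Ontology, params: PPOParams = PPOParams()
) -> PropagatedProfile:
    """Compute P(t|d_k) over A(H_k) for one disease.

    Directly annotated terms take their frequency (or dp); ancestors are
    filled bottom-up over C_k = children(t) ∩ A(H_k).  A term that is both
    annotated and an ancestor of other annotated terms keeps its direct
    frequency.
    """
    h = disease.terms
    if not h:
        raise ValueError(f"disease {sorted(disease.codes)} has no annotations")
    closure = o.annotation_closure(h)
    cond: dict[TermID, float] = {}
    for t in h:
        rec = disease.annotations.get(t)
        cond[t] = params.dp if rec is None or rec.provenance == "default" else rec.value

    # ancestors in increasing order of remaining descendants => resolve via
    # explicit DFS with memoization (depth bounded by DAG depth)
    def value(t: TermID) -> float:
        if t in cond:
            return cond[t]
        ck = o.children.get(t, set()) & closure
        # every non-annotated closure member has a closure child on some
        # path down to an annotated term
        probs = [value(c) for c in sorted(ck)]
        v = _combine(params.propagation, probs)
        cond[t] = v
        return v

    for t in closure:
        value(t)
    return PropagatedProfile(disease=frozenset(disease.codes), cond_prob=cond)


def _profiles(kb: KnowledgeBase, o: Ontology, params: PPOParams):
    for entry in kb.diseases:
        if not entry.terms:
            yield entry, None
            continue
        yield entry, propagate(entry, o, params)


def _phenotype_loglik(
    query: set[TermID],
    profile: PropagatedProfile | None,
    ic: ICTable,
) -> float:
    total = 0.0
    for t in query:
        if profile is not None and t in profile.cond_prob:
            p = profile.cond_prob[t]
        else:
            p = ic.prob(t)
        total += math.log(max(p, ic.floor))
    return total


def score_case(
    case: PatientCase,
    kb: KnowledgeBase,
    ic: ICTable,
    o: Ontology,
    params: PPOParams = PPOParams(),
) -> RankedPrediction:
    """Rank all KB diseases for a case by the PPO log-likelihood."""
    scored = [
        (entry.codes, _phenotype_loglik(case.query, prof, ic))
        for entry, prof in _profiles(kb, o, params)
    ]
    return rank_scores(scored, method="ppo", descending=True)


def score_case_with_genes(
    case: PatientCase,
    genes: GeneEvidence,
    kb: KnowledgeBase,
    ic: ICTable,
    o: Ontology,
    params: PPOParams = PPOParams(),
) -> RankedPrediction:
    """PPO ranking with additional gene evidence.

    score(d_k) = sum_t ln P(t|d_k) + sum_g ln P(g|d_k); with an empty gene
    set this reduces exactly to :func:`score_case`.
    """
    scored = []
    for entry, prof in _profiles(kb, o, params):
        s = _phenotype_loglik(case.query, prof, ic)
        codes = frozenset(entry.codes)
        for g in sorted(genes.genes):
            s += math.log(genes.prob(g, codes))
        scored.append((entry.codes, s))
    return rank_scores(scored, method="ppo+genes", descending=True)
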