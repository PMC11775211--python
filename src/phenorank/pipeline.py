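"""End-to-end orchestration: score cases with every requested method,
ensemble the member rankings, and evaluate against true diagnoses."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

from .ensemble import NullApprox, ensemble_rank, fit_null
from .fewshot import (
    AugmentationConfig,
    CNBParams,
    MLPParams,
    build_standard_cases,
    cnb_fit,
    cnb_rank,
    mlp_fit,
    mlp_rank,
    query_vector,
)
from .knowledgebase import KnowledgeBase
from .ontology import ICTable, Ontology, compute_ic
from .ppo import PPOParams, score_case
from .ranking import PatientCase, RankedPrediction
from .semantic_sim import (
    PAIRWISE_MEASURES,
    SET_MEASURES,
    rank_diseases_by_similarity,
)

logger = logging.getLogger(__name__)

__all__ = ["DiagnosisEngine", "filter_cases", "derive_seed", "ENSEMBLE_MEMBERS"]

ENSEMBLE_MEMBERS = ("icto", "ppo", "cnb", "mlp")
ALL_METHODS = ("icto", "icto_one_sided", "ppo", "cnb", "mlp",
               *SET_MEASURES, *PAIRWISE_MEASURES)


def derive_seed(global_seed: int, stream: str) -> int:
    """Stable per-stream seed below 2**31, so adding one method never
    perturbs another method's random stream."""
    h = hashlib.sha256(f"{global_seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def filter_cases(cases: list[PatientCase], min_terms: int = 3) -> list[PatientCase]:
    """Drop cases with fewer than ``min_terms`` query phenotypes."""
    if min_terms < 1:
        raise ValueError("min_terms must be >= 1")
    kept = [c for c in cases if len(c.query) >= min_terms]
    logger.info("filter_cases: kept %d of %d", len(kept), len(cases))
    if not kept:
        raise ValueError("all cases removed by the minimum-phenotype filter")
    return kept


@dataclass
class DiagnosisEngine:
    """Prepares every method once against a KB, then ranks cases.

    Preparation covers the IC table, the few-shot training matrix, the CNB
    theta table, the (augmented) MLP, and the ensemble null distribution.
    """

    ontology: Ontology
    kb: KnowledgeBase
    methods: tuple[str, ...] = ENSEMBLE_MEMBERS
    ppo_params: PPOParams = field(default_factory=PPOParams)
    cnb_params: CNBParams = field(default_factory=CNBParams)
    mlp_params: MLPParams = field(default_factory=MLPParams)
    augmentation: AugmentationConfig | None = None
    seed: int = 0
    null_samples: int = 100_000
    ic: ICTable = field(init=False)
    null: NullApprox | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        self.ic = compute_ic(self.ontology, self.kb)
        need_matrix = {"cnb", "mlp"} & set(self.methods)
        self._train = build_standard_cases(self.kb, self.ontology) if need_matrix else None
        self._theta = (
            cnb_fit(self._train, self.cnb_params) if "cnb" in self.methods else None
        )
        if "mlp" in self.methods:
            aug = self.augmentation or AugmentationConfig(
                seed=derive_seed(self.seed, "augment")
            )
            params = MLPParams(
                hidden_size=self.mlp_params.hidden_size,
                l2_lambda=self.mlp_params.l2_lambda,
                learning_rate=self.mlp_params.learning_rate,
                epochs=self.mlp_params.epochs,
                seed=derive_seed(self.seed, "mlp"),
            )
            self._mlp = mlp_fit(self._train, params, cfg=aug, o=self.ontology)
        else:
            self._mlp = None
        if len(self.methods) >= 2:
            self.null = fit_null(
                len(self.methods),
                mc_samples=self.null_samples,
                seed=derive_seed(self.seed, "null"),
            )

    def rank_one(self, case: PatientCase, method: str) -> RankedPrediction:
        if method == "ppo":
            return score_case(case, self.kb, self.ic, self.ontology, self.ppo_params)
        if method == "cnb":
            q = query_vector(case.query, self._train.term_index, self.ontology)
            return cnb_rank(q, self._theta, self._train.disease_codes)
        if method == "mlp":
            q = query_vector(case.query, self._mlp.term_index, self.ontology)
            return mlp_rank(q, self._mlp)
        return rank_diseases_by_similarity(case, self.kb, self.ic, self.ontology, method)

    def diagnose(
        self, cases: list[PatientCase], with_ensemble: bool = True
    ) -> dict[str, dict[str, RankedPrediction]]:
        """Per-method (plus ``ensemble``) predictions for every case.

        Returns ``{method: {case_id: RankedPrediction}}``.
        """
        out: dict[str, dict[str, RankedPrediction]] = {m: {} for m in self.methods}
        if with_ensemble and len(self.methods) >= 2:
            out["ensemble"] = {}
        for case in cases:
            members = []
            for m in self.methods:
                try:
                    pred = self.rank_one(case, m)
                except Exception as exc:
                    raise RuntimeError(
                        f"stage {m!r} failed on case {case.case_id}"
                    ) from exc
                out[m][case.case_id] = pred
                members.append(pred)
            if "ensemble" in out:
                out["ensemble"][case.case_id] = ensemble_rank(members, null=self.null)
        return out
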