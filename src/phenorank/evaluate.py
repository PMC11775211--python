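"""Evaluation metrics for ranked differential-diagnosis predictions.

Per case the quantity of interest is the *first-hit rank*: the best rank of
any of the case's true diagnoses in the prediction.  Across cases we report
top-k recall (fraction of cases with first-hit rank <= k) and the median
rank, with percentile bootstrap confidence intervals, plus a paired
two-sided Wilcoxon signed-rank test for comparing methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ranking import RankedPrediction

logger = logging.getLogger(__name__)

__all__ = [
    "EvalResult",
    "ComparisonResult",
    "first_hit_rank",
    "metrics",
    "bootstrap_ci",
    "compare_methods",
    "evaluate_predictions",
]


@dataclass
class EvalResult:
    per_case_rank: dict[str, float]
    top_k_recall: dict[int, float]
    median_rank: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0
    seed: int = 0


@dataclass
class ComparisonResult:
    method_a: str
    method_b: str
    statistic: float
    p_value: float
    significant: bool  # at the conventional 0.05 level


def first_hit_rank(pred: RankedPrediction, true_codes: set[str]) -> int:
    """Best (minimum) rank over the entries matching any true diagnosis code.

    If no true code resolves against the prediction, returns the sentinel
    D + 1 so that downstream medians stay finite while the miss is penalized.
    """
    if not true_codes:
        raise ValueError("true_codes must be non-empty")
    best: int | None = None
    for codes, _, rank in pred.entries:
        if codes & true_codes and (best is None or rank < best):
            best = rank
    if best is None:
        logger.warning("no true code of %s found in prediction; sentinel rank %d",
                       sorted(true_codes), pred.n_diseases + 1)
        return pred.n_diseases + 1
    return best


def metrics(ranks: list[float], ks: list[int] = [1, 3, 10]) -> EvalResult:
    """Point estimates: top-k recall for each k and the median rank."""
    if not ranks:
        raise ValueError("no ranks to evaluate")
    arr = np.asarray(ranks, dtype=float)
    recall = {k: float(np.mean(arr <= k)) for k in ks}
    return EvalResult(
        per_case_rank={str(i): float(r) for i, r in enumerate(ranks)},
        top_k_recall=recall,
        median_rank=float(np.median(arr)),
    )


def bootstrap_ci(
    ranks: list[float],
    metric: str = "median",
    n_boot: int = 10_000,
    seed: int = 0,
    k: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI for ``median`` or ``recall@k``.

    Cases are resampled with replacement ``n_boot`` times; the interval is
    the (2.5, 97.5) percentile of the resampled statistic.  Deterministic
    under ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    arr = np.asarray(ranks, dtype=float)
    if len(arr) < 5:
        logger.warning("bootstrap over %d cases: intervals will be wide", len(arr))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(arr), size=(n_boot, len(arr)))
    samples = arr[idx]
    if metric == "median":
        vals = np.median(samples, axis=1)
    elif metric == "recall":
        if k is None:
            raise ValueError("recall bootstrap needs k")
        vals = np.mean(samples <= k, axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def compare_methods(
    ranks_a: list[float],
    ranks_b: list[float],
    name_a: str = "a",
    name_b: str = "b",
) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-case ranks.

    Zero differences are handled by the Pratt convention; if every pair is
    tied the test is degenerate and p = 1 is reported.
    """
    if len(ranks_a) != len(ranks_b):
        raise ValueError("rank lists must be paired (equal length)")
    if len(ranks_a) < 6:
        raise ValueError("signed-rank comparison needs at least 6 pairs")
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if np.all(a == b):
        return ComparisonResult(name_a, name_b, 0.0, 1.0, False)
    stat, p = stats.wilcoxon(a, b, zero_method="pratt", alternative="two-sided")
    return ComparisonResult(name_a, name_b, float(stat), float(p), bool(p < 0.05))


def evaluate_predictions(
    predictions: dict[str, RankedPrediction],
    true_codes: dict[str, set[str]],
    ks: list[int] = [1, 3, 10],
    n_boot: int = 0,
    seed: int = 0,
) -> EvalResult:
    """First-hit ranks for a batch of per-case predictions, plus metrics.

    ``predictions`` and ``true_codes`` are keyed by case_id; with
    ``n_boot > 0`` percentile CIs are attached for the median and each
    recall@k.
    """
    ranks, per_case = [], {}
    for case_id, pred in predictions.items():
        r = first_hit_rank(pred, true_codes[case_id])
        per_case[case_id] = float(r)
        ranks.append(float(r))
    res = metrics(ranks, ks=ks)
    res.per_case_rank = per_case
    if n_boot:
        res.n_boot = n_boot
        res.seed = seed
        res.ci["median"] = bootstrap_ci(ranks, "median", n_boot, seed)
        for k in ks:
            res.ci[f"recall@{k}"] = bootstrap_ci(ranks, "recall", n_boot, seed, k=k)
    return res
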