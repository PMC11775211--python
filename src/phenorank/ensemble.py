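"""Order-statistics ensemble over multiple disease rankings.

Each member method contributes a rank ratio r_i = rank_i / D for a disease.
Under the null hypothesis that every method ranks the disease uniformly at
random, the sorted ratio vector (r_1 <= ... <= r_N) is a draw of N uniform
order statistics, and

    Z(r_1, ..., r_N) = N! * Vol{0 <= s_1 <= ... <= s_N, s_i <= r_i}

is the joint CDF of those order statistics — the probability that random
ratios would all be at least as small as the observed ones.  A small Z
marks a disease consistently ranked near the top by all members.  Z is
computed by the classical recursion

    V_0 = 1,   V_k = sum_{i=1}^{k} (-1)^(i-1) * V_{k-i} / i! * r_{N-k+1}^i,
    Z = N! * V_N.

Calibrated p-values come from a parametric fit to the simulated null of Z:
Beta for N <= 5, Gamma for N > 5 (moment matching by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ranking import RankedPrediction, rank_scores

logger = logging.getLogger(__name__)

__all__ = [
    "rank_ratios",
    "z_statistic",
    "NullApprox",
    "fit_null",
    "ensemble_rank",
    "merge_with_physician",
]


def rank_ratios(
    rankings: list[RankedPrediction], disease: frozenset | set
) -> np.ndarray:
    """Sorted ascending rank ratios of one disease across the member rankings."""
    want = frozenset(disease)
    ratios = []
    for pred in rankings:
        rank = pred.rank_of(set(want))
        if rank is None:
            raise ValueError(f"disease {sorted(want)} absent from {pred.method}")
        ratios.append(rank / pred.n_diseases)
    return np.sort(np.asarray(ratios, dtype=float))


def z_statistic(r: np.ndarray) -> float:
    """Joint order-statistic CDF of a sorted ratio vector.

    Requires 0 <= r_1 <= ... <= r_N <= 1 (raises on unsorted input); returns
    a value in [0, 1].
    """
    r = np.asarray(r, dtype=float)
    n = len(r)
    if n == 0:
        raise ValueError("need at least one ratio")
    if np.any(r[1:] < r[:-1]):
        raise ValueError("ratio vector must be sorted ascending")
    if r[0] < 0 or r[-1] > 1:
        raise ValueError("ratios must lie in [0, 1]")
    v = np.zeros(n + 1)
    v[0] = 1.0
    for k in range(1, n + 1):
        acc = 0.0
        base = r[n - k]  # r_{N-k+1}, 1-indexed
        for i in range(1, k + 1):
            acc += (-1) ** (i - 1) * v[k - i] / math.factorial(i) * base**i
        v[k] = acc
    z = math.factorial(n) * v[n]
    return min(max(z, 0.0), 1.0)


@dataclass(frozen=True)
class NullApprox:
    """Parametric approximation of the null distribution of Z.

    Beta(a, b) when the ensemble has N <= 5 members, Gamma(shape, scale)
    when N > 5.
    """

    family: str
    params: tuple[float, ...]
    n_methods: int
    mc_samples: int
    seed: int

    def cdf(self, z: float | np.ndarray) -> float | np.ndarray:
        if self.family == "beta":
            return stats.beta.cdf(z, *self.params)
        return stats.gamma.cdf(z, self.params[0], scale=self.params[1])


def fit_null(
    n_methods: int,
    mc_samples: int = 100_000,
    seed: int = 20240101,
    method: str = "moments",
) -> NullApprox:
    """Fit the null distribution of Z by simulation.

    Draws ``mc_samples`` sorted-uniform ratio vectors, computes Z for each,
    and fits Beta (N <= 5) or Gamma (N > 5) by moment matching (default) or
    maximum likelihood (``method="mle"``).  Deterministic given the seed.
    """
    if n_methods < 1:
        raise ValueError("need at least one method")
    if mc_samples < 1000:
        logger.warning("fit_null with %d samples is unreliable", mc_samples)
    rng = np.random.default_rng(seed)
    u = np.sort(rng.random((mc_samples, n_methods)), axis=1)
    zs = _z_batch(u)
    family = "beta" if n_methods <= 5 else "gamma"
    m = float(zs.mean())
    v = float(zs.var())
    if method == "mle":
        if family == "beta":
            a, b, _, _ = stats.beta.fit(np.clip(zs, 1e-12, 1 - 1e-12), floc=0, fscale=1)
            params = (a, b)
        else:
            a, _, sc = stats.gamma.fit(np.clip(zs, 1e-12, None), floc=0)
            params = (a, sc)
    elif family == "beta":
        common = m * (1 - m) / v - 1.0
        params = (m * common, (1 - m) * common)
    else:
        params = (m * m / v, v / m)  # shape, scale
    return NullApprox(family=family, params=params, n_methods=n_methods,
                      mc_samples=mc_samples, seed=seed)


def _z_batch(r_sorted: np.ndarray) -> np.ndarray:
    """Vectorized Z recursion over rows of sorted ratio matrices."""
    nrow, n = r_sorted.shape
    v = np.zeros((nrow, n + 1))
    v[:, 0] = 1.0
    for k in range(1, n + 1):
        base = r_sorted[:, n - k]
        acc = np.zeros(nrow)
        powb = np.ones(nrow)
        for i in range(1, k + 1):
            powb = powb * base
            acc += (-1) ** (i - 1) * v[:, k - i] / math.factorial(i) * powb
        v[:, k] = acc
    return np.clip(math.factorial(n) * v[:, n], 0.0, 1.0)


def ensemble_rank(
    rankings: list[RankedPrediction],
    null: NullApprox | None = None,
    method_name: str = "ensemble",
) -> RankedPrediction:
    """Aggregate member rankings: per disease compute Z, then rank ascending.

    Member rankings must cover identical disease universes.  When a fitted
    null is supplied, scores are calibrated p-values CDF(Z); ordering is the
    same either way because the CDF is monotone.
    """
    if len(rankings) < 2:
        raise ValueError("ensemble needs at least two member rankings")
    universes = [frozenset(c for c, _, _ in p.entries) for p in rankings]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("member rankings cover different disease sets")
    if null is not None and null.n_methods != len(rankings):
        raise ValueError("null approximation fitted for a different N")
    scored = []
    for codes in universes[0]:
        z = z_statistic(rank_ratios(rankings, codes))
        p = float(null.cdf(z)) if null is not None else z
        scored.append((codes, p))
    return rank_scores(scored, method=method_name, descending=False)


def humanize_ranking(
    human: list[str],
    universe: list[frozenset],
    method: str = "physician",
) -> RankedPrediction:
    """Turn a physician's short ordered candidate list into a full ranking.

    Listed diseases get ranks 1..m in the stated order; all unlisted
    diseases share the worst rank D (ratio 1.0, maximally uninformative).
    Codes not found in the universe are logged and dropped.
    """
    d = len(universe)
    by_code = {c: codes for codes in universe for c in codes}
    picked: list[frozenset] = []
    for code in human:
        codes = by_code.get(code)
        if codes is None:
            logger.warning("physician code %s not in knowledge base; dropped", code)
        elif codes not in picked:
            picked.append(codes)
    scored = []
    for codes in universe:
        if codes in picked:
            scored.append((codes, float(picked.index(codes) + 1)))
        else:
            scored.append((codes, float(d)))
    pred = rank_scores(scored, method=method, descending=False)
    # force unlisted diseases to share exactly rank D (ratio 1.0)
    entries = [
        (codes, score, rank if codes in picked else d)
        for codes, score, rank in pred.entries
    ]
    return RankedPrediction(entries=entries, method=method)


def merge_with_physician(
    model: RankedPrediction,
    human: list[str],
    null: NullApprox | None = None,
) -> RankedPrediction:
    """Order-statistics merge of a model ranking with a physician's list.

    An empty physician list contributes a constant ratio to every disease
    and leaves the model's ordering unchanged.
    """
    universe = [codes for codes, _, _ in model.entries]
    humanized = humanize_ranking(human, universe)
    return ensemble_rank([model, humanized], null=null, method_name="human+model")
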