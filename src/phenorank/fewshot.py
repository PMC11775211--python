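"""Few-shot disease classifiers trained on one "standard case" per disease.

With no per-disease patient corpora available, each disease contributes a
single training example: the multi-hot indicator of its annotation closure.
The training set is then expanded by two augmentation schemes —

* **Mixup**: convex interpolation of two random cases (and their labels)
  with a Beta(alpha, alpha) mixing coefficient;
* **Random Perturbation**: K random edits per sample, drawn from
  {remove, generalize (replace by an ancestor), specialize (replace by a
  descendant), add-noise (activate an unrelated term)} — the kinds of
  corruption real patient phenotype sets exhibit.

Two classifiers consume this training set: Complement Naive Bayes (CNB),
which models the *complement* of each class and is robust when each class
has about one example, and a single-hidden-layer MLP trained with softmax
cross-entropy (supporting the soft labels Mixup produces).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .knowledgebase import KnowledgeBase
from .ontology import Ontology, TermID
from .ranking import RankedPrediction, rank_scores

__all__ = [
    "TrainingMatrix",
    "AugmentationConfig",
    "CNBParams",
    "MLPParams",
    "build_standard_cases",
    "query_vector",
    "mixup",
    "random_perturb",
    "augment",
    "cnb_fit",
    "cnb_rank",
    "MLPModel",
    "mlp_fit",
    "mlp_rank",
]

PERTURB_OPS = ("remove", "generalize", "specialize", "add_noise")


@dataclass
class TrainingMatrix:
    """Training rows X in [0,1]^M with soft labels Y (rows sum to 1).

    The first ``n_classes`` rows are always the untouched standard cases,
    one per disease, in KB order.
    """

    X: np.ndarray
    Y: np.ndarray  # (n_samples, n_classes) soft labels
    term_index: dict[TermID, int]
    disease_codes: list[frozenset]

    @property
    def M(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return self.Y.shape[1]


@dataclass(frozen=True)
class AugmentationConfig:
    mixup_alpha: float = 0.4
    n_mixup: int = 4          # per disease
    perturb_K: int = 2
    perturb_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_perturb: int = 4        # per disease
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.perturb_mix) - 1.0) > 1e-9:
            raise ValueError("perturb_mix proportions must sum to 1")
        if self.perturb_K < 1:
            raise ValueError("perturb_K must be >= 1")


@dataclass(frozen=True)
class CNBParams:
    """Per-column Laplace-style smoothing for the complement counts."""

    alpha_j: float = 1.0


@dataclass(frozen=True)
class MLPParams:
    hidden_size: int = 256
    l2_lambda: float = 1e-4
    learning_rate: float = 0.05
    epochs: int = 200
    seed: int = 0


def build_standard_cases(kb: KnowledgeBase, o: Ontology) -> TrainingMatrix:
    """One multi-hot row per disease: the indicator of its annotation closure.

    Columns cover every term appearing in any disease's closure, in sorted
    term order.
    """
    if not kb.diseases:
        raise ValueError("empty knowledge base")
    closures = [o.annotation_closure(e.terms) for e in kb.diseases]
    all_terms = sorted(set().union(*closures)) if closures else []
    term_index = {t: j for j, t in enumerate(all_terms)}
    n, m = len(kb.diseases), len(all_terms)
    X = np.zeros((n, m))
    for i, cl in enumerate(closures):
        for t in cl:
            X[i, term_index[t]] = 1.0
    Y = np.eye(n)
    return TrainingMatrix(
        X=X, Y=Y, term_index=term_index,
        disease_codes=[frozenset(e.codes) for e in kb.diseases],
    )


def query_vector(
    query: set[TermID],
    term_index: dict[TermID, int],
    o: Ontology,
    close: bool = True,
) -> np.ndarray:
    """Encode a query as a multi-hot vector over the training columns.

    ``close=True`` ancestor-closes the query first, matching the encoding
    of the standard cases; terms outside the column index are ignored.
    """
    terms = o.annotation_closure(query) if close else set(query)
    q = np.zeros(len(term_index))
    for t in terms:
        j = term_index.get(t)
        if j is not None:
            q[j] = 1.0
    return q


# -- augmentation ----------------------------------------------------------


def mixup(
    a: tuple[np.ndarray, np.ndarray],
    b: tuple[np.ndarray, np.ndarray],
    alpha: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Convex combination of two (vector, soft-label) samples, lam ~ Beta(alpha, alpha)."""
    xa, ya = a
    xb, yb = b
    if xa.shape != xb.shape or ya.shape != yb.shape:
        raise ValueError("mixup requires samples of identical dimension")
    lam = rng.beta(alpha, alpha)
    return lam * xa + (1 - lam) * xb, lam * ya + (1 - lam) * yb


def random_perturb(
    x: np.ndarray,
    o: Ontology,
    term_index: dict[TermID, int],
    cfg: AugmentationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply K random edits to a multi-hot phenotype vector; label unchanged.

    Edits: remove an active term (never the last one); generalize/specialize
    replace an active term with a random proper ancestor/descendant present
    in the column index; add-noise activates a term that is neither ancestor
    nor descendant of any active term.  Infeasible edits are skipped.
    """
    index_terms = sorted(term_index, key=term_index.get)
    out = x.copy()
    ops = rng.choice(len(PERTURB_OPS), size=cfg.perturb_K, p=cfg.perturb_mix)
    for op_i in ops:
        op = PERTURB_OPS[op_i]
        active = [index_terms[j] for j in np.flatnonzero(out > 0.5)]
        if not active:
            break
        if op == "remove":
            if len(active) <= 1:
                continue
            t = active[rng.integers(len(active))]
            out[term_index[t]] = 0.0
        elif op in ("generalize", "specialize"):
            t = active[rng.integers(len(active))]
            pool = (
                o.ancestors(t) if op == "generalize" else o.descendants(t)
            )
            cand = sorted(p for p in pool if p in term_index)
            if not cand:
                continue
            repl = cand[rng.integers(len(cand))]
            out[term_index[t]] = 0.0
            out[term_index[repl]] = 1.0
        else:  # add_noise
            related = set()
            for t in active:
                related |= o.ancestors(t, include_self=True)
                related |= o.descendants(t)
            cand = sorted(t for t in index_terms if t not in related)
            if not cand:
                continue
            out[term_index[cand[rng.integers(len(cand))]]] = 1.0
    return out


def augment(
    train: TrainingMatrix, o: Ontology, cfg: AugmentationConfig
) -> TrainingMatrix:
    """Standard cases plus n_mixup + n_perturb synthetic samples per disease.

    The original standard-case rows are kept untouched at the top of the
    matrix; all randomness flows through one generator seeded by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = train.X.shape[0]
    xs, ys = [train.X], [train.Y]
    if n >= 2:
        for _ in range(cfg.n_mixup * n):
            i, j = rng.choice(n, size=2, replace=False)
            x, y = mixup(
                (train.X[i], train.Y[i]), (train.X[j], train.Y[j]),
                cfg.mixup_alpha, rng,
            )
            xs.append(x[None, :])
            ys.append(y[None, :])
    for i in range(n):
        for _ in range(cfg.n_perturb):
            x = random_perturb(train.X[i], o, train.term_index, cfg, rng)
            xs.append(x[None, :])
            ys.append(train.Y[i][None, :])
    return TrainingMatrix(
        X=np.vstack(xs), Y=np.vstack(ys),
        term_index=train.term_index, disease_codes=train.disease_codes,
    )


# -- Complement Naive Bayes ------------------------------------------------


def cnb_fit(train: TrainingMatrix, params: CNBParams = CNBParams()) -> np.ndarray:
    """Complement feature statistics theta[k, j].

    theta_kj = (alpha_j + sum_{y_i != k} x_ij) / (alpha + sum_{y_i != k} sum_j' x_ij'),
    where membership of sample i in class k's complement is weighted by its
    soft label mass off class k (hard labels reduce to the plain definition).
    """
    n, m = train.X.shape
    k = train.n_classes
    if k < 2:
        raise ValueError("CNB requires at least two diseases")
    alpha_j = params.alpha_j
    alpha = alpha_j * m
    # complement weight of sample i for class k: 1 - Y[i, k]
    comp = 1.0 - train.Y  # (n, k)
    num = alpha_j + comp.T @ train.X                      # (k, m)
    den = alpha + (comp.T @ train.X.sum(axis=1))[:, None]  # (k, 1)
    return num / den


def cnb_rank(
    q: np.ndarray,
    theta: np.ndarray,
    disease_codes: list[frozenset],
) -> RankedPrediction:
    """Rank by s_k = sum_j q_j log theta_kj, ascending (small complement mass
    means the query looks unlike "everything but disease k")."""
    with np.errstate(divide="ignore"):
        logt = np.log(theta)
    s = logt @ q  # -inf propagates as strongest possible evidence
    scored = [(codes, float(s[k])) for k, codes in enumerate(disease_codes)]
    return rank_scores(scored, method="cnb", descending=False)


# -- single-hidden-layer MLP ----------------------------------------------


@dataclass
class MLPModel:
    """Weights of a 1-hidden-layer softmax network plus its column index."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    term_index: dict[TermID, int]
    disease_codes: list[frozenset] = field(default_factory=list)

    def predict_proba(self, q: np.ndarray) -> np.ndarray:
        h = np.tanh(q @ self.W1 + self.b1)
        z = h @ self.W2 + self.b2
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)


def mlp_fit(
    train: TrainingMatrix,
    params: MLPParams = MLPParams(),
    cfg: AugmentationConfig | None = None,
    o: Ontology | None = None,
) -> MLPModel:
    """Train the MLP by full-batch Adam on softmax cross-entropy + L2.

    If ``cfg`` and ``o`` are given the training matrix is augmented first.
    Deterministic for a fixed (params.seed, cfg.seed) pair.
    """
    if cfg is not None:
        if o is None:
            raise ValueError("augmentation requires the ontology")
        train = augment(train, o, cfg)
    rng = np.random.default_rng(params.seed)
    n, m = train.X.shape
    k = train.n_classes
    hs = params.hidden_size
    W1 = rng.normal(0, 1.0 / np.sqrt(max(m, 1)), size=(m, hs))
    b1 = np.zeros(hs)
    W2 = rng.normal(0, 1.0 / np.sqrt(hs), size=(hs, k))
    b2 = np.zeros(k)
    mom = [np.zeros_like(p) for p in (W1, b1, W2, b2)]
    vel = [np.zeros_like(p) for p in (W1, b1, W2, b2)]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    X, Y = train.X, train.Y
    for step in range(1, params.epochs + 1):
        H = np.tanh(X @ W1 + b1)
        Z = H @ W2 + b2
        Z = Z - Z.max(axis=1, keepdims=True)
        E = np.exp(Z)
        P = E / E.sum(axis=1, keepdims=True)
        dZ = (P - Y) / n
        gW2 = H.T @ dZ + params.l2_lambda * W2
        gb2 = dZ.sum(axis=0)
        dH = dZ @ W2.T * (1.0 - H * H)
        gW1 = X.T @ dH + params.l2_lambda * W1
        gb1 = dH.sum(axis=0)
        grads = (gW1, gb1, gW2, gb2)
        new = []
        for idx, (p, g) in enumerate(zip((W1, b1, W2, b2), grads)):
            mom[idx] = beta1 * mom[idx] + (1 - beta1) * g
            vel[idx] = beta2 * vel[idx] + (1 - beta2) * g * g
            mhat = mom[idx] / (1 - beta1**step)
            vhat = vel[idx] / (1 - beta2**step)
            new.append(p - params.learning_rate * mhat / (np.sqrt(vhat) + eps))
        W1, b1, W2, b2 = new
    return MLPModel(W1=W1, b1=b1, W2=W2, b2=b2,
                    term_index=train.term_index,
                    disease_codes=train.disease_codes)


def mlp_rank(q: np.ndarray, model: MLPModel) -> RankedPrediction:
    """Rank diseases by descending predicted class probability."""
    p = model.predict_proba(q)
    scored = [(codes, float(p[k])) for k, codes in enumerate(model.disease_codes)]
    return rank_scores(scored, method="mlp", descending=True)
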