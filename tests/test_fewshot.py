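import math

import numpy as np
import pytest

from phenorank.fewshot import (
    AugmentationConfig,
    CNBParams,
    MLPParams,
    augment,
    build_standard_cases,
    cnb_fit,
    cnb_rank,
    mixup,
    mlp_fit,
    mlp_rank,
    query_vector,
    random_perturb,
)
from phenorank.knowledgebase import KnowledgeBase
from phenorank.ontology import from_edges

from conftest import make_entry, random_dag, random_kb


class FixedBeta:
    """rng stub returning a forced Beta draw."""

    def __init__(self, lam):
        self.lam = lam

    def beta(self, a, b):
        return self.lam


@pytest.fixture
def two_disease_matrix():
    """Hand matrix: rows (1,1,0) and (0,1,1), hard labels."""
    from phenorank.fewshot import TrainingMatrix

    return TrainingMatrix(
        X=np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]]),
        Y=np.eye(2),
        term_index={"X:0": 0, "X:1": 1, "X:2": 2},
        disease_codes=[frozenset({"D:1"}), frozenset({"D:2"})],
    )


class TestStandardCases:
    def test_rows_are_closure_indicators(self, six_node):
        kb = KnowledgeBase(diseases=[
            make_entry("D:1", {"X:3": None}),
            make_entry("D:2", {"X:5": None}),
        ])
        train = build_standard_cases(kb, six_node)
        # columns: union of closures = {X:0, X:1, X:2, X:3, X:5}
        assert train.M == 5
        cl1 = six_node.annotation_closure({"X:3"})
        for t, j in train.term_index.items():
            assert train.X[0, j] == (1.0 if t in cl1 else 0.0)

    def test_root_only_disease(self, chain):
        kb = KnowledgeBase(diseases=[
            make_entry("D:1", {"X:0": None}),
            make_entry("D:2", {"X:2": None}),
        ])
        train = build_standard_cases(kb, chain)
        i = [k for k, c in enumerate(train.disease_codes) if "D:1" in c][0]
        row = train.X[i]
        assert row.sum() == 1.0
        assert row[train.term_index["X:0"]] == 1.0

    def test_matches_brute_force_closures(self):
        rng = np.random.default_rng(17)
        o = random_dag(rng, 25)
        kb = random_kb(o, rng, 8)
        train = build_standard_cases(kb, o)
        for i, entry in enumerate(kb.diseases):
            cl = o.annotation_closure(entry.terms)
            for t, j in train.term_index.items():
                assert train.X[i, j] == (1.0 if t in cl else 0.0)

    def test_labels_one_hot(self, two_disease_matrix):
        assert np.allclose(two_disease_matrix.Y, np.eye(2))


class TestMixup:
    def test_midpoint(self):
        x, y = mixup(
            (np.array([1.0, 0.0]), np.array([1.0, 0.0])),
            (np.array([0.0, 1.0]), np.array([0.0, 1.0])),
            alpha=0.4, rng=FixedBeta(0.5),
        )
        assert np.allclose(x, [0.5, 0.5]) and np.allclose(y, [0.5, 0.5])

    def test_endpoint(self):
        a = (np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        b = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        x, y = mixup(a, b, alpha=0.4, rng=FixedBeta(1.0))
        assert np.allclose(x, a[0]) and np.allclose(y, a[1])

    def test_beta_symmetry_monte_carlo(self):
        rng = np.random.default_rng(123)
        lams = [rng.beta(0.4, 0.4) for _ in range(100)]
        se = math.sqrt(np.var(lams) / len(lams))
        assert abs(np.mean(lams) - 0.5) < 3 * se + 1e-9

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mixup((np.zeros(2), np.zeros(2)), (np.zeros(3), np.zeros(2)),
                  0.4, FixedBeta(0.5))

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(5)
        xa, xb = rng.random(10), rng.random(10)
        x, _ = mixup((xa, np.array([1.0, 0])), (xb, np.array([0, 1.0])),
                     0.4, rng)
        assert np.all(x >= np.minimum(xa, xb) - 1e-12)
        assert np.all(x <= np.maximum(xa, xb) + 1e-12)


class TestRandomPerturb:
    def _setup(self):
        rng = np.random.default_rng(31)
        o = random_dag(rng, 30)
        kb = random_kb(o, rng, 5, lo=4, hi=6)
        train = build_standard_cases(kb, o)
        return o, train

    def test_pure_removal_count(self):
        o, train = self._setup()
        cfg = AugmentationConfig(perturb_K=1, perturb_mix=(1.0, 0, 0, 0), seed=0)
        rng = np.random.default_rng(0)
        x = train.X[0]
        out = random_perturb(x, o, train.term_index, cfg, rng)
        assert out.sum() == x.sum() - 1

    def test_removal_never_empties(self):
        o, train = self._setup()
        cfg = AugmentationConfig(perturb_K=50, perturb_mix=(1.0, 0, 0, 0), seed=0)
        rng = np.random.default_rng(1)
        out = random_perturb(train.X[0], o, train.term_index, cfg, rng)
        assert out.sum() >= 1

    def test_generalize_moves_to_ancestor(self, chain):
        kb = KnowledgeBase(diseases=[make_entry("D:1", {"X:2": None}),
                                     make_entry("D:2", {"X:1": None})])
        train = build_standard_cases(kb, chain)
        x = np.zeros(train.M)
        x[train.term_index["X:2"]] = 1.0
        cfg = AugmentationConfig(perturb_K=1, perturb_mix=(0, 1.0, 0, 0), seed=0)
        out = random_perturb(x, chain, train.term_index, cfg,
                             np.random.default_rng(2))
        assert out[train.term_index["X:2"]] == 0.0
        active = {t for t, j in train.term_index.items() if out[j] == 1.0}
        assert active <= {"X:0", "X:1"} and len(active) == 1

    def test_noise_term_unrelated(self):
        o, train = self._setup()
        cfg = AugmentationConfig(perturb_K=1, perturb_mix=(0, 0, 0, 1.0), seed=0)
        rng = np.random.default_rng(3)
        x = train.X[0]
        out = random_perturb(x, o, train.term_index, cfg, rng)
        added = np.flatnonzero((out > 0.5) & (x < 0.5))
        idx_terms = sorted(train.term_index, key=train.term_index.get)
        active = [idx_terms[j] for j in np.flatnonzero(x > 0.5)]
        for j in added:
            t = idx_terms[j]
            for a in active:
                assert t not in o.ancestors(a, include_self=True)
                assert t not in o.descendants(a)

    def test_deterministic_given_seed(self):
        o, train = self._setup()
        cfg = AugmentationConfig(perturb_K=3, seed=0)
        out1 = random_perturb(train.X[1], o, train.term_index, cfg,
                              np.random.default_rng(42))
        out2 = random_perturb(train.X[1], o, train.term_index, cfg,
                              np.random.default_rng(42))
        assert np.array_equal(out1, out2)


class TestAugment:
    def test_standard_rows_preserved_and_counts(self):
        rng = np.random.default_rng(8)
        o = random_dag(rng, 20)
        kb = random_kb(o, rng, 4)
        train = build_standard_cases(kb, o)
        cfg = AugmentationConfig(n_mixup=2, n_perturb=3, seed=9)
        aug = augment(train, o, cfg)
        n = train.X.shape[0]
        assert np.array_equal(aug.X[:n], train.X)
        assert np.array_equal(aug.Y[:n], train.Y)
        assert aug.X.shape[0] == n + 2 * n + 3 * n

    def test_soft_labels_sum_to_one(self):
        rng = np.random.default_rng(10)
        o = random_dag(rng, 20)
        kb = random_kb(o, rng, 4)
        aug = augment(build_standard_cases(kb, o), o, AugmentationConfig(seed=1))
        assert np.allclose(aug.Y.sum(axis=1), 1.0)


class TestCNB:
    def test_hand_computed_theta(self, two_disease_matrix):
        theta = cnb_fit(two_disease_matrix, CNBParams(alpha_j=1.0))
        # columns sorted by term id: X:0, X:1, X:2; rows (1,1,0), (0,1,1)
        ti = two_disease_matrix.term_index
        k1 = 0  # complement of class 0 = row 2 = (0,1,1)
        assert theta[k1, ti["X:0"]] == pytest.approx((1 + 0) / (3 + 2))
        assert theta[k1, ti["X:1"]] == pytest.approx((1 + 1) / 5)
        assert theta[k1, ti["X:2"]] == pytest.approx(0.4)

    def test_degenerate_zero_smoothing(self, two_disease_matrix):
        theta = cnb_fit(two_disease_matrix, CNBParams(alpha_j=0.0))
        assert theta.min() == 0.0  # caller handles log 0

    def test_single_class_rejected(self, chain):
        kb = KnowledgeBase(diseases=[make_entry("D:1", {"X:2": None}),
                                     make_entry("D:2", {"X:1": None})])
        train = build_standard_cases(kb, chain)
        train.Y = train.Y[:, :1]
        with pytest.raises(ValueError):
            cnb_fit(train)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(21)
        o = random_dag(rng, 20)
        kb = random_kb(o, rng, 5)
        train = build_standard_cases(kb, o)
        aug = augment(train, o, AugmentationConfig(seed=3))
        theta = cnb_fit(aug, CNBParams(alpha_j=1.0))
        n, m = aug.X.shape
        for k in range(aug.n_classes):
            denom = m + sum(
                (1 - aug.Y[i, k]) * aug.X[i, jp]
                for i in range(n) for jp in range(m)
            )
            for j in range(m):
                num = 1 + sum((1 - aug.Y[i, k]) * aug.X[i, j] for i in range(n))
                assert theta[k, j] == pytest.approx(num / denom)

    def test_rank_zero_query_full_tie(self, two_disease_matrix):
        theta = cnb_fit(two_disease_matrix)
        pred = cnb_rank(np.zeros(3), theta, two_disease_matrix.disease_codes)
        assert [r for _, _, r in pred.entries] == [1, 1]

    def test_rank_hand_example(self, two_disease_matrix):
        theta = cnb_fit(two_disease_matrix)
        ti = two_disease_matrix.term_index
        q = np.zeros(3)
        q[ti["X:0"]] = 1.0
        # s_1 = log 0.2 < s_2 = log 0.4: disease 1 first under ascending order
        pred = cnb_rank(q, theta, two_disease_matrix.disease_codes)
        assert pred.rank_of("D:1") == 1

    def test_ranking_invariant_to_log_base(self, two_disease_matrix):
        theta = cnb_fit(two_disease_matrix)
        q = np.array([1.0, 0.0, 1.0])
        pred = cnb_rank(q, theta, two_disease_matrix.disease_codes)
        scores = np.array([s for _, s, _ in pred.entries])
        rescaled = scores / math.log(10)  # natural log -> log10
        assert np.array_equal(np.argsort(scores), np.argsort(rescaled))


class TestMLP:
    def _separable(self):
        # three diseases with disjoint closures under distinct branches
        o = from_edges([
            ("X:1", "X:0"), ("X:2", "X:0"), ("X:3", "X:0"),
            ("X:4", "X:1"), ("X:5", "X:2"), ("X:6", "X:3"),
        ])
        kb = KnowledgeBase(diseases=[
            make_entry("D:1", {"X:4": None}),
            make_entry("D:2", {"X:5": None}),
            make_entry("D:3", {"X:6": None}),
        ])
        return o, kb

    def test_separable_standard_cases_rank_first(self):
        o, kb = self._separable()
        train = build_standard_cases(kb, o)
        model = mlp_fit(train, MLPParams(hidden_size=16, epochs=100, seed=0))
        for i, entry in enumerate(kb.diseases):
            pred = mlp_rank(train.X[i], model)
            assert pred.rank_of(entry.codes) == 1

    def test_deterministic_given_seeds(self):
        o, kb = self._separable()
        train = build_standard_cases(kb, o)
        cfg = AugmentationConfig(seed=4)
        m1 = mlp_fit(train, MLPParams(hidden_size=8, epochs=50, seed=1), cfg, o)
        m2 = mlp_fit(train, MLPParams(hidden_size=8, epochs=50, seed=1), cfg, o)
        assert np.array_equal(m1.W1, m2.W1) and np.array_equal(m1.W2, m2.W2)

    def test_zero_epochs_deterministic_output(self):
        o, kb = self._separable()
        train = build_standard_cases(kb, o)
        m1 = mlp_fit(train, MLPParams(hidden_size=8, epochs=0, seed=1))
        m2 = mlp_fit(train, MLPParams(hidden_size=8, epochs=0, seed=1))
        q = train.X[0]
        assert np.array_equal(m1.predict_proba(q), m2.predict_proba(q))

    def test_agrees_with_sklearn_on_hard_labels(self):
        """Cross-check: sklearn's MLP separates the same fixture."""
        from sklearn.neural_network import MLPClassifier

        o, kb = self._separable()
        train = build_standard_cases(kb, o)
        clf = MLPClassifier(hidden_layer_sizes=(16,), max_iter=2000,
                            random_state=0).fit(train.X, train.Y.argmax(axis=1))
        ours = mlp_fit(train, MLPParams(hidden_size=16, epochs=100, seed=0))
        for i in range(3):
            assert clf.predict(train.X[i:i + 1])[0] == i
            assert mlp_rank(train.X[i], ours).rank_of(
                kb.diseases[i].codes
            ) == 1


def test_query_vector_closure_matches_standard_encoding(six_node):
    kb = KnowledgeBase(diseases=[
        make_entry("D:1", {"X:3": None}),
        make_entry("D:2", {"X:4": None}),
    ])
    train = build_standard_cases(kb, six_node)
    q = query_vector({"X:3"}, train.term_index, six_node)
    i = [k for k, c in enumerate(train.disease_codes) if "D:1" in c][0]
    assert np.array_equal(q, train.X[i])


def test_cnb_agrees_with_sklearn_complement_nb():
    """Independent oracle: sklearn ComplementNB (norm=False) scores."""
    from sklearn.naive_bayes import ComplementNB

    rng = np.random.default_rng(44)
    o = random_dag(rng, 20)
    kb = random_kb(o, rng, 6)
    train = build_standard_cases(kb, o)
    theta = cnb_fit(train, CNBParams(alpha_j=1.0))
    clf = ComplementNB(alpha=1.0, norm=False).fit(
        train.X, train.Y.argmax(axis=1)
    )
    # sklearn stores feature_log_prob_ = -log(theta)
    assert np.allclose(clf.feature_log_prob_, -np.log(theta))
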