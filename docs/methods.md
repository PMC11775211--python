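# Methods

This note documents the models implemented in `phenorank`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Ontology and information content

The ontology is a validated single-rooted DAG over is-a edges; other edge
types (e.g. part-of) are ignored at load time, obsolete terms are dropped,
and multi-rooted inputs are rejected (callers should pre-filter to a
sub-ontology). The annotation closure `A(H)` of a term set is the union of
each term with all its ancestors.

Information content uses natural logarithms throughout. The log base only
rescales every score monotonically, so rankings are invariant to it; nats
are used and documented rather than left ambiguous. `P(t)` counts diseases
through ancestor-closed annotation sets by default (`compute_ic(...,
closure=True)`): a disease annotated with a specific term implicitly carries
every ancestor, which is the semantics the similarity and Bayes models
assume when they intersect queries with `A(H_k)`. Raw (un-closed) counting
is available via the flag. Terms annotating no disease receive the smallest
observed nonzero probability rather than zero, keeping IC finite for query
terms absent from the knowledge base; under closure-based counting the root
has probability 1 and IC 0, and IC is anti-monotone along every edge.

## Knowledge base

HPOA-style TSV sources are merged through an explicit equivalence table of
disease codes; no equivalences are inferred. Annotation frequencies are
parsed from `a/b` fractions, `n%` percentages, and the categorical frequency
classes, which map to the midpoints of their defining intervals: obligate
1.0, very frequent 0.895, frequent 0.545, occasional 0.17, very rare 0.025.
"Excluded" (zero-frequency) annotations are dropped. When two sources give
conflicting frequencies for the same (disease, term), the record from the
higher-priority source wins; the default priority is CCRD > OMIM >
Orphanet, configurable. Entries with very few annotations are retained (the
methods must not crash on them). Serialization is sorted-key JSON so builds
are bit-reproducible, and merging is order-insensitive at the term-set
level.

## Diagnostic models

**ICTO.** One-sided score `Σ IC(t)` over `t ∈ Q ∩ A(H_k)`; the symmetric
score averages the two directions. Because only terms inside the disease's
closure contribute, adding out-of-closure terms to the query cannot change
the one-sided score. The implementation sums over sorted terms so this
invariance holds bit-exactly in floating point, not just mathematically.

**PPO.** Per-term conditionals: a directly annotated term uses its recorded
frequency, or the default probability `dp` when the frequency is unknown
(dp = 0.5 by default; it is a tuning parameter and exposed as
configuration). A term that is both annotated and an ancestor of other
annotated terms keeps its direct frequency. Un-annotated closure members are
filled bottom-up over `C_k = children(t) ∩ A(H_k)` by one of three rules;
`f_ind` is the default because it is bounded between the other two
(`f_max ≤ f_ind ≤ f_sum` at every ancestor, asserted in tests) and treats
children as independent evidence, consistent with the model's
conditional-independence assumption. A single closure child reduces all
three rules to the child's value, and the implementation short-circuits
that case so the rules agree bit-exactly there. Terms outside the closure
use the background `P(t)` (same counting convention as the IC table, floored
away from zero). The disease prior is uniform, so ranking uses the log
conditional likelihood only. Gene evidence, when supplied, adds
`ln P(g|d_k)` per gene with a configurable background of 1e-3 for unlisted
(gene, disease) pairs.

Note that self-retrieval at rank 1 from a disease's own full annotation set
is not a theorem for PPO: a disease whose annotations carry low frequencies
(e.g. many "occasional" terms) can be outscored by a rival whose closure
happens to cover the query with higher propagated probabilities. On the
seeded evaluation worlds used in the tests this does not occur, but across
arbitrary worlds PPO's self-retrieval fraction can fall below 1.0 while the
score computation is still exactly the sum-of-logs model (verified against
a brute-force oracle).

**Few-shot classifiers.** Each disease contributes one "standard case": the
multi-hot indicator of its annotation closure over the union of all closure
terms. Queries are ancestor-closed before encoding to match (configurable).
Augmentation defaults — 4 Mixup and 4 perturbation samples per disease,
Beta(0.4, 0.4) mixing, K = 2 edits with equal mix over remove / generalize /
specialize / add-noise — are conventional small values; none are critical
and all sit in `AugmentationConfig`. Removal never empties a case, and the
untouched standard rows always stay at the top of the training matrix. CNB
uses Laplace smoothing (α_j = 1) by default; its θ statistics generalize to
soft labels by weighting sample i's complement membership by `1 − y_ik`,
which reduces exactly to the hard-label definition on one-hot labels (and is
cross-checked against scikit-learn's ComplementNB). With α_j = 0 a zero θ
yields a −∞ log term, which ranks as the strongest possible evidence for
the class — documented behavior, not an error. The MLP is a one-hidden-layer
softmax network (hidden 256, L2 1e-4, 200 epochs of full-batch Adam at
learning rate 0.05, fixed-seed initialization) trained on softmax
cross-entropy. It is implemented in numpy rather than delegated to
scikit-learn because Mixup produces soft label vectors, which
`MLPClassifier` does not accept; scikit-learn serves as an independent
cross-check on hard-label fixtures instead. Zero-epoch models are valid and
deterministic (useful for testing).

**Ensemble.** Rank ratios `rank/D` per member method are sorted ascending
before the recursion — the joint CDF of order statistics is only defined
over the ordered region, and the recursion indexes `r_{N−k+1}` accordingly.
Z is clipped to [0, 1] against float round-off. The null distribution of Z
under independent uniform rankings is simulated (default 1e5 sorted-uniform
vectors) and fitted by moment matching — Beta for N ≤ 5, Gamma for N > 5 —
because moment matching is cheap, deterministic, and reproducible; a
maximum-likelihood fit is available behind a flag. The default ensemble
members are ICTO, PPO, CNB, and MLP (N = 4). Physician lists are merged by
converting the ordered candidate list to a full ranking: listed diseases
take ranks 1..m, all unlisted diseases share the maximally uninformative
ratio 1.0, and the two-member ensemble re-ranks. This convention is the
package's own; short candidate lists are not total orders and some
convention is required.

## Evaluation

First-hit rank is the best rank among a case's true diagnoses; a true
disease absent from the prediction scores the sentinel D + 1, which keeps
medians finite while penalizing the miss. Ranks use competition (min-rank)
ties with lexicographic display order, a deterministic and conservative
convention. Top-k recall is the fraction of cases with first-hit rank ≤ k;
the bootstrap is the percentile flavor (2.5/97.5) with 10,000 repetitions by
default, deterministic under its seed; BCa is deliberately not implemented.
Method comparisons use the two-sided Wilcoxon signed-rank test with the
Pratt treatment of zero differences; all-tied inputs report p = 1.

## Synthetic data

The generator emulates the *structure* the methods consume, not the
empirical distributions of any real registry: a single-rooted DAG grown by
preferential attachment to recent nodes (diamond edges added with
probability 0.15), leaf-biased annotation draws (weight 1 + depth, because
real annotations skew specific), class-style frequencies drawn as 20%
obligate / 40% very frequent / 30% frequent / 10% occasional on a
configurable 60% of annotations, and cases built by frequency-weighted
sampling of a disease's annotations followed by two corruptions:
imprecision replaces a fraction of terms with random proper ancestors
(never the root), and noise adds terms outside both the ancestor and
descendant cones of the disease's annotations. Every emitted case has at
least three phenotypes, matching the usual evaluation filter, and emitted
noise terms are verifiable post hoc as out-of-cone. Four presets
(noise-low/high at rates 0.2/0.5, imprecise-low/high likewise) cover the
standard corruption scenarios.

Each case attempt draws from its own spawned RNG stream, so two configs
differing only in corruption rates generate the same disease and base-term
skeletons — corruption comparisons across noise levels are paired, which is
what makes the monotone-degradation checks sharp at 200 cases.

Passing tests on these worlds demonstrates the algorithms' correctness and
their qualitative behavior under corruption. They do not demonstrate
clinical performance: real ontologies are deeper and wider, real annotation
sets are larger and correlated, and real patient noise is not uniform over
unrelated terms.

## Numerical conventions and test design

* Natural logs everywhere; log-base changes rankings nowhere.
* Deterministic seeding: one global seed fans out to per-stream seeds via
  SHA-256 of `"{seed}:{stream}"` reduced below 2^31, so adding a method
  never perturbs another stream.
* Problem sizes in the test suite and acceptance script — 150-term
  ontologies, 20–30 diseases, 200 cases per corruption level, 1e6-sample
  Monte-Carlo checks of the order-statistics recursion, 1e5-sample null
  fits — were chosen as the smallest sizes at which the checked properties
  are sharp.
* Monte-Carlo agreement checks flag a vector when the recursion differs
  from the estimate by more than 3 standard errors, then re-estimate flagged
  vectors once from an independent sample. With ~400 three-sigma
  comparisons, one-shot testing would fail on statistical flukes about
  two-thirds of the time even for an exact recursion; the two-stage check
  keeps the 3-SE agreement band per comparison while a genuinely wrong
  recursion still fails decisively because its bias does not resample away.
* MinIC is implemented as `IC(MICA) / min(IC(a), IC(b))` with identical
  terms scoring 1 by convention. A literal minimum of IC over common
  ancestors is degenerate — the root is a common ancestor of every pair, so
  that score is identically zero. Lin similarity uses the same
  identity-scores-1 convention, which also removes a zero-IC 0/0 case.
* Best-match-average aggregation (symmetric mean of the two directed best
  matches) is used for Resnik/Lin/JC/MinIC; best-pair aggregation is not
  implemented. Unnormalized Resnik BMA can rank a disease annotating only
  the highest-IC subset of a query above the true disease on small dense
  ontologies; this is a property of the measure, not a bug.

## Known limitations

No OWL parsing, no non-is-a relations, no cross-ontology mappings, no
variant-severity weighting of gene evidence, no department-stratified
reporting beyond a group-by, and no attempt to reproduce real-registry case
distributions. The CLI covers simulation, KB building, diagnosis, null
fitting, evaluation, and an all-in-one run; web services and interactive
use are out of scope.
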