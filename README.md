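# phenorank

Ontology-based differential diagnosis of rare diseases from patient
phenotype profiles.

Rare diseases are individually uncommon but collectively affect hundreds of
millions of people, and their diagnosis is routinely delayed by years: a
clinician must differentiate among thousands of candidate disorders, each
presenting with overlapping, partially observed combinations of phenotypes.
`phenorank` is a library and CLI for researchers and tool builders working
on this problem. Given

* a phenotype ontology — a single-rooted DAG of terms linked by is-a edges
  (HPO or a synthetic look-alike),
* a disease–phenotype annotation knowledge base (HPOA-style TSV sources
  merged through a disease-code equivalence table), and
* a patient's set of phenotype terms Q,

it ranks every knowledge-base disease by each of several methods and fuses
the rankings with an order-statistics ensemble.

## Methods

With `H_k` the annotation set of disease `d_k` and `A(H_k)` its ancestor
closure in the ontology:

* **ICTO** — information-content term overlap:
  `Sim(Q→H_k) = Σ_{t ∈ Q ∩ A(H_k)} IC(t)` with `IC(t) = −ln P(t)`, where
  `P(t)` is the fraction of diseases annotated (under closure) with `t`;
  symmetrized as the mean of the two directed scores. The one-sided score is
  provably insensitive to query terms outside `A(H_k)` — the "noise"
  phenotypes that plague real patient records.
* **PPO** — probability propagation in the ontology: a naive-Bayes model
  `log P(d_k|Q) ∝ Σ_{t∈Q} ln P(t|d_k)` whose per-term conditionals come from
  annotation frequencies, propagated bottom-up to un-annotated ancestors by
  `f_max` (max child), `f_ind` (1 − Π(1 − p), default), or `f_sum`
  (capped sum); terms outside the closure fall back to the background
  `P(t)`. Optional gene evidence enters as `Σ_{g∈G} ln P(g|d_k)`.
* **CNB** — complement naive Bayes over "standard cases" (one multi-hot
  closure indicator per disease):
  `θ_kj = (α_j + Σ_{y_i≠k} x_ij) / (α + Σ_{y_i≠k} Σ_j' x_ij')`, ranking by
  ascending `Σ_j q_j log θ_kj`.
* **MLP** — a single-hidden-layer softmax network trained on the standard
  cases augmented by Mixup (`λ ~ Beta(α, α)` convex interpolation) and
  Random Perturbation (remove / generalize / specialize / add-noise edits).
* **Ensemble** — per disease, the sorted rank ratios `r_1 ≤ … ≤ r_N` across
  methods are scored by the joint CDF of N uniform order statistics,
  `Z = N!·V_N` with `V_k = Σ_i (−1)^{i−1} (V_{k−i}/i!) r_{N−k+1}^i`;
  smaller Z means stronger consensus. P-values come from a simulated null
  (Beta fit for N ≤ 5, Gamma above). The same machinery merges a
  physician's short candidate list with a model ranking.
* Baselines: SimGIC, SimUI (Jaccard), term overlap, cosine over closures,
  and best-match-average Resnik / Lin / Jiang–Conrath / MinIC.

Evaluation follows the field's conventions: per-case first-hit rank (best
rank among the true diagnoses), top-k recall, median rank, 10,000-rep
percentile bootstrap CIs, and paired Wilcoxon signed-rank comparisons.
A synthetic-data module generates seeded ontologies, knowledge bases, and
patient cases corrupted by "noise" (unrelated) and "imprecise"
(ancestor-replaced) phenotypes so the whole stack is testable offline.

## Worked example

Simulate a 150-term ontology with 30 diseases, draw 100 patient cases with
30% added noise phenotypes, rank with all four methods plus the ensemble,
and evaluate:

```bash
cat > scenario.yaml <<EOF
n_terms: 150
n_diseases: 30
noise_rate: 0.3
n_cases: 100
EOF
phenorank run scenario.yaml --seed 11 --out-dir out/
```

`out/metrics.json` then contains, per method, the median first-hit rank,
top-k recall, and bootstrap CIs. With this seed:

| method   | median rank | top-1 | top-3 | top-10 |
|----------|------------:|------:|------:|-------:|
| icto     | 1.0         | 0.95  | 1.00  | 1.00   |
| ppo      | 1.0         | 0.79  | 0.93  | 0.98   |
| cnb      | 1.0         | 0.78  | 0.99  | 1.00   |
| mlp      | 1.0         | 0.78  | 0.91  | 1.00   |
| ensemble | 1.0         | 0.93  | 1.00  | 1.00   |

Reading: with a third of each query being unrelated noise, every method
still places the true disease near the top of the 30-disease list; the
order-statistics ensemble recovers almost all of the best single method's
top-1 accuracy while being more robust than any fixed member across noise
levels. The per-case predictions are written alongside as TSV.

The same engine is available as a library:

```python
from phenorank import DiagnosisEngine, SimConfig, make_world
from phenorank.evaluate import evaluate_predictions

ontology, kb, cases = make_world(SimConfig(noise_rate=0.3, seed=11), n_cases=100)
engine = DiagnosisEngine(ontology=ontology, kb=kb, seed=11)
predictions = engine.diagnose(cases)
truth = {c.case_id: c.true_codes for c in cases}
print(evaluate_predictions(predictions["ensemble"], truth).top_k_recall)
```

Real data enter through `phenorank build-kb` (OBO ontology + HPOA-style
TSVs + a two-column code-equivalence table) and JSONL case files; see
`phenorank --help`.

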