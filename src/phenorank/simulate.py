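"""Synthetic ontologies, knowledge bases, and patient cases.

The generator emulates the structure the diagnostic methods consume: a
single-rooted DAG of phenotype terms (with diamond paths), per-disease
annotation sets biased toward specific (deep) terms with optional
class-style frequencies, and patient cases built from a disease's
annotations and then corrupted by

* **imprecision** — replacing a fraction of terms with proper ancestors,
  the way clinicians record general rather than specific findings; and
* **noise** — adding terms unrelated (neither ancestor nor descendant) to
  any of the disease's phenotypes.

Emitted cases always carry at least three phenotypes, matching the usual
inclusion filter for evaluation datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .knowledgebase import (
    FREQUENCY_CLASS_MIDPOINTS,
    DiseaseEntry,
    FrequencyRecord,
    KnowledgeBase,
)
from .ontology import Ontology, TermID, from_edges
from .ranking import PatientCase

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "PRESETS", "make_ontology", "make_kb", "make_cases", "make_world"]

TERM_PREFIX = "SIM"
DISEASE_PREFIX = "SIMD"

# class-label mixture for synthetic frequency annotations:
# (obligate, very frequent, frequent, occasional)
_FREQ_CLASSES = ("HP:0040280", "HP:0040281", "HP:0040282", "HP:0040283")
_FREQ_WEIGHTS = (0.2, 0.4, 0.3, 0.1)


@dataclass(frozen=True)
class SimConfig:
    n_terms: int = 150
    n_diseases: int = 30
    dag_branching: float = 3.0          # mean children per internal node
    second_parent_prob: float = 0.15    # chance a term gets a diamond edge
    annotations_per_disease: tuple[int, int] = (6, 12)
    frequency_coverage: float = 0.6
    duplicate_fraction: float = 0.0     # fraction of diseases cloning another's set
    noise_rate: float = 0.0             # noise terms added per drawn term
    imprecision_rate: float = 0.0       # fraction replaced by proper ancestors
    terms_per_case: tuple[int, int] = (4, 8)
    min_case_terms: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.noise_rate, self.imprecision_rate, self.frequency_coverage,
                  self.duplicate_fraction):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.n_terms < 2:
            raise ValueError("need at least two terms")


PRESETS: dict[str, SimConfig] = {
    "noise-low": SimConfig(noise_rate=0.2),
    "noise-high": SimConfig(noise_rate=0.5),
    "imprecise-low": SimConfig(imprecision_rate=0.2),
    "imprecise-high": SimConfig(imprecision_rate=0.5),
}


def _term_id(i: int) -> TermID:
    return f"{TERM_PREFIX}:{i:07d}"


def make_ontology(cfg: SimConfig, rng: np.random.Generator) -> Ontology:
    """Random single-rooted DAG; edges only point from deeper to shallower nodes.

    Each new term attaches to a parent drawn among existing terms (weighted
    toward recently created ones, producing a branching tree of mean arity
    ``dag_branching``), and with probability ``second_parent_prob`` gains a
    second parent at strictly smaller depth, creating diamond paths.
    """
    n = cfg.n_terms
    edges: list[tuple[TermID, TermID]] = []
    depth = {0: 0}
    for i in range(1, n):
        # window over the most recent candidates keeps mean out-degree near
        # dag_branching without explicit bookkeeping
        window = max(1, int(round(cfg.dag_branching)))
        lo = max(0, i - window * 3)
        parent = int(rng.integers(lo, i))
        edges.append((_term_id(i), _term_id(parent)))
        depth[i] = depth[parent] + 1
        if depth[i] > 1 and rng.random() < cfg.second_parent_prob:
            shallower = [j for j in range(i) if depth[j] < depth[i]]
            extra = int(shallower[rng.integers(len(shallower))])
            if extra != parent:
                edges.append((_term_id(i), _term_id(extra)))
    names = {_term_id(i): f"synthetic term {i}" for i in range(n)}
    return from_edges(edges, names=names)


def make_kb(o: Ontology, cfg: SimConfig, rng: np.random.Generator) -> KnowledgeBase:
    """Diseases with leaf-biased annotation draws and class-style frequencies.

    Sampling weight of a term is 1 + depth, favouring specific phenotypes.
    A ``duplicate_fraction`` of diseases copy another disease's term set to
    emulate diseases with indistinguishable annotation profiles.
    """
    terms = sorted(o.terms - {o.root})
    depths = np.array([o.depth(t) for t in terms], dtype=float)
    weights = (1.0 + depths) / (1.0 + depths).sum()
    lo, hi = cfg.annotations_per_disease
    entries: list[DiseaseEntry] = []
    n_dup = int(round(cfg.duplicate_fraction * cfg.n_diseases))
    term_sets: list[list[TermID]] = []
    for k in range(cfg.n_diseases):
        if k >= cfg.n_diseases - n_dup and term_sets:
            chosen = list(term_sets[int(rng.integers(len(term_sets)))])
        else:
            size = int(rng.integers(lo, hi + 1))
            size = min(size, len(terms))
            idx = rng.choice(len(terms), size=size, replace=False, p=weights)
            chosen = [terms[i] for i in sorted(idx)]
        term_sets.append(chosen)
        annotations: dict[TermID, FrequencyRecord | None] = {}
        for t in chosen:
            if rng.random() < cfg.frequency_coverage:
                cls = _FREQ_CLASSES[
                    int(rng.choice(len(_FREQ_CLASSES), p=_FREQ_WEIGHTS))
                ]
                annotations[t] = FrequencyRecord(
                    FREQUENCY_CLASS_MIDPOINTS[cls], "frequency-class"
                )
            else:
                annotations[t] = None
        entries.append(
            DiseaseEntry(
                codes={f"{DISEASE_PREFIX}:{k:05d}"},
                name=f"synthetic disease {k}",
                annotations=annotations,
            )
        )
    return KnowledgeBase(diseases=entries, ontology_ref=o,
                         source_manifest=[("simulated", len(entries))])


def _corrupt(
    terms: list[TermID],
    h_closure: set[TermID],
    h_desc: set[TermID],
    o: Ontology,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[TermID]:
    out = list(terms)
    # imprecision: replace a fraction with random proper ancestors (never root)
    n_impr = int(round(cfg.imprecision_rate * len(out)))
    if n_impr:
        idx = rng.choice(len(out), size=n_impr, replace=False)
        for i in sorted(idx):
            anc = sorted(o.ancestors(out[i]) - {o.root})
            if anc:
                out[i] = anc[int(rng.integers(len(anc)))]
    # noise: add unrelated terms (outside ancestor and descendant cones of H)
    n_noise = int(round(cfg.noise_rate * len(out)))
    if n_noise:
        pool = sorted(o.terms - h_closure - h_desc - {o.root})
        if not pool:
            logger.warning("no eligible noise terms; skipping noise injection")
        else:
            take = min(n_noise, len(pool))
            idx = rng.choice(len(pool), size=take, replace=False)
            out.extend(pool[i] for i in idx)
    # dedupe, preserve first occurrence
    seen: set[TermID] = set()
    uniq = [t for t in out if not (t in seen or seen.add(t))]
    return uniq


def make_cases(
    kb: KnowledgeBase,
    o: Ontology,
    cfg: SimConfig,
    rng: np.random.Generator,
    n_cases: int = 100,
) -> list[PatientCase]:
    """Cases drawn from diseases and corrupted by imprecision then noise.

    Terms are sampled from the disease's annotations, frequency-weighted
    when frequencies exist (unknown frequencies weigh as the mean of the
    known ones); cases ending up with fewer than ``min_case_terms`` distinct
    terms are discarded and redrawn.
    """
    if not kb.diseases:
        raise ValueError("empty knowledge base")
    cases: list[PatientCase] = []
    lo, hi = cfg.terms_per_case
    attempts = 0
    while len(cases) < n_cases and attempts < 50 * n_cases:
        attempts += 1
        # one spawned generator per attempt: the disease and base term draw
        # of attempt j are then identical across corruption settings, so
        # case sets at different noise levels differ only in the corruption
        (rng_case,) = rng.spawn(1)
        entry = kb.diseases[int(rng_case.integers(len(kb.diseases)))]
        terms = sorted(entry.terms)
        if not terms:
            logger.warning("skipping disease %s with no annotations",
                           sorted(entry.codes))
            continue
        freqs = np.array(
            [
                entry.annotations[t].value
                if entry.annotations[t] is not None
                else np.nan
                for t in terms
            ]
        )
        if np.isnan(freqs).all():
            w = np.ones(len(terms))
        else:
            fill = np.nanmean(freqs)
            w = np.where(np.isnan(freqs), fill, freqs)
        w = w / w.sum()
        size = min(int(rng_case.integers(lo, hi + 1)), len(terms))
        idx = rng_case.choice(len(terms), size=size, replace=False, p=w)
        drawn = [terms[i] for i in sorted(idx)]
        h_closure = o.annotation_closure(entry.terms)
        h_desc = set().union(*(o.descendants(t) for t in entry.terms))
        query = _corrupt(drawn, h_closure, h_desc, o, cfg, rng_case)
        if len(query) < cfg.min_case_terms:
            continue
        cases.append(
            PatientCase(
                case_id=f"case-{len(cases):05d}",
                query=set(query),
                true_codes=set(entry.codes),
            )
        )
    if len(cases) < n_cases:
        logger.warning("generated only %d/%d cases", len(cases), n_cases)
    return cases


def make_world(
    cfg: SimConfig, n_cases: int = 100
) -> tuple[Ontology, KnowledgeBase, list[PatientCase]]:
    """Ontology + KB + cases from one seeded generator.

    The ontology and KB depend only on the structural part of the config,
    so two configs differing only in corruption rates share the same world
    and their case sets differ only in the corruption applied.
    """
    base = replace(cfg, noise_rate=0.0, imprecision_rate=0.0)
    rng = np.random.default_rng(base.seed)
    o = make_ontology(base, rng)
    kb = make_kb(o, base, rng)
    case_rng = np.random.default_rng(cfg.seed + 1)
    cases = make_cases(kb, o, cfg, case_rng, n_cases=n_cases)
    return o, kb, cases
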