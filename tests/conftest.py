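"""Shared fixtures: hand-built ontologies, random DAG worlds, and oracles."""

from __future__ import annotations

import numpy as np
import pytest

from phenorank.knowledgebase import DiseaseEntry, FrequencyRecord, KnowledgeBase
from phenorank.ontology import Ontology, from_edges
from phenorank.simulate import SimConfig, make_kb, make_ontology


@pytest.fixture
def chain() -> Ontology:
    """R <- A <- B."""
    return from_edges([("X:2", "X:1"), ("X:1", "X:0")])


@pytest.fixture
def diamond() -> Ontology:
    """R <- A, R <- B, A <- C, B <- C."""
    return from_edges(
        [("X:1", "X:0"), ("X:2", "X:0"), ("X:3", "X:1"), ("X:3", "X:2")]
    )


@pytest.fixture
def six_node() -> Ontology:
    """Root with two branches, one diamond: R<-A<-C, R<-B<-D, A,B<-E."""
    return from_edges(
        [
            ("X:1", "X:0"),
            ("X:2", "X:0"),
            ("X:3", "X:1"),
            ("X:4", "X:2"),
            ("X:5", "X:1"),
            ("X:5", "X:2"),
        ]
    )


def random_dag(rng: np.random.Generator, n: int) -> Ontology:
    """Independent random single-rooted DAG for oracle comparisons."""
    cfg = SimConfig(n_terms=n, seed=0)
    return make_ontology(cfg, rng)


def random_kb(o: Ontology, rng: np.random.Generator, n_diseases: int,
              lo: int = 2, hi: int = 5, freq: float = 0.5) -> KnowledgeBase:
    cfg = SimConfig(
        n_terms=len(o.terms), n_diseases=n_diseases,
        annotations_per_disease=(lo, hi), frequency_coverage=freq,
    )
    return make_kb(o, cfg, rng)


def bfs_ancestors(o: Ontology, t: str) -> set[str]:
    """Brute-force BFS over parent edges, independent of Ontology caching."""
    out: set[str] = set()
    frontier = [t]
    while frontier:
        nxt = []
        for u in frontier:
            for p in o.parents.get(u, ()):
                if p not in out:
                    out.add(p)
                    nxt.append(p)
        frontier = nxt
    return out


def make_entry(code: str, annotations: dict) -> DiseaseEntry:
    """annotations: term -> float frequency or None."""
    return DiseaseEntry(
        codes={code},
        name=code,
        annotations={
            t: None if v is None else FrequencyRecord(v, "fraction")
            for t, v in annotations.items()
        },
    )
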