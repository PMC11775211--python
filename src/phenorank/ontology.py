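"""Phenotype ontology: DAG structure, ancestor closures, and information content.

The ontology is a single-rooted directed acyclic graph of phenotype terms
connected by is-a edges.  Diseases are annotated with terms; because an
annotation with a specific term implies every more general ancestor term,
most quantities here operate on the *annotation closure* A(H): the annotated
terms together with all of their ancestors.

Information content of a term t is IC(t) = -ln P(t), where P(t) is the
fraction of knowledge-base diseases whose (closed) annotation set contains t.
Rare, specific terms carry high IC; the root carries zero.
"""

from __future__ import annotations

import json
import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "TermID",
    "Ontology",
    "ICTable",
    "OntologyError",
    "OboFormatError",
    "CycleError",
    "UnknownTermError",
    "parse_term_id",
    "load_obo",
    "compute_ic",
]

TermID = str

_TERM_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_]*):(\d+)$")


class OntologyError(Exception):
    """Base class for ontology loading/validation failures."""


class OboFormatError(OntologyError):
    """Raised when an OBO file cannot be parsed or violates structural rules."""


class CycleError(OntologyError):
    """Raised when the is-a graph contains a cycle; carries one offending cycle."""

    def __init__(self, cycle: list[TermID]):
        self.cycle = cycle
        super().__init__("is_a cycle detected: " + " -> ".join(cycle + cycle[:1]))


class UnknownTermError(KeyError, OntologyError):
    """Raised when a term ID is not present in the ontology."""


def parse_term_id(curie: str) -> TermID:
    """Validate and canonicalize a CURIE-style term ID such as ``HP:0000118``.

    The prefix is uppercased; the numeric local part is kept verbatim.
    Raises ``ValueError`` on malformed input.
    """
    m = _TERM_RE.match(curie.strip())
    if not m:
        raise ValueError(f"malformed term ID: {curie!r}")
    return f"{m.group(1).upper()}:{m.group(2)}"


@dataclass
class Ontology:
    """A validated single-rooted DAG of phenotype terms.

    ``parents``/``children`` are mutually consistent adjacency maps over
    is-a edges (child -> parents).  Ancestor closures are memoized.
    """

    terms: set[TermID]
    parents: dict[TermID, set[TermID]]
    children: dict[TermID, set[TermID]]
    root: TermID
    names: dict[TermID, str] = field(default_factory=dict)
    _anc_cache: dict[TermID, frozenset[TermID]] = field(
        default_factory=dict, repr=False, compare=False
    )
    _desc_cache: dict[TermID, frozenset[TermID]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        for t in self.terms:
            for p in self.parents.get(t, ()):
                if p not in self.terms:
                    raise OntologyError(f"parent {p} of {t} not a known term")
                if t not in self.children.get(p, ()):
                    raise OntologyError(f"inconsistent adjacency at edge {t} is_a {p}")
        for p in self.terms:
            for c in self.children.get(p, ()):
                if p not in self.parents.get(c, ()):
                    raise OntologyError(f"inconsistent adjacency at edge {c} is_a {p}")
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(
            (t, p) for t in self.terms for p in self.parents.get(t, ())
        )
        try:
            cyc = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise CycleError([u for u, _ in cyc])
        roots = [t for t in self.terms if not self.parents.get(t)]
        if len(roots) != 1:
            raise OntologyError(
                f"expected exactly one root, found {len(roots)}: {sorted(roots)[:5]}"
            )
        if roots[0] != self.root:
            raise OntologyError(f"declared root {self.root} != actual root {roots[0]}")

    # -- queries ----------------------------------------------------------

    def _require(self, t: TermID) -> None:
        if t not in self.terms:
            raise UnknownTermError(t)

    def ancestors(self, t: TermID, include_self: bool = False) -> set[TermID]:
        """Transitive closure of ``t`` over parent edges."""
        self._require(t)
        if t not in self._anc_cache:
            out: set[TermID] = set()
            stack = deque(self.parents.get(t, ()))
            while stack:
                a = stack.pop()
                if a not in out:
                    out.add(a)
                    cached = self._anc_cache.get(a)
                    if cached is not None:
                        out |= cached
                    else:
                        stack.extend(self.parents.get(a, ()))
            self._anc_cache[t] = frozenset(out)
        res = set(self._anc_cache[t])
        if include_self:
            res.add(t)
        return res

    def descendants(self, t: TermID, include_self: bool = False) -> set[TermID]:
        """Transitive closure of ``t`` over child edges."""
        self._require(t)
        if t not in self._desc_cache:
            out: set[TermID] = set()
            stack = deque(self.children.get(t, ()))
            while stack:
                d = stack.pop()
                if d not in out:
                    out.add(d)
                    stack.extend(self.children.get(d, ()))
            self._desc_cache[t] = frozenset(out)
        res = set(self._desc_cache[t])
        if include_self:
            res.add(t)
        return res

    def annotation_closure(self, terms: Iterable[TermID]) -> set[TermID]:
        """A(H): the union over ``terms`` of each term plus its ancestors."""
        out: set[TermID] = set()
        for t in terms:
            out |= self.ancestors(t, include_self=True)
        return out

    def depth(self, t: TermID) -> int:
        """Shortest parent-path distance from ``t`` to the root."""
        self._require(t)
        if t == self.root:
            return 0
        seen = {t: 0}
        q = deque([t])
        while q:
            u = q.popleft()
            for p in self.parents.get(u, ()):
                if p not in seen:
                    seen[p] = seen[u] + 1
                    if p == self.root:
                        return seen[p]
                    q.append(p)
        raise OntologyError(f"{t} does not reach root")  # unreachable post-validate

    def summary(self) -> dict:
        """Term/edge counts and a depth histogram, JSON-serializable."""
        depths = [self.depth(t) for t in self.terms]
        hist: dict[int, int] = {}
        for d in depths:
            hist[d] = hist.get(d, 0) + 1
        return {
            "n_terms": len(self.terms),
            "n_edges": sum(len(v) for v in self.parents.values()),
            "root": self.root,
            "depth_histogram": {str(k): hist[k] for k in sorted(hist)},
        }

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def from_edges(
    edges: Iterable[tuple[TermID, TermID]],
    terms: Iterable[TermID] | None = None,
    names: Mapping[TermID, str] | None = None,
) -> Ontology:
    """Build an Ontology from (child, parent) is-a pairs."""
    parents: dict[TermID, set[TermID]] = {}
    children: dict[TermID, set[TermID]] = {}
    tset: set[TermID] = set(terms or ())
    for c, p in edges:
        tset.add(c)
        tset.add(p)
        parents.setdefault(c, set()).add(p)
        children.setdefault(p, set()).add(c)
    roots = [t for t in tset if not parents.get(t)]
    if len(roots) != 1:
        raise OntologyError(f"expected exactly one root, found {len(roots)}")
    return Ontology(
        terms=tset,
        parents={t: parents.get(t, set()) for t in tset},
        children={t: children.get(t, set()) for t in tset},
        root=roots[0],
        names=dict(names or {}),
    )


def load_obo(path) -> Ontology:
    """Read an OBO 1.2/1.4 flat file into a validated :class:`Ontology`.

    Only ``is_a`` edges define the DAG; obsolete stanzas are dropped
    (``obonet`` excludes them by default).  Edges pointing at terms outside
    the file are ignored.
    """
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=True)
    except OntologyError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise OboFormatError(f"cannot parse OBO file {path}: {exc}") from exc
    tset = {parse_term_id(n) for n in graph.nodes}
    names = {
        parse_term_id(n): data.get("name", "")
        for n, data in graph.nodes(data=True)
    }
    edges = [
        (parse_term_id(c), parse_term_id(p))
        for c, p, key in graph.edges(keys=True)
        if key == "is_a" and p in graph.nodes
    ]
    return from_edges(edges, terms=tset, names=names)


def write_obo(o: Ontology, path) -> None:
    """Serialize an Ontology back to a minimal OBO flat file."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for t in sorted(o.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {t}\n")
            fh.write(f"name: {o.names.get(t, t)}\n")
            for p in sorted(o.parents.get(t, ())):
                fh.write(f"is_a: {p}\n")
            fh.write("\n")


@dataclass(frozen=True)
class ICTable:
    """Per-term background probability P(t) and information content IC(t) in nats.

    ``floor`` is the probability assigned to terms never seen annotating a
    disease, keeping IC finite for out-of-KB query terms.
    """

    background_prob: dict[TermID, float]
    ic: dict[TermID, float]
    floor: float

    def prob(self, t: TermID) -> float:
        return self.background_prob.get(t, self.floor)

    def get(self, t: TermID) -> float:
        """IC of ``t``, falling back to the floor-derived IC for unseen terms."""
        v = self.ic.get(t)
        if v is None:
            import math

            return -math.log(self.floor)
        return v


def compute_ic(o: Ontology, kb, closure: bool = True) -> ICTable:
    """Information content from disease annotation counts.

    P(t) = |{d : t in A(H_d)}| / |diseases| with ``closure=True`` (default);
    with ``closure=False`` only directly annotated terms are counted.  Terms
    annotating no disease get the smallest observed nonzero probability so
    their IC stays finite.
    """
    import math

    diseases = kb.diseases
    if not diseases:
        raise ValueError("cannot compute IC over an empty knowledge base")
    n = len(diseases)
    counts: dict[TermID, int] = {t: 0 for t in o.terms}
    for entry in diseases:
        terms = set(entry.annotations)
        if closure:
            terms = o.annotation_closure(terms)
        for t in terms:
            if t in counts:
                counts[t] += 1
    nonzero = [c for c in counts.values() if c > 0]
    floor = (min(nonzero) / n) if nonzero else 1.0 / n
    prob = {t: (c / n if c > 0 else floor) for t, c in counts.items()}
    ic = {t: -math.log(p) for t, p in prob.items()}
    return ICTable(background_prob=prob, ic=ic, floor=floor)
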