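"""Disease–phenotype knowledge base: loading, merging and querying annotations.

Annotation sources (HPOA-style TSV files) list one (disease, phenotype,
optional frequency) triple per row.  Sources are merged through an explicit
disease-code equivalence table so that, e.g., the OMIM, Orphanet and CCRD
codes for phenylketonuria collapse into a single disease entry carrying the
union of the three annotation sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from .ontology import Ontology, TermID, parse_term_id

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyRecord",
    "DiseaseEntry",
    "KnowledgeBase",
    "load_hpoa",
    "parse_frequency",
    "load_equivalence",
    "merge_sources",
    "restrict",
]

# HPO frequency-class terms mapped to the midpoint of their defining interval.
# "excluded" annotations are dropped at merge time.
FREQUENCY_CLASS_MIDPOINTS: dict[str, float] = {
    "HP:0040280": 1.0,    # obligate, 100%
    "HP:0040281": 0.895,  # very frequent, 80-99%
    "HP:0040282": 0.545,  # frequent, 30-79%
    "HP:0040283": 0.17,   # occasional, 5-29%
    "HP:0040284": 0.025,  # very rare, 1-4%
    "HP:0040285": 0.0,    # excluded, 0%
}
_CLASS_LABELS = {
    "obligate": "HP:0040280",
    "very frequent": "HP:0040281",
    "frequent": "HP:0040282",
    "occasional": "HP:0040283",
    "very rare": "HP:0040284",
    "excluded": "HP:0040285",
}

# On conflicting frequency records for the same (disease, term), keep the
# record from the highest-priority source.
DEFAULT_SOURCE_PRIORITY: tuple[str, ...] = ("CCRD", "OMIM", "ORPHANET")


@dataclass(frozen=True)
class FrequencyRecord:
    """A phenotype frequency in (0, 1] with provenance for audit."""

    value: float
    provenance: str  # fraction | percentage | frequency-class | default

    def __post_init__(self) -> None:
        if not (0.0 < self.value <= 1.0):
            raise ValueError(f"frequency must lie in (0,1], got {self.value}")


@dataclass
class DiseaseEntry:
    """One disease: its source-qualified codes and term -> frequency map."""

    codes: set[str]
    name: str
    annotations: dict[TermID, FrequencyRecord | None]

    @property
    def primary_code(self) -> str:
        return min(self.codes)

    @property
    def terms(self) -> set[TermID]:
        return set(self.annotations)


@dataclass
class KnowledgeBase:
    """Merged disease entries bound to an ontology, deterministically ordered."""

    diseases: list[DiseaseEntry]
    ontology_ref: Ontology | None = None
    source_manifest: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.diseases.sort(key=lambda e: e.primary_code)
        seen: dict[str, str] = {}
        for e in self.diseases:
            for c in e.codes:
                if c in seen:
                    raise ValueError(f"code {c} appears in two entries after merge")
                seen[c] = e.primary_code

    def __len__(self) -> int:
        return len(self.diseases)

    def __iter__(self):
        return iter(self.diseases)

    def find(self, code: str) -> DiseaseEntry | None:
        for e in self.diseases:
            if code in e.codes:
                return e
        return None

    # -- serialization ----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "schema": "phenorank-kb/1",
            "source_manifest": [list(x) for x in self.source_manifest],
            "diseases": [
                {
                    "codes": sorted(e.codes),
                    "name": e.name,
                    "annotations": {
                        t: (
                            None
                            if rec is None
                            else {"value": rec.value, "provenance": rec.provenance}
                        )
                        for t, rec in sorted(e.annotations.items())
                    },
                }
                for e in self.diseases
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path, ontology: Ontology | None = None) -> "KnowledgeBase":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema") != "phenorank-kb/1":
            raise ValueError(f"unrecognized KB schema in {path}")
        diseases = [
            DiseaseEntry(
                codes=set(d["codes"]),
                name=d["name"],
                annotations={
                    t: (
                        None
                        if rec is None
                        else FrequencyRecord(rec["value"], rec["provenance"])
                    )
                    for t, rec in d["annotations"].items()
                },
            )
            for d in payload["diseases"]
        ]
        return cls(
            diseases=diseases,
            ontology_ref=ontology,
            source_manifest=[tuple(x) for x in payload.get("source_manifest", [])],
        )


def parse_frequency(raw: str) -> FrequencyRecord:
    """Parse a raw HPOA frequency field.

    Accepts ``a/b`` fractions, ``n%`` percentages, and HPO frequency-class
    CURIEs or labels (mapped to interval midpoints).  Anything else yields a
    ``default`` record whose value is resolved downstream (e.g. by PPO's dp).
    """
    s = raw.strip()
    if not s:
        raise ValueError("empty frequency string")
    if "/" in s:
        try:
            frac = Fraction(s.replace(" ", ""))
        except (ValueError, ZeroDivisionError) as exc:
            raise ValueError(f"bad fraction {raw!r}") from exc
        return FrequencyRecord(float(frac), "fraction")
    if s.endswith("%"):
        try:
            v = float(s[:-1]) / 100.0
        except ValueError as exc:
            raise ValueError(f"bad percentage {raw!r}") from exc
        return FrequencyRecord(v, "percentage")
    key = s.upper() if s.upper().startswith("HP:") else _CLASS_LABELS.get(s.lower())
    if key in FREQUENCY_CLASS_MIDPOINTS:
        v = FREQUENCY_CLASS_MIDPOINTS[key]
        if v == 0.0:
            raise ValueError("excluded annotation carries no positive frequency")
        return FrequencyRecord(v, "frequency-class")
    # Unparseable: defer to the consumer's default probability.
    return FrequencyRecord(1.0, "default")


def load_hpoa(path, source: str) -> list[tuple[str, TermID, str | None]]:
    """Read an HPOA-style TSV into (disease-code, term, raw-frequency) tuples.

    Requires ``database_id`` and ``hpo_id`` columns (or at least two unnamed
    columns in that order); the frequency column is optional.  Rows with
    malformed term IDs are dropped and counted.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    if "database_id" in cols and "hpo_id" in cols:
        did, hid = cols["database_id"], cols["hpo_id"]
        freq = cols.get("frequency")
    elif len(df.columns) >= 2:
        did, hid = df.columns[0], df.columns[1]
        freq = df.columns[2] if len(df.columns) > 2 else None
    else:
        raise ValueError(f"{path}: need at least disease-ID and HPO-ID columns")
    out: list[tuple[str, TermID, str | None]] = []
    rejected = 0
    for _, row in df.iterrows():
        try:
            term = parse_term_id(row[hid])
            code = row[did].strip()
            if not code:
                raise ValueError("empty disease code")
        except ValueError:
            rejected += 1
            continue
        raw = row[freq].strip() if freq is not None else ""
        out.append((code, term, raw or None))
    if rejected:
        logger.warning("%s (%s): rejected %d malformed rows", path, source, rejected)
    return out


def load_equivalence(path) -> list[set[str]]:
    """Read a two-column TSV (class-id, disease-code) into code equivalence sets."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, header=None,
                     names=["class_id", "code"])
    groups: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        groups.setdefault(row["class_id"].strip(), set()).add(row["code"].strip())
    return list(groups.values())


def _source_rank(code: str, priority: Sequence[str]) -> int:
    prefix = code.split(":", 1)[0].upper()
    aliases = {"ORPHA": "ORPHANET"}
    prefix = aliases.get(prefix, prefix)
    try:
        return priority.index(prefix)
    except ValueError:
        return len(priority)


def merge_sources(
    sources: dict[str, list[tuple[str, TermID, str | None]]],
    equivalence: Iterable[set[str]] = (),
    ontology: Ontology | None = None,
    names: dict[str, str] | None = None,
    source_priority: Sequence[str] = DEFAULT_SOURCE_PRIORITY,
) -> KnowledgeBase:
    """Merge per-source annotation lists into a unified :class:`KnowledgeBase`.

    Disease codes in the same equivalence class become one entry whose codes
    and annotations are the unions across sources.  Conflicting frequency
    records for a term are resolved by ``source_priority`` on the code prefix.
    "Excluded" (zero-frequency) annotations are dropped.
    """
    classes = [set(c) for c in equivalence]
    seen_codes: set[str] = set()
    for c in classes:
        if c & seen_codes:
            raise ValueError("equivalence classes overlap")
        seen_codes |= c
    code_to_class: dict[str, int] = {}
    for i, c in enumerate(classes):
        for code in c:
            code_to_class[code] = i

    # group rows by canonical key: class index or the singleton code
    grouped: dict[object, list[tuple[str, TermID, str | None]]] = {}
    manifest: list[tuple[str, int]] = []
    for source, rows in sources.items():
        manifest.append((source, len(rows)))
        for code, term, raw in rows:
            key = code_to_class.get(code, code)
            grouped.setdefault(key, []).append((code, term, raw))

    entries: list[DiseaseEntry] = []
    for key, rows in grouped.items():
        codes = set(classes[key]) if isinstance(key, int) else {rows[0][0]}
        codes |= {code for code, _, _ in rows}
        annotations: dict[TermID, FrequencyRecord | None] = {}
        best_rank: dict[TermID, int] = {}
        for code, term, raw in sorted(rows):
            if ontology is not None and term not in ontology.terms:
                logger.warning("dropping %s: term %s not in ontology", code, term)
                continue
            rec: FrequencyRecord | None = None
            if raw is not None:
                try:
                    rec = parse_frequency(raw)
                except ValueError:
                    continue  # zero/ill-formed frequency: annotation dropped
            rank = _source_rank(code, source_priority)
            if term not in annotations:
                annotations[term] = rec
                best_rank[term] = rank
            elif rec is not None and (
                annotations[term] is None or rank < best_rank[term]
            ):
                annotations[term] = rec
                best_rank[term] = rank
        if len(annotations) < 1:
            logger.warning("disease %s has no usable annotations", sorted(codes))
        entries.append(
            DiseaseEntry(
                codes=codes,
                name=(names or {}).get(min(codes), min(codes)),
                annotations=annotations,
            )
        )
    return KnowledgeBase(diseases=entries, ontology_ref=ontology,
                         source_manifest=manifest)


def restrict(kb: KnowledgeBase, codes: set[str]) -> KnowledgeBase:
    """Sub-KB of entries carrying at least one of ``codes``; order preserved."""
    if not codes:
        raise ValueError("restrict requires a non-empty code set")
    known = {c for e in kb.diseases for c in e.codes}
    unknown = codes - known
    if unknown:
        logger.warning("restrict: %d unknown codes ignored", len(unknown))
    kept = [e for e in kb.diseases if e.codes & codes]
    if not kept:
        logger.warning("restrict produced an empty knowledge base")
    return KnowledgeBase(
        diseases=kept,
        ontology_ref=kb.ontology_ref,
        source_manifest=list(kb.source_manifest),
    )
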