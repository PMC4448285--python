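"""Knowledge-base assembly, querying, and export.

Accepted fact hypotheses are merged into one :class:`Fact` per triple,
with the union of supporting occurrences kept as provenance (a fact can
occur in multiple sentences across multiple sources, so the fact count
and the occurrence count differ).  Exports are deterministic: identical
KBs produce byte-identical TSV and N-Triples files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from urllib.parse import quote

import pandas as pd
from rdflib import Graph, URIRef

from .analysis import FactCandidate
from .reasoning import ReasonerResult

log = logging.getLogger(__name__)

KB_NAMESPACE = "http://kbharvest.example.org/"


@dataclass(frozen=True)
class Provenance:
    doc_id: str
    locator: str
    pattern: tuple[str, ...]
    genre: str
    source: str


@dataclass(frozen=True)
class Fact:
    relation: str
    left_entity: str
    right_entity: str
    weight: float
    provenance: tuple[Provenance, ...]

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("fact must carry provenance")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.relation, self.left_entity, self.right_entity)


def assemble_kb(result: ReasonerResult, candidates: list[FactCandidate]) -> list[Fact]:
    """One fact per accepted triple; provenance is the union of support."""
    facts = []
    for c in sorted(candidates, key=lambda c: c.key):
        if c.key not in result.accepted:
            continue
        prov = tuple(
            Provenance(o.doc_id, o.locator, o.pattern, o.genre, o.source)
            for o in c.support
        )
        facts.append(Fact(c.relation, c.left_entity, c.right_entity, c.weight, prov))
    return facts


def kb_counts(facts: list[Fact]) -> tuple[int, int]:
    """(fact count, fact-occurrence count); the former never exceeds the latter."""
    return len(facts), sum(len(f.provenance) for f in facts)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("relation", "left_entity", "right_entity", "weight", "provenance_count", "sources")


def export_kb(facts: list[Fact], path: str | Path, format: str = "tsv") -> None:
    if format == "tsv":
        export_kb_tsv(facts, path)
    elif format == "ntriples":
        export_kb_ntriples(facts, path)
    else:
        raise ValueError(f"unknown export format {format!r}; expected tsv or ntriples")


def export_kb_tsv(facts: list[Fact], path: str | Path) -> None:
    rows = [
        {
            "relation": f.relation,
            "left_entity": f.left_entity,
            "right_entity": f.right_entity,
            "weight": f"{f.weight:.6f}",
            "provenance_count": len(f.provenance),
            "sources": ";".join(sorted({p.source for p in f.provenance if p.source})),
        }
        for f in sorted(facts, key=lambda f: f.key)
    ]
    pd.DataFrame(rows, columns=list(_TSV_COLUMNS)).to_csv(path, sep="\t", index=False)


def import_kb_tsv(path: str | Path) -> list[Fact]:
    """Re-read an exported TSV.  Provenance locators are non-portable:
    entries come back as placeholder records preserving count and source."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    facts = []
    for row in df.itertuples(index=False):
        n = int(row.provenance_count)
        prov = tuple(
            Provenance("", "", (), "scientific", row.sources.split(";")[0] if row.sources else "")
            for _ in range(n)
        )
        facts.append(
            Fact(row.relation, row.left_entity, row.right_entity, float(row.weight), prov)
        )
    return facts


def entity_iri(entity_id: str) -> str:
    return f"{KB_NAMESPACE}entity/{quote(entity_id, safe='')}"


def relation_iri(relation: str) -> str:
    return f"{KB_NAMESPACE}relation/{quote(relation, safe='')}"


def export_kb_ntriples(
    facts: list[Fact], path: str | Path, provenance_path: str | Path | None = None
) -> None:
    """One N-Triples line per fact (deterministic IRI scheme, sorted lines);
    provenance goes to a sidecar TSV when requested."""
    g = Graph()
    for f in facts:
        g.add(
            (URIRef(entity_iri(f.left_entity)), URIRef(relation_iri(f.relation)),
             URIRef(entity_iri(f.right_entity)))
        )
    lines = sorted(
        line for line in g.serialize(format="nt").splitlines() if line.strip()
    )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    if provenance_path is not None:
        rows = [
            {
                "relation": f.relation,
                "left_entity": f.left_entity,
                "right_entity": f.right_entity,
                "doc_id": p.doc_id,
                "locator": p.locator,
                "pattern": " ".join(p.pattern),
                "genre": p.genre,
                "source": p.source,
            }
            for f in sorted(facts, key=lambda f: f.key)
            for p in f.provenance
        ]
        pd.DataFrame(
            rows,
            columns=[
                "relation", "left_entity", "right_entity",
                "doc_id", "locator", "pattern", "genre", "source",
            ],
        ).to_csv(provenance_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Query
# ---------------------------------------------------------------------------

def query_kb(
    facts: list[Fact],
    relation: str | None = None,
    entity: str | None = None,
    left: str | None = None,
    right: str | None = None,
) -> list[Fact]:
    """Facts matching all supplied filters, ordered by descending weight.

    ``entity`` matches either argument; ``left``/``right`` a specific one.
    """
    out = [
        f
        for f in facts
        if (relation is None or f.relation == relation)
        and (entity is None or entity in (f.left_entity, f.right_entity))
        and (left is None or f.left_entity == left)
        and (right is None or f.right_entity == right)
    ]
    out.sort(key=lambda f: (-f.weight, f.key))
    return out
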