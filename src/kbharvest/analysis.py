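"""Distant supervision: subsequence mining, pattern confidence, fact candidates.

Seed facts R(e1, e2) presumed true label pattern occurrences without any
hand-annotated training data.  For a mined subsequence q and relation R,

    confidence(q, R) = |{s : q occurs in s and some pair in SX(R) occurs in s}|
                       ----------------------------------------------------------
                       |{s : q occurs in s and some pair in SX(R) u CX(R) occurs in s}|

where SX(R) are the seed entity pairs of R and CX(R) those of the other
relations, and "q occurs in s" means q is an (order-preserving, not
necessarily contiguous) subsequence of a pattern gathered in sentence s.
Counting is over distinct sentences.  Subsequences whose confidence
strictly exceeds a threshold (default 0.3) become *seed patterns*;
pattern occurrences are then scored against the seed pattern set by
token-set Jaccard x confidence, and occurrences of the same triple are
merged with noisy-or aggregation into weighted fact candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import DocumentMeta
from .gathering import DomPattern, SentencePattern
from .relations import DEFAULT_RELATIONS

log = logging.getLogger(__name__)

_MAX_ENUMERATED_LENGTH = 20  # 2^20 subsequences; gathered patterns are far shorter


@dataclass(frozen=True)
class SeedFact:
    relation: str
    left_entity: str
    right_entity: str

    @property
    def pair(self) -> tuple[str, str]:
        return (self.left_entity, self.right_entity)


@dataclass(frozen=True)
class PatternOccurrence:
    """A rendered pattern between two entities, with provenance."""

    pattern: tuple[str, ...]
    left_entity: str
    right_entity: str
    doc_id: str
    locator: str  # sentence id, or DOM path for document-structure patterns
    genre: str = "scientific"
    source: str = ""
    kind: str = "sentence"  # "sentence" | "dom"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("pattern occurrence must have a non-empty pattern")

    @property
    def sentence_key(self) -> tuple[str, str]:
        return (self.doc_id, self.locator)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.left_entity, self.right_entity)


@dataclass(frozen=True)
class SeedPattern:
    tokens: tuple[str, ...]
    relation: str
    confidence: float


@dataclass(frozen=True)
class FactCandidate:
    relation: str
    left_entity: str
    right_entity: str
    weight: float
    support: tuple[PatternOccurrence, ...]

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0):
            raise ValueError(f"candidate weight must be in (0, 1], got {self.weight}")
        if not self.support:
            raise ValueError("candidate must have supporting occurrences")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.relation, self.left_entity, self.right_entity)


def occurrence_from_sentence_pattern(
    sp: SentencePattern, meta: DocumentMeta
) -> PatternOccurrence:
    return PatternOccurrence(
        sp.tokens,
        sp.left_mention.entity_id,
        sp.right_mention.entity_id,
        sp.doc_id,
        sp.sent_id,
        meta.genre,
        meta.source,
        "sentence",
    )


def occurrence_from_dom_pattern(
    dp: DomPattern, genre: str = "encyclopedic", source: str = ""
) -> PatternOccurrence | None:
    """Heading texts, tokenized and lowercased, act as the pattern sequence."""
    tokens = tuple(w for h in dp.headings for w in h.lower().split())
    if not tokens:
        return None
    return PatternOccurrence(
        tokens, dp.title_entity, dp.item_entity, dp.doc_id, dp.dom_path, genre, source, "dom"
    )


def read_seed_facts(path: str | Path) -> list[SeedFact]:
    """TSV with columns relation, left_entity_id, right_entity_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        SeedFact(r.relation, r.left_entity_id, r.right_entity_id)
        for r in df.itertuples(index=False)
    ]


def write_seed_facts(seeds: Sequence[SeedFact], path: str | Path) -> None:
    rows = [
        {"relation": s.relation, "left_entity_id": s.left_entity, "right_entity_id": s.right_entity}
        for s in seeds
    ]
    pd.DataFrame(rows, columns=["relation", "left_entity_id", "right_entity_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Seed index
# ---------------------------------------------------------------------------

class RelationSeedIndex:
    """SX/CX partition of seed entity pairs per relation.

    ``sx(R)`` holds the ordered pairs of R's seed facts; ``cx(R)`` the
    remaining seed pairs (those appearing only in other relations' seeds).
    """

    def __init__(self, sx: Mapping[str, frozenset[tuple[str, str]]]) -> None:
        self._sx = {r: frozenset(p) for r, p in sx.items()}
        self.all_pairs = frozenset(p for pairs in self._sx.values() for p in pairs)

    @property
    def relations(self) -> tuple[str, ...]:
        return tuple(sorted(self._sx))

    def sx(self, relation: str) -> frozenset[tuple[str, str]]:
        return self._sx.get(relation, frozenset())

    def cx(self, relation: str) -> frozenset[tuple[str, str]]:
        return self.all_pairs - self.sx(relation)


def build_seed_index(
    seeds: Sequence[SeedFact], known_relations: Iterable[str] = DEFAULT_RELATIONS
) -> RelationSeedIndex:
    if not seeds:
        raise ValueError("seed set must be non-empty")
    known = set(known_relations)
    sx: dict[str, set[tuple[str, str]]] = {}
    for s in seeds:
        if s.relation not in known:
            raise ValueError(f"unknown relation {s.relation!r} in seed fact {s}")
        sx.setdefault(s.relation, set()).add(s.pair)
    return RelationSeedIndex({r: frozenset(p) for r, p in sx.items()})


# ---------------------------------------------------------------------------
# Frequent subsequence mining
# ---------------------------------------------------------------------------

def is_subsequence(q: Sequence[str], p: Sequence[str]) -> bool:
    it = iter(p)
    return all(tok in it for tok in q)


def _subsequences(pattern: tuple[str, ...]) -> set[tuple[str, ...]]:
    if len(pattern) > _MAX_ENUMERATED_LENGTH:
        log.warning(
            "pattern of length %d truncated to %d tokens for subsequence mining",
            len(pattern),
            _MAX_ENUMERATED_LENGTH,
        )
        pattern = pattern[:_MAX_ENUMERATED_LENGTH]
    out: set[tuple[str, ...]] = set()
    for k in range(1, len(pattern) + 1):
        for idxs in combinations(range(len(pattern)), k):
            out.add(tuple(pattern[i] for i in idxs))
    return out


def mine_frequent_subsequences(
    occurrences: Sequence[PatternOccurrence], min_support: int = 2
) -> dict[tuple[str, ...], int]:
    """All order-preserving subsequences occurring in >= min_support
    distinct occurrences, mapped to their support counts."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    counts: dict[tuple[str, ...], int] = {}
    for occ in occurrences:
        for sub in _subsequences(occ.pattern):
            counts[sub] = counts.get(sub, 0) + 1
    return {q: c for q, c in counts.items() if c >= min_support}


# ---------------------------------------------------------------------------
# Confidence
# ---------------------------------------------------------------------------

def group_by_sentence(
    occurrences: Sequence[PatternOccurrence],
) -> dict[tuple[str, str], list[PatternOccurrence]]:
    groups: dict[tuple[str, str], list[PatternOccurrence]] = {}
    for occ in occurrences:
        groups.setdefault(occ.sentence_key, []).append(occ)
    return groups


def compute_confidence(
    q: tuple[str, ...],
    relation: str,
    occurrences: Sequence[PatternOccurrence],
    index: RelationSeedIndex,
) -> float | None:
    """Distant-supervision confidence of subsequence q for a relation.

    Returns ``None`` (undefined) when no sentence pairs q with any seed
    pair at all; such patterns are excluded from seed-pattern candidacy.
    """
    sx = index.sx(relation)
    num = den = 0
    for occs in group_by_sentence(occurrences).values():
        if not any(is_subsequence(q, o.pattern) for o in occs):
            continue
        pairs = {o.pair for o in occs}
        if pairs & index.all_pairs:
            den += 1
            if pairs & sx:
                num += 1
    if den == 0:
        return None
    return num / den


def compute_all_confidences(
    mined: Iterable[tuple[str, ...]],
    occurrences: Sequence[PatternOccurrence],
    index: RelationSeedIndex,
) -> dict[tuple[tuple[str, ...], str], float]:
    """Confidence for every (mined subsequence, relation) pair with a
    defined denominator.  One pass over sentence groups per subsequence."""
    groups = list(group_by_sentence(occurrences).values())
    sentence_pairs = [frozenset(o.pair for o in occs) & index.all_pairs for occs in groups]
    sentence_patterns = [tuple({o.pattern for o in occs}) for occs in groups]
    out: dict[tuple[tuple[str, ...], str], float] = {}
    for q in sorted(mined):
        hit = [
            pairs
            for pats, pairs in zip(sentence_patterns, sentence_pairs)
            if pairs and any(is_subsequence(q, p) for p in pats)
        ]
        den = len(hit)
        if den == 0:
            continue
        for rel in index.relations:
            sx = index.sx(rel)
            num = sum(1 for pairs in hit if pairs & sx)
            out[(q, rel)] = num / den
    return out


def select_seed_patterns(
    confidences: Mapping[tuple[tuple[str, ...], str], float], threshold: float = 0.3
) -> list[SeedPattern]:
    """Keep (q, R) with confidence *strictly* greater than the threshold."""
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must be in [0, 1)")
    kept = [
        SeedPattern(q, rel, conf)
        for (q, rel), conf in confidences.items()
        if conf > threshold
    ]
    kept.sort(key=lambda sp: (sp.relation, sp.tokens, -sp.confidence))
    return kept


# ---------------------------------------------------------------------------
# Candidate scoring
# ---------------------------------------------------------------------------

def token_set_jaccard(a: Sequence[str], b: Sequence[str]) -> float:
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def score_pattern(
    pattern: tuple[str, ...], seed_patterns: Sequence[SeedPattern]
) -> tuple[float, str] | None:
    """Best Jaccard-times-confidence match of a pattern against Q.

    Ties broken by higher confidence, then lexicographic relation id,
    then lexicographic seed tokens.  ``None`` when no token overlaps.
    """
    if not seed_patterns:
        raise ValueError("seed pattern set is empty")
    best: tuple[float, float, str, tuple[str, ...]] | None = None
    for sp in seed_patterns:
        w = token_set_jaccard(pattern, sp.tokens) * sp.confidence
        if w <= 0.0:
            continue
        cand = (-w, -sp.confidence, sp.relation, sp.tokens)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    return (-best[0], best[2])


def build_fact_candidates(
    occurrences: Sequence[PatternOccurrence], seed_patterns: Sequence[SeedPattern]
) -> list[FactCandidate]:
    """Score occurrences and merge identical triples with noisy-or weights.

    w = 1 - prod(1 - w_i) over supporting occurrences: bounded in (0, 1]
    and monotone in added support.
    """
    grouped: dict[tuple[str, str, str], list[tuple[float, PatternOccurrence]]] = {}
    for occ in occurrences:
        scored = score_pattern(occ.pattern, seed_patterns)
        if scored is None:
            continue
        w, rel = scored
        grouped.setdefault((rel, occ.left_entity, occ.right_entity), []).append((w, occ))
    out: list[FactCandidate] = []
    for key in sorted(grouped):
        rel, left, right = key
        ws_occs = grouped[key]
        weight = 1.0
        for w, _ in ws_occs:
            weight *= 1.0 - w
        weight = 1.0 - weight
        support = tuple(
            occ for _, occ in sorted(ws_occs, key=lambda t: (t[1].doc_id, t[1].locator))
        )
        out.append(FactCandidate(rel, left, right, weight, support))
    return out
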