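"""Dictionary entity recognition: character-3-gram MinHash/LSH matching.

Every dictionary name and every candidate token span is represented as a
set of character n-grams (default 3) over a lowercased, whitespace-
normalized, boundary-padded string.  MinHash signatures banded into an
LSH table retrieve match candidates in near-constant time; every
candidate is then *verified* with the exact Jaccard similarity, so the
LSH layer can only lose matches, never admit spurious ones below the
threshold.

Overlap resolution keeps, per span, the most specifically typed entities
(deepest semantic type in the hierarchy) and lets longer spans suppress
spans they strictly contain.  No further entity disambiguation is done.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from hashlib import blake2b
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import DictionaryEntry, ParsedSentence

log = logging.getLogger(__name__)

_PAD = "#"


def normalize_name(text: str) -> str:
    return " ".join(text.lower().split())


def trigram_set(text: str, ngram_size: int = 3) -> frozenset[str]:
    """Character n-grams of the normalized, boundary-padded string.

    The string is padded with ``ngram_size - 1`` boundary marks on both
    sides, so even 1-character names have a non-empty n-gram set.
    """
    if not text or not text.strip():
        raise ValueError("cannot build n-grams of empty text")
    s = _PAD * (ngram_size - 1) + normalize_name(text) + _PAD * (ngram_size - 1)
    return frozenset(s[i : i + ngram_size] for i in range(len(s) - ngram_size + 1))


def jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@dataclass(frozen=True)
class MatchIndexParams:
    ngram_size: int = 3
    signature_length: int = 256
    band_count: int = 64
    threshold: float = 0.7
    max_window: int = 6
    hash_seed: int = 42

    def __post_init__(self) -> None:
        if self.signature_length % self.band_count != 0:
            raise ValueError(
                f"signature_length ({self.signature_length}) must be divisible by "
                f"band_count ({self.band_count})"
            )
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")

    @property
    def rows_per_band(self) -> int:
        return self.signature_length // self.band_count


@lru_cache(maxsize=1 << 17)
def _gram_hash(gram: str) -> int:
    return int.from_bytes(blake2b(gram.encode("utf-8"), digest_size=8).digest(), "little")


def _splitmix64(z: np.ndarray) -> np.ndarray:
    # splitmix64 finalizer; uint64 arithmetic wraps, which is what we want
    z = (z + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z


class MinHasher:
    """Vectorized MinHash over 64-bit gram hashes.

    Hash function *i* mixes a per-function random seed into the gram hash
    with a splitmix64 finalizer; the signature is the column-wise minimum.
    Deterministic for a fixed ``seed``.
    """

    def __init__(self, signature_length: int, seed: int) -> None:
        rng = np.random.default_rng(seed)
        self._seeds = rng.integers(0, 2**63, size=signature_length, dtype=np.uint64)

    def signature(self, grams: frozenset[str]) -> np.ndarray:
        x = np.fromiter((_gram_hash(g) for g in grams), dtype=np.uint64, count=len(grams))
        mixed = _splitmix64(x[None, :] ^ self._seeds[:, None])
        return mixed.min(axis=1)

    @staticmethod
    def estimate(sig_a: np.ndarray, sig_b: np.ndarray) -> float:
        return float(np.mean(sig_a == sig_b))


@dataclass(frozen=True)
class TextMatch:
    entity_id: str
    matched_name: str
    semantic_types: frozenset[str]
    similarity: float


class MatchIndex:
    """LSH-banded MinHash index over dictionary names with exact verification."""

    def __init__(self, entries: Sequence[DictionaryEntry], params: MatchIndexParams) -> None:
        if not entries:
            raise ValueError("cannot build a match index from zero entries")
        self.params = params
        self.entries = list(entries)
        self.hasher = MinHasher(params.signature_length, params.hash_seed)
        self._grams = [trigram_set(e.name, params.ngram_size) for e in self.entries]
        self._sigs = [self.hasher.signature(g) for g in self._grams]
        r = params.rows_per_band
        self._buckets: dict[tuple[int, bytes], list[int]] = {}
        for row, sig in enumerate(self._sigs):
            for b in range(params.band_count):
                key = (b, sig[b * r : (b + 1) * r].tobytes())
                self._buckets.setdefault(key, []).append(row)

    def signatures(self) -> list[np.ndarray]:
        return list(self._sigs)

    def candidate_rows(self, grams: frozenset[str]) -> list[int]:
        sig = self.hasher.signature(grams)
        r = self.params.rows_per_band
        rows: set[int] = set()
        for b in range(self.params.band_count):
            rows.update(self._buckets.get((b, sig[b * r : (b + 1) * r].tobytes()), ()))
        return sorted(rows)

    def match_text(self, text: str) -> list[TextMatch]:
        """All entities whose name matches ``text`` with exact Jaccard >= threshold.

        Synonym rows of the same entity are collapsed to the best-matching
        row.  Sorted by descending similarity then entity id.
        """
        if not text or not text.strip():
            return []
        grams = trigram_set(text, self.params.ngram_size)
        best: dict[str, TextMatch] = {}
        for row in self.candidate_rows(grams):
            sim = jaccard(grams, self._grams[row])
            if sim < self.params.threshold:
                continue
            e = self.entries[row]
            prev = best.get(e.entity_id)
            if prev is None or sim > prev.similarity:
                best[e.entity_id] = TextMatch(e.entity_id, e.name, e.semantic_types, sim)
        return sorted(best.values(), key=lambda m: (-m.similarity, m.entity_id))


def build_match_index(
    entries: Sequence[DictionaryEntry], params: MatchIndexParams | None = None
) -> MatchIndex:
    return MatchIndex(entries, params or MatchIndexParams())


# ---------------------------------------------------------------------------
# Semantic type hierarchy
# ---------------------------------------------------------------------------

class SemanticTypeHierarchy:
    """Forest of semantic type codes; depth = path length to a root."""

    def __init__(self, parent_of: Mapping[str, str | None]) -> None:
        self.parent_of = dict(parent_of)
        self._warned: set[str] = set()
        for code in self.parent_of:
            seen = {code}
            cur = self.parent_of[code]
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle in type hierarchy at {cur!r}")
                seen.add(cur)
                if cur not in self.parent_of:
                    raise ValueError(f"type {cur!r} referenced but not defined")
                cur = self.parent_of[cur]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SemanticTypeHierarchy":
        """Read child->parent TSV (columns child, parent; empty parent = root)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls({r.child: (r.parent or None) for r in df.itertuples(index=False)})

    def to_tsv(self, path: str | Path) -> None:
        rows = [{"child": c, "parent": p or ""} for c, p in sorted(self.parent_of.items())]
        pd.DataFrame(rows, columns=["child", "parent"]).to_csv(path, sep="\t", index=False)

    def depth(self, code: str) -> int:
        if code not in self.parent_of:
            if code not in self._warned:
                log.warning("semantic type %r not in hierarchy; treated as depth 0", code)
                self._warned.add(code)
            return 0
        d = 0
        cur = self.parent_of[code]
        while cur is not None:
            d += 1
            cur = self.parent_of[cur]
        return d

    def ancestors_or_self(self, code: str) -> tuple[str, ...]:
        if code not in self.parent_of:
            return (code,)
        out = [code]
        cur = self.parent_of[code]
        while cur is not None:
            out.append(cur)
            cur = self.parent_of[cur]
        return tuple(out)

    def max_depth(self, codes: Iterable[str]) -> int:
        return max((self.depth(c) for c in codes), default=0)


# ---------------------------------------------------------------------------
# Mention recognition and overlap resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EntityMention:
    """A dictionary entity grounded at a half-open token span of a sentence."""

    doc_id: str
    sent_id: str
    start: int
    end: int
    entity_id: str
    semantic_types: frozenset[str]
    matched_name: str
    similarity: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("mention span must be non-empty")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def recognize_mentions(sentence: ParsedSentence, index: MatchIndex) -> list[EntityMention]:
    """Scan token windows of length 1..max_window against the dictionary.

    Every returned mention carries the *exact* trigram Jaccard similarity
    of its window surface against the matched dictionary name; the LSH
    layer only pre-filters candidates.
    """
    mentions: list[EntityMention] = []
    n = len(sentence.tokens)
    max_w = index.params.max_window
    for start in range(n):
        for end in range(start + 1, min(start + max_w, n) + 1):
            surface = " ".join(t.surface for t in sentence.tokens[start:end])
            if not surface.strip():
                continue
            for m in index.match_text(surface):
                mentions.append(
                    EntityMention(
                        sentence.doc_id,
                        sentence.sent_id,
                        start,
                        end,
                        m.entity_id,
                        m.semantic_types,
                        m.matched_name,
                        m.similarity,
                    )
                )
    mentions.sort(key=lambda m: (m.start, m.end, m.entity_id))
    return mentions


def resolve_overlaps(
    mentions: Sequence[EntityMention], hierarchy: SemanticTypeHierarchy
) -> list[EntityMention]:
    """Most-specific-type resolution within one sentence.

    Among mentions sharing an identical span, only those whose deepest
    semantic type is maximal are kept (ties keep all).  A span strictly
    contained in another surviving span is then suppressed.  Idempotent.
    """
    by_span: dict[tuple[int, int], list[EntityMention]] = {}
    for m in mentions:
        by_span.setdefault(m.span, []).append(m)
    kept: list[EntityMention] = []
    for span in sorted(by_span):
        group = by_span[span]
        top = max(hierarchy.max_depth(m.semantic_types) for m in group)
        kept.extend(m for m in group if hierarchy.max_depth(m.semantic_types) == top)
    spans = {m.span for m in kept}

    def subsumed(s: tuple[int, int]) -> bool:
        return any(t != s and t[0] <= s[0] and s[1] <= t[1] for t in spans)

    return [m for m in kept if not subsumed(m.span)]
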