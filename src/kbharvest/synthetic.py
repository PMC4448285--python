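"""Synthetic corpus generation with planted ground truth.

Every pipeline stage is testable without licensed resources: this module
generates an entity dictionary with a small semantic-type hierarchy,
type-consistent seed facts, a dependency-parsed corpus in which pattern
phrases are planted between entity pairs with an exactly realized
seed-co-occurrence plan, and HTML documents with title/heading/list
structure.  A ledger records every planted mention, pattern and intended
fact so that end-to-end precision and recall can be audited.

The dependency skeleton of a planted sentence is a chain running from
the left entity head through the pattern tokens to the right entity
head, with entity-internal tokens hanging off their heads — the simplest
graph on which the shortest dependency path reproduces the planted
phrase exactly.

Everything is deterministic under ``CorpusSpec.rng_seed``.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .analysis import SeedFact, write_seed_facts
from .corpus import (
    DependencyEdge,
    DictionaryEntry,
    DocumentMeta,
    ParsedSentence,
    Token,
    write_dictionary,
    write_parsed_corpus,
)
from .recognition import SemanticTypeHierarchy, jaccard, trigram_set
from .relations import CORE_TYPES, DEFAULT_RELATIONS, DEFAULT_SEED_COUNTS, DEFAULT_SIGNATURES

FactKey = tuple[str, str, str]
Phrase = tuple[tuple[str, str], ...]  # ((surface, lemma), ...)

TYPE_ROOT = "entity"

_GENRE_CYCLE = (
    ("scientific", "pubmed-medline"),
    ("encyclopedic", "healthpedia"),
    ("social", "forum-boards"),
)

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"


class InfeasiblePlanError(ValueError):
    """The seed co-occurrence plan asks for more sentences than the seed
    pairs (times the reuse limit) can provide."""


def make_phrase(surface: str, lemma: str | None = None) -> Phrase:
    """Build a phrase from whitespace-separated surface (and lemma) strings."""
    surf = surface.split()
    lem = lemma.split() if lemma is not None else surf
    if len(surf) != len(lem):
        raise ValueError("surface and lemma token counts differ")
    return tuple(zip(surf, lem))


@dataclass
class CorpusSpec:
    """Study conditions for the synthetic corpus.

    Defaults plant, for each of the 13 relations, two pattern phrases,
    each paired with that relation's seed pairs in 3 sentences and with
    fresh (non-seed, type-consistent) pairs in 2 harvest sentences, with
    the reference per-relation seed counts (467 in total) and no noise.
    """

    relations: tuple[str, ...] = DEFAULT_RELATIONS
    patterns_per_relation: int = 2
    pattern_length: tuple[int, int] = (2, 3)
    pattern_phrases: Mapping[str, Sequence[Phrase]] | None = None
    seed_pairs_per_relation: Mapping[str, int] | None = None  # None -> reference counts
    seed_sentences_per_pattern: int = 3
    harvest_sentences_per_pattern: int = 2
    seed_cooccurrence_plan: Mapping[tuple[tuple[str, ...], str], int] | None = None
    seed_pair_reuse_limit: int = 1
    noise_rate: float = 0.0
    type_violations: int = 0
    modifier_rate: float = 0.0
    surface_edit_rate: float = 0.0
    synonym_rate: float = 0.2
    near_miss_rate: float = 0.1
    dom_documents_per_relation: int = 0
    dom_items_per_document: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_rate < 1.0):
            raise ValueError("noise_rate must be in [0, 1)")
        unknown = set(self.relations) - set(DEFAULT_RELATIONS)
        if unknown:
            raise ValueError(f"unknown relations {sorted(unknown)}")

    def seed_counts(self) -> dict[str, int]:
        if self.seed_pairs_per_relation is None:
            return {r: DEFAULT_SEED_COUNTS[r] for r in self.relations}
        return {r: int(self.seed_pairs_per_relation.get(r, 0)) for r in self.relations}


@dataclass
class Ledger:
    """Planted ground truth: what the corpus actually contains."""

    mentions: list[tuple[str, str, int, int, str]] = field(default_factory=list)
    patterns: list[tuple[str, str, tuple[str, ...]]] = field(default_factory=list)
    sentence_facts: set[FactKey] = field(default_factory=set)
    dom_facts: set[FactKey] = field(default_factory=set)
    violation_facts: set[FactKey] = field(default_factory=set)
    plan_realized: dict[tuple[tuple[str, ...], str], int] = field(default_factory=dict)
    dom_triples: list[tuple[str, str, tuple[str, ...], str]] = field(default_factory=list)
    token_count: int = 0
    edge_count: int = 0
    planted_sentences: int = 0
    noise_sentences: int = 0
    violation_sentences: int = 0

    @property
    def true_facts(self) -> set[FactKey]:
        return self.sentence_facts | self.dom_facts

    def write_facts_tsv(self, path: str | Path) -> None:
        rows = [
            {"relation": r, "left_entity": l, "right_entity": rt}
            for r, l, rt in sorted(self.true_facts)
        ]
        pd.DataFrame(rows, columns=["relation", "left_entity", "right_entity"]).to_csv(
            path, sep="\t", index=False
        )


def read_truth_facts(path: str | Path) -> set[FactKey]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {(r.relation, r.left_entity, r.right_entity) for r in df.itertuples(index=False)}


# ---------------------------------------------------------------------------
# Sentence builder (shared with hand-built fixtures)
# ---------------------------------------------------------------------------

def build_planted_sentence(
    doc_id: str,
    sent_id: str,
    left_tokens: Sequence[str],
    phrase: Phrase,
    right_tokens: Sequence[str],
    modifiers: Sequence[tuple[int, str, str]] = (),
) -> tuple[ParsedSentence, tuple[int, int], tuple[int, int]]:
    """Plant ``left phrase right`` with a chain dependency skeleton.

    ``modifiers`` are (phrase_index, word, label) triples inserted in
    surface order directly before their anchor phrase token and attached
    to it by a dependency edge with the given label (e.g. amod, neg).
    Returns the sentence and the half-open spans of the two entities.
    """
    if not phrase:
        raise ValueError("phrase must be non-empty")
    mods_by_anchor: dict[int, list[tuple[str, str]]] = {}
    for anchor, word, label in modifiers:
        mods_by_anchor.setdefault(anchor, []).append((word, label))

    items: list[tuple[str, str, str, object]] = []  # (surface, lemma, pos, role)
    for w in left_tokens:
        items.append((w, w.lower(), "NN", "L"))
    for j, (surf, lemma) in enumerate(phrase):
        for word, label in mods_by_anchor.get(j, ()):
            items.append((word, word.lower(), "JJ", ("M", j, label)))
        items.append((surf, lemma, "XX", ("P", j)))
    for w in right_tokens:
        items.append((w, w.lower(), "NN", "R"))

    tokens = tuple(
        Token(i, surf, lemma, pos) for i, (surf, lemma, pos, _) in enumerate(items)
    )
    left_idx = [i for i, it in enumerate(items) if it[3] == "L"]
    right_idx = [i for i, it in enumerate(items) if it[3] == "R"]
    phrase_idx = {
        it[3][1]: i for i, it in enumerate(items) if isinstance(it[3], tuple) and it[3][0] == "P"
    }
    edges: list[DependencyEdge] = []
    lhead = left_idx[0]
    for i in left_idx[1:]:
        edges.append(DependencyEdge(lhead, i, "nn"))
    prev = lhead
    for j in sorted(phrase_idx):
        edges.append(DependencyEdge(prev, phrase_idx[j], "dep"))
        prev = phrase_idx[j]
    rhead = right_idx[0]
    edges.append(DependencyEdge(prev, rhead, "dep"))
    for i in right_idx[1:]:
        edges.append(DependencyEdge(rhead, i, "nn"))
    for i, it in enumerate(items):
        if isinstance(it[3], tuple) and it[3][0] == "M":
            edges.append(DependencyEdge(phrase_idx[it[3][1]], i, it[3][2]))

    sent = ParsedSentence(doc_id, sent_id, tokens, tuple(edges))
    left_span = (left_idx[0], left_idx[-1] + 1)
    right_span = (right_idx[0], right_idx[-1] + 1)
    return sent, left_span, right_span


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def default_hierarchy() -> SemanticTypeHierarchy:
    """Root -> 7 core types -> two leaf subtypes each (depths 0/1/2)."""
    parent: dict[str, str | None] = {TYPE_ROOT: None}
    for t in CORE_TYPES:
        parent[t] = TYPE_ROOT
        parent[f"{t}.a"] = t
        parent[f"{t}.b"] = t
    return SemanticTypeHierarchy(parent)


@dataclass
class SyntheticCorpus:
    spec: CorpusSpec
    dictionary: list[DictionaryEntry]
    hierarchy: SemanticTypeHierarchy
    seeds: list[SeedFact]
    sentences: list[tuple[DocumentMeta, ParsedSentence]]
    html_documents: dict[str, str]
    ledger: Ledger

    @property
    def entity_types(self) -> dict[str, frozenset[str]]:
        out: dict[str, frozenset[str]] = {}
        for e in self.dictionary:
            out[e.entity_id] = out.get(e.entity_id, frozenset()) | e.semantic_types
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "dictionary": outdir / "dictionary.tsv",
            "hierarchy": outdir / "hierarchy.tsv",
            "seeds": outdir / "seeds.tsv",
            "corpus": outdir / "corpus.jsonl",
            "truth": outdir / "truth_facts.tsv",
            "html_dir": outdir / "html",
        }
        write_dictionary(self.dictionary, paths["dictionary"])
        self.hierarchy.to_tsv(paths["hierarchy"])
        write_seed_facts(self.seeds, paths["seeds"])
        write_parsed_corpus(self.sentences, paths["corpus"])
        self.ledger.write_facts_tsv(paths["truth"])
        paths["html_dir"].mkdir(exist_ok=True)
        for name, html in sorted(self.html_documents.items()):
            (paths["html_dir"] / f"{name}.html").write_text(html, encoding="utf-8")
        return paths


class _Generator:
    def __init__(self, spec: CorpusSpec) -> None:
        self.spec = spec
        self.rng = random.Random(spec.rng_seed)
        self.hierarchy = default_hierarchy()
        self.used_words: set[str] = set()
        self._word_grams: dict[str, frozenset[str]] = {}
        self._gram_index: dict[str, set[str]] = {}
        self.dictionary: list[DictionaryEntry] = []
        self.entity_names: dict[str, str] = {}
        self._entity_no = 0
        self.seeds: list[SeedFact] = []
        self.seed_pairs: dict[str, list[tuple[str, str]]] = {}
        self.phrases: dict[str, list[Phrase]] = {}
        self.ledger = Ledger()
        self.sentences: list[tuple[DocumentMeta, ParsedSentence]] = []
        self.html_documents: dict[str, str] = {}
        self._build()

    # -- vocabulary ---------------------------------------------------------

    # distinct words must also be *dissimilar* (trigram Jaccard below the
    # matcher threshold), or an approximate match could cross entities
    _MAX_WORD_SIMILARITY = 0.5

    def _word_ok(self, word: str, exclude: str | None = None) -> bool:
        grams = trigram_set(word)
        rivals = {w for g in grams for w in self._gram_index.get(g, ())}
        rivals.discard(exclude)
        return all(jaccard(grams, self._word_grams[w]) < self._MAX_WORD_SIMILARITY
                   for w in rivals)

    def _register_word(self, word: str) -> None:
        grams = trigram_set(word)
        self.used_words.add(word)
        self._word_grams[word] = grams
        for g in grams:
            self._gram_index.setdefault(g, set()).add(word)

    def _fresh_word(self, syllables: int | None = None) -> str:
        while True:
            n = syllables or self.rng.choice((2, 2, 3))
            w = "".join(
                self.rng.choice(_CONSONANTS) + self.rng.choice(_VOWELS) for _ in range(n)
            )
            if w not in self.used_words and self._word_ok(w):
                self._register_word(w)
                return w

    def _new_entity(self, top_type: str) -> str:
        eid = f"E{self._entity_no:04d}"
        self._entity_no += 1
        leaf = f"{top_type}.{self.rng.choice('ab')}"
        n_words = 1 if self.rng.random() < 0.6 else 2
        name = " ".join(self._fresh_word() for _ in range(n_words))
        self.entity_names[eid] = name
        types = frozenset({leaf})
        self.dictionary.append(DictionaryEntry(eid, name, types, True))
        if self.rng.random() < self.spec.synonym_rate:
            syn = " ".join(self._fresh_word() for _ in range(n_words))
            self.dictionary.append(DictionaryEntry(eid, syn, types, False))
        if self.rng.random() < self.spec.near_miss_rate and len(name) > 4:
            pos = self.rng.randrange(len(name))
            if name[pos] != " ":
                alt = self.rng.choice([c for c in _CONSONANTS + _VOWELS if c != name[pos]])
                miss = name[:pos] + alt + name[pos + 1 :]
                # a perturbed word is intentionally similar to its own source,
                # but must stay dissimilar from every other generated word
                originals = name.split()
                changed = [
                    (w, o) for w, o in zip(miss.split(), originals) if w != o
                ]
                if all(
                    w not in self.used_words and self._word_ok(w, exclude=o)
                    for w, o in changed
                ):
                    for w, _ in changed:
                        self._register_word(w)
                    self.dictionary.append(DictionaryEntry(eid, miss, types, False))
        return eid

    def _entity_pool(self, top_type: str, size: int) -> list[str]:
        return [self._new_entity(top_type) for _ in range(size)]

    # -- construction -------------------------------------------------------

    def _build(self) -> None:
        spec = self.spec
        # phrases first: their tokens must not collide with entity names
        for rel in spec.relations:
            if spec.pattern_phrases is not None and rel in spec.pattern_phrases:
                self.phrases[rel] = list(spec.pattern_phrases[rel])
                for ph in self.phrases[rel]:
                    self.used_words.update(lemma for _, lemma in ph)
            else:
                self.phrases[rel] = [
                    make_phrase(
                        " ".join(
                            self._fresh_word()
                            for _ in range(self.rng.randint(*spec.pattern_length))
                        )
                    )
                    for _ in range(spec.patterns_per_relation)
                ]
        self._build_seeds()
        self._build_sentences()
        self._build_dom()
        self._build_noise()

    def _sample_pairs(
        self, rel: str, count: int, left_pool: list[str], right_pool: list[str]
    ) -> list[tuple[str, str]]:
        grid = len(left_pool) * len(right_pool)
        picks = self.rng.sample(range(grid), count)
        return [
            (left_pool[i // len(right_pool)], right_pool[i % len(right_pool)])
            for i in sorted(picks)
        ]

    def _pool_side(self, types: frozenset[str], count: int) -> list[str]:
        # alternate over the allowed top types so multi-type signatures are exercised
        tops = sorted(types)
        size = max(2, math.isqrt(count - 1) + 1) if count > 0 else 0
        return [self._new_entity(tops[i % len(tops)]) for i in range(size)]

    def _build_seeds(self) -> None:
        counts = self.spec.seed_counts()
        for rel in self.spec.relations:
            c = counts.get(rel, 0)
            sig = DEFAULT_SIGNATURES[rel]
            if c <= 0:
                self.seed_pairs[rel] = []
                continue
            left = self._pool_side(sig.domain_types, c)
            right = self._pool_side(sig.range_types, c)
            pairs = self._sample_pairs(rel, c, left, right)
            self.seed_pairs[rel] = pairs
            self.seeds.extend(SeedFact(rel, l, r) for l, r in pairs)

    def _emit(
        self,
        relation_of_fact: str,
        phrase: Phrase,
        pair: tuple[str, str],
        is_violation: bool = False,
    ) -> None:
        sid = len(self.sentences)
        doc_id = f"d{sid:05d}"
        genre, source = _GENRE_CYCLE[sid % len(_GENRE_CYCLE)]
        left_name = self.entity_names[pair[0]].split()
        right_name = self.entity_names[pair[1]].split()
        if self.spec.surface_edit_rate > 0 and self.rng.random() < self.spec.surface_edit_rate:
            side = self.rng.choice((left_name, right_name))
            w = self.rng.randrange(len(side))
            word = side[w]
            pos = self.rng.randrange(len(word))
            alt = self.rng.choice([c for c in _CONSONANTS + _VOWELS if c != word[pos]])
            side[w] = word[:pos] + alt + word[pos + 1 :]
        modifiers: list[tuple[int, str, str]] = []
        if self.spec.modifier_rate > 0 and self.rng.random() < self.spec.modifier_rate:
            modifiers.append((0, self._fresh_word(), "amod"))
        sent, lspan, rspan = build_planted_sentence(
            doc_id, "s0", left_name, phrase, right_name, modifiers
        )
        self.sentences.append((DocumentMeta(doc_id, genre, source), sent))
        self.ledger.token_count += len(sent.tokens)
        self.ledger.edge_count += len(sent.edges)
        self.ledger.mentions.append((doc_id, "s0", lspan[0], lspan[1], pair[0]))
        self.ledger.mentions.append((doc_id, "s0", rspan[0], rspan[1], pair[1]))
        rendered = tuple(
            sent.tokens[i].lemma for i in range(lspan[1], rspan[0])
        )
        self.ledger.patterns.append((doc_id, "s0", rendered))
        if is_violation:
            self.ledger.violation_facts.add((relation_of_fact, *pair))
            self.ledger.violation_sentences += 1
        else:
            self.ledger.sentence_facts.add((relation_of_fact, *pair))
            self.ledger.planted_sentences += 1

    def _phrase_by_lemmas(self, lemmas: tuple[str, ...]) -> Phrase:
        for phrases in self.phrases.values():
            for ph in phrases:
                if tuple(l for _, l in ph) == lemmas:
                    return ph
        raise ValueError(f"plan references unplanted phrase {lemmas}")

    def _build_sentences(self) -> None:
        spec = self.spec
        # seed co-occurrence sentences, exactly realizing the plan
        if spec.seed_cooccurrence_plan is not None:
            plan = dict(spec.seed_cooccurrence_plan)
        else:
            plan = {
                (tuple(l for _, l in ph), rel): spec.seed_sentences_per_pattern
                for rel in spec.relations
                if self.seed_pairs.get(rel)  # no seeds -> harvest-only relation
                for ph in self.phrases[rel]
            }
        for (lemmas, rel), count in sorted(plan.items()):
            if count <= 0:
                continue
            phrase = self._phrase_by_lemmas(lemmas)
            pairs = self.seed_pairs.get(rel, [])
            if count > len(pairs) * spec.seed_pair_reuse_limit:
                raise InfeasiblePlanError(
                    f"plan wants {count} sentences for {(lemmas, rel)} but only "
                    f"{len(pairs)} seed pairs x reuse limit {spec.seed_pair_reuse_limit}"
                )
            for i in range(count):
                self._emit(rel, phrase, pairs[i % len(pairs)])
                key = (lemmas, rel)
                self.ledger.plan_realized[key] = self.ledger.plan_realized.get(key, 0) + 1
        # harvest sentences: fresh type-consistent non-seed pairs
        for rel in spec.relations:
            sig = DEFAULT_SIGNATURES[rel]
            n_pairs = len(self.phrases[rel]) * spec.harvest_sentences_per_pattern
            if n_pairs == 0:
                continue
            left = self._pool_side(sig.domain_types, n_pairs)
            right = self._pool_side(sig.range_types, n_pairs)
            pairs = self._sample_pairs(rel, n_pairs, left, right)
            i = 0
            for ph in self.phrases[rel]:
                for _ in range(spec.harvest_sentences_per_pattern):
                    self._emit(rel, ph, pairs[i])
                    i += 1
        # type-violating distractors
        for v in range(spec.type_violations):
            rel = spec.relations[v % len(spec.relations)]
            sig = DEFAULT_SIGNATURES[rel]
            bad_type = next(t for t in CORE_TYPES if t not in sig.domain_types)
            left = self._new_entity(bad_type)
            right = self._pool_side(sig.range_types, 1)[0]
            self._emit(rel, self.phrases[rel][0], (left, right), is_violation=True)

    def _build_dom(self) -> None:
        spec = self.spec
        for rel in spec.relations:
            sig = DEFAULT_SIGNATURES[rel]
            for d in range(spec.dom_documents_per_relation):
                title = self._new_entity(sorted(sig.domain_types)[0])
                items = self._entity_pool(
                    sorted(sig.range_types)[0], spec.dom_items_per_document
                )
                phrase = self.phrases[rel][d % len(self.phrases[rel])]
                heading = " ".join(l for _, l in phrase)
                doc_id = f"dom-{rel}-{d}"
                lis = "".join(f"<li>{self.entity_names[e]}</li>" for e in items)
                self.html_documents[doc_id] = (
                    "<html><body>"
                    f"<h1>{self.entity_names[title]}</h1>"
                    f"<h2>{heading}</h2><ul>{lis}</ul>"
                    "</body></html>"
                )
                for e in items:
                    self.ledger.dom_facts.add((rel, title, e))
                    self.ledger.dom_triples.append((doc_id, title, (heading,), e))

    def _build_noise(self) -> None:
        spec = self.spec
        planted = len(self.sentences)
        if spec.noise_rate <= 0.0 or planted == 0:
            return
        n_noise = round(spec.noise_rate * planted / (1.0 - spec.noise_rate))
        for _ in range(n_noise):
            k = self.rng.randint(4, 8)
            words = [self._fresh_word() for _ in range(k)]
            sid = len(self.sentences)
            doc_id = f"d{sid:05d}"
            genre, source = _GENRE_CYCLE[sid % len(_GENRE_CYCLE)]
            tokens = tuple(Token(i, w, w, "NN") for i, w in enumerate(words))
            edges = tuple(DependencyEdge(i, i + 1, "dep") for i in range(k - 1))
            sent = ParsedSentence(doc_id, "s0", tokens, edges)
            pos = self.rng.randrange(len(self.sentences) + 1)
            self.sentences.insert(pos, (DocumentMeta(doc_id, genre, source), sent))
            self.ledger.token_count += len(tokens)
            self.ledger.edge_count += len(edges)
            self.ledger.noise_sentences += 1


def generate_corpus(spec: CorpusSpec) -> SyntheticCorpus:
    """Generate the full fixture bundle for a spec, deterministically."""
    g = _Generator(spec)
    return SyntheticCorpus(
        spec, g.dictionary, g.hierarchy, g.seeds, g.sentences, g.html_documents, g.ledger
    )


def generate_dictionary(spec: CorpusSpec) -> tuple[list[DictionaryEntry], SemanticTypeHierarchy]:
    c = generate_corpus(spec)
    return c.dictionary, c.hierarchy


def generate_seed_facts(spec: CorpusSpec) -> list[SeedFact]:
    return generate_corpus(spec).seeds


def generate_parsed_corpus(
    spec: CorpusSpec,
) -> tuple[list[tuple[DocumentMeta, ParsedSentence]], Ledger]:
    c = generate_corpus(spec)
    return c.sentences, c.ledger


def generate_dom_corpus(spec: CorpusSpec) -> tuple[dict[str, str], Ledger]:
    c = generate_corpus(spec)
    return c.html_documents, c.ledger
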