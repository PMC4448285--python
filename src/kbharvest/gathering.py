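"""Pattern gathering: sentence-level dependency paths and DOM-structure patterns.

A sentence-level pattern is the shortest path between two entity mentions
in the (undirected view of the) dependency graph, expanded with negation,
adjectival and adverbial modifiers of the path tokens, rendered as the
lemma sequence in surface order with mention-internal tokens removed.
E.g. for *Anemia is a common symptom of sarcoidosis* the path yields
*symptom of*, expanded via an ``amod`` edge to *common symptom of*.

A document-structure pattern binds a page's h1 title entity to an entity
inside an <li> item, with the intermediate h2..h6 heading texts as the
pattern.  Emission is gated on the title resolving to exactly one entity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx

from .corpus import DomNode, ParsedSentence
from .recognition import EntityMention, MatchIndex

log = logging.getLogger(__name__)

MODIFIER_LABELS = frozenset({"neg", "amod", "advmod"})


@dataclass(frozen=True)
class SentencePattern:
    """Rendered lemma sequence between two mentions, in surface order."""

    tokens: tuple[str, ...]
    left_mention: EntityMention
    right_mention: EntityMention
    doc_id: str
    sent_id: str


@dataclass(frozen=True)
class DomPattern:
    """Title-entity / heading-path / item-entity triple from one document."""

    title_entity: str
    title_text: str
    headings: tuple[str, ...]
    item_entity: str
    item_text: str
    doc_id: str
    dom_path: str


@dataclass
class GatherDiagnostics:
    """Counts of pairs skipped during gathering, for the diagnostics log."""

    disconnected_pairs: int = 0
    empty_patterns: int = 0
    overlapping_pairs: int = 0

    def as_rows(self) -> list[tuple[str, int]]:
        return [
            ("disconnected_pairs", self.disconnected_pairs),
            ("empty_patterns", self.empty_patterns),
            ("overlapping_pairs", self.overlapping_pairs),
        ]


def dependency_graph(sentence: ParsedSentence) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(sentence.tokens)))
    g.add_edges_from((e.governor, e.dependent) for e in sentence.edges)
    return g


def mention_head(sentence: ParsedSentence, mention: EntityMention) -> int:
    """Head token of a mention span: leftmost token whose governor (if any)
    lies outside the span; falls back to the leftmost span token."""
    span = range(mention.start, mention.end)
    governors: dict[int, list[int]] = {i: [] for i in span}
    for e in sentence.edges:
        if e.dependent in governors:
            governors[e.dependent].append(e.governor)
    for i in span:
        govs = governors[i]
        if not govs or any(g < mention.start or g >= mention.end for g in govs):
            return i
    return mention.start


def shortest_dependency_path(
    sentence: ParsedSentence, m1: EntityMention, m2: EntityMention
) -> tuple[int, ...] | None:
    """BFS shortest path (endpoints included) between the mention heads.

    Edge direction is ignored.  Among equally short paths the
    lexicographically smallest index sequence is returned; ``None`` when
    the heads lie in disconnected components.
    """
    h1 = mention_head(sentence, m1)
    h2 = mention_head(sentence, m2)
    g = dependency_graph(sentence)
    dist = nx.single_source_shortest_path_length(g, h2)
    if h1 not in dist:
        return None
    path = [h1]
    cur = h1
    while cur != h2:
        cur = min(n for n in g.neighbors(cur) if dist.get(n, -1) == dist[cur] - 1)
        path.append(cur)
    return tuple(path)


def expand_with_modifiers(
    path: Sequence[int], sentence: ParsedSentence
) -> frozenset[int]:
    """Close the path token set over neg/amod/advmod dependent edges.

    Taking the fixpoint (modifiers of modifiers included) makes the
    operation idempotent.
    """
    out = set(path)
    deps_by_gov: dict[int, list[int]] = {}
    for e in sentence.edges:
        if e.label in MODIFIER_LABELS:
            deps_by_gov.setdefault(e.governor, []).append(e.dependent)
    frontier = list(out)
    while frontier:
        nxt = []
        for tok in frontier:
            for d in deps_by_gov.get(tok, ()):
                if d not in out:
                    out.add(d)
                    nxt.append(d)
        frontier = nxt
    return frozenset(out)


def render_pattern(
    indices: frozenset[int] | Sequence[int],
    sentence: ParsedSentence,
    m1: EntityMention,
    m2: EntityMention,
) -> SentencePattern | None:
    """Emit lemmas in surface order, dropping mention-internal tokens.

    Returns ``None`` (pattern discarded) when nothing remains.
    """
    left, right = (m1, m2) if (m1.start, m1.end) <= (m2.start, m2.end) else (m2, m1)
    excluded = set(range(left.start, left.end)) | set(range(right.start, right.end))
    kept = sorted(i for i in set(indices) if i not in excluded)
    if not kept:
        return None
    return SentencePattern(
        sentence.lemmas(kept), left, right, sentence.doc_id, sentence.sent_id
    )


def gather_sentence_patterns(
    sentence: ParsedSentence,
    mentions: Sequence[EntityMention],
    diagnostics: GatherDiagnostics | None = None,
) -> list[SentencePattern]:
    """Extract one pattern per pair of disjoint mentions in the sentence."""
    diag = diagnostics if diagnostics is not None else GatherDiagnostics()
    ordered = sorted(mentions, key=lambda m: (m.start, m.end, m.entity_id))
    patterns: list[SentencePattern] = []
    for a, b in combinations(ordered, 2):
        if not (a.end <= b.start or b.end <= a.start):
            diag.overlapping_pairs += 1
            continue
        path = shortest_dependency_path(sentence, a, b)
        if path is None:
            diag.disconnected_pairs += 1
            continue
        expanded = expand_with_modifiers(path, sentence)
        sp = render_pattern(expanded, sentence, a, b)
        if sp is None:
            diag.empty_patterns += 1
            continue
        patterns.append(sp)
    return patterns


# ---------------------------------------------------------------------------
# Document-structure patterns
# ---------------------------------------------------------------------------

def _find_h1(tree: DomNode) -> DomNode | None:
    if tree.tag == "h1":
        return tree
    for child in tree.children:
        if child.tag == "h1":
            return child
    return None


def extract_dom_patterns(
    tree: DomNode, index: MatchIndex, doc_id: str = "doc"
) -> list[DomPattern]:
    """Harvest (title entity, heading path, item entity) triples.

    Emitted only when the h1 text resolves to exactly one dictionary
    entity and an li text resolves to at least one entity (best match
    taken).  Headings are the h2..h6 texts on the tree path from the h1
    to the li, in document order.
    """
    h1 = _find_h1(tree)
    if h1 is None or not h1.text:
        return []
    title_matches = index.match_text(h1.text)
    title_ids = {m.entity_id for m in title_matches}
    if len(title_ids) != 1:
        if len(title_ids) > 1:
            log.debug("%s: title %r resolves to %d entities; skipped", doc_id, h1.text, len(title_ids))
        return []
    title_id = next(iter(title_ids))

    out: list[DomPattern] = []

    def walk(node: DomNode, headings: tuple[str, ...], path: str) -> None:
        for i, child in enumerate(node.children):
            cpath = f"{path}/{i}"
            if child.tag == "li":
                if not child.text:
                    continue
                matches = index.match_text(child.text)
                if not matches:
                    continue
                best = matches[0]
                out.append(
                    DomPattern(
                        title_id, h1.text, headings, best.entity_id, child.text, doc_id, cpath
                    )
                )
            elif child.tag in ("h2", "h3", "h4", "h5", "h6"):
                walk(child, headings + (child.text,), cpath)
            else:
                walk(child, headings, cpath)

    walk(h1, (), "h1")
    return out
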