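"""Data model and I/O for parsed sentences, dictionaries, and HTML documents.

The pipeline consumes text that has *already* been tokenized, lemmatized,
POS-tagged and dependency-parsed by a standard NLP pipeline; this module
defines the in-memory model for such sentences, a JSON-Lines reader/writer
for them, a reader for MRCONSO-style entity dictionaries, and a tolerant
HTML parser that reduces a page to the document structure the pattern
gatherer cares about (headings and list items).

Conventions: token indices are 0-based and contiguous within a sentence;
all spans elsewhere in the package are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from html import escape as _html_escape
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from lxml import etree
from lxml import html as lxml_html

log = logging.getLogger(__name__)

GENRES = ("scientific", "encyclopedic", "social")
HEADING_TAGS = ("h1", "h2", "h3", "h4", "h5", "h6")


class CorpusError(ValueError):
    """A corpus record violated the parsed-corpus contract."""


class UnusableDocumentError(ValueError):
    """An HTML document yielded no extractable content."""


@dataclass(frozen=True)
class Token:
    index: int
    surface: str
    lemma: str
    pos: str


@dataclass(frozen=True)
class DependencyEdge:
    governor: int
    dependent: int
    label: str


@dataclass(frozen=True)
class ParsedSentence:
    """One dependency-parsed sentence.

    The edge set, viewed undirected, is *not* required to be connected:
    degenerate parses occur in real corpora and downstream path finding
    copes with them explicitly.
    """

    doc_id: str
    sent_id: str
    tokens: tuple[Token, ...]
    edges: tuple[DependencyEdge, ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise CorpusError(f"{self.doc_id}/{self.sent_id}: sentence has no tokens")
        for pos, tok in enumerate(self.tokens):
            if tok.index != pos:
                raise CorpusError(
                    f"{self.doc_id}/{self.sent_id}: token indices must be 0-based and "
                    f"contiguous (token at position {pos} has index {tok.index})"
                )
            if not tok.lemma:
                raise CorpusError(f"{self.doc_id}/{self.sent_id}: empty lemma at token {pos}")
        n = len(self.tokens)
        for e in self.edges:
            if e.governor == e.dependent:
                raise CorpusError(f"{self.doc_id}/{self.sent_id}: self-loop at token {e.governor}")
            if not (0 <= e.governor < n) or not (0 <= e.dependent < n):
                raise CorpusError(
                    f"{self.doc_id}/{self.sent_id}: edge {e.governor}->{e.dependent} "
                    f"references a missing token (sentence has {n} tokens)"
                )

    def lemmas(self, indices: Iterable[int]) -> tuple[str, ...]:
        return tuple(self.tokens[i].lemma for i in indices)


@dataclass(frozen=True)
class DocumentMeta:
    doc_id: str
    genre: str
    source: str

    def __post_init__(self) -> None:
        if self.genre not in GENRES:
            raise CorpusError(f"unknown genre {self.genre!r}; expected one of {GENRES}")


@dataclass(frozen=True)
class DictionaryEntry:
    """One dictionary row: a surface name for an entity, with semantic types.

    Several rows may share ``entity_id`` — they are synonyms of one
    canonical entity (e.g. *heart attack* and *myocardial infarction*).
    """

    entity_id: str
    name: str
    semantic_types: frozenset[str]
    is_canonical: bool = True

    def __post_init__(self) -> None:
        if not self.semantic_types:
            raise CorpusError(f"dictionary entry {self.entity_id!r} has no semantic types")


@dataclass(eq=True)
class DomNode:
    """Node of the retained document structure.

    ``tag`` is one of h1..h6, li, or "other" (container / demoted node).
    Children are ordered; the parser guarantees a tree with at most one h1.
    """

    tag: str
    text: str
    children: list["DomNode"] = field(default_factory=list)

    def iter_nodes(self) -> Iterator["DomNode"]:
        yield self
        for c in self.children:
            yield from c.iter_nodes()


# ---------------------------------------------------------------------------
# Parsed-corpus JSONL dialect
# ---------------------------------------------------------------------------

def _record_to_pair(rec: dict) -> tuple[DocumentMeta, ParsedSentence]:
    meta = DocumentMeta(rec["doc_id"], rec["genre"], rec["source"])
    tokens = tuple(
        Token(t["i"], t["surface"], t["lemma"], t["pos"]) for t in rec["tokens"]
    )
    edges = tuple(
        DependencyEdge(e["gov"], e["dep"], e["label"]) for e in rec["edges"]
    )
    return meta, ParsedSentence(rec["doc_id"], rec["sent_id"], tokens, edges)


def read_parsed_corpus(path: str | Path) -> Iterator[tuple[DocumentMeta, ParsedSentence]]:
    """Yield ``(DocumentMeta, ParsedSentence)`` per line, re-validating invariants.

    Raises :class:`CorpusError` naming the offending line number on any
    malformed or invariant-violating record.
    """
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                yield _record_to_pair(rec)
            except (KeyError, TypeError, json.JSONDecodeError, CorpusError) as exc:
                raise CorpusError(f"{path}, line {lineno}: {exc}") from exc


def write_parsed_corpus(
    records: Iterable[tuple[DocumentMeta, ParsedSentence]], path: str | Path
) -> int:
    """Write records in the JSONL dialect; returns the number of lines written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for meta, sent in records:
            rec = {
                "doc_id": sent.doc_id,
                "sent_id": sent.sent_id,
                "genre": meta.genre,
                "source": meta.source,
                "tokens": [
                    {"i": t.index, "surface": t.surface, "lemma": t.lemma, "pos": t.pos}
                    for t in sent.tokens
                ],
                "edges": [
                    {"gov": e.governor, "dep": e.dependent, "label": e.label}
                    for e in sent.edges
                ],
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Dictionary TSV
# ---------------------------------------------------------------------------

_DICT_COLUMNS = ("entity_id", "name", "semantic_type_codes", "is_canonical")


def read_dictionary(path: str | Path) -> list[DictionaryEntry]:
    """Read an MRCONSO-like TSV with columns entity_id, name,
    semantic_type_codes (comma separated), is_canonical (0/1)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        log.warning("dictionary file %s is empty", path)
        return []
    missing = [c for c in _DICT_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusError(f"{path}: missing dictionary column(s) {missing}")
    entries: list[DictionaryEntry] = []
    for row in df.itertuples(index=False):
        if not row.name.strip():
            log.warning("dictionary row for %s has empty name; skipped", row.entity_id)
            continue
        types = frozenset(t.strip() for t in row.semantic_type_codes.split(",") if t.strip())
        entries.append(
            DictionaryEntry(row.entity_id, row.name, types, row.is_canonical == "1")
        )
    if not entries:
        log.warning("dictionary file %s yielded no entries", path)
    return entries


def write_dictionary(entries: Iterable[DictionaryEntry], path: str | Path) -> None:
    rows = [
        {
            "entity_id": e.entity_id,
            "name": e.name,
            "semantic_type_codes": ",".join(sorted(e.semantic_types)),
            "is_canonical": "1" if e.is_canonical else "0",
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=list(_DICT_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# HTML -> retained document structure
# ---------------------------------------------------------------------------

def _norm_text(text: str) -> str:
    return " ".join(text.split())


def parse_dom_document(html_text: str, doc_id: str = "doc") -> DomNode:
    """Parse (tolerantly) an HTML document into the retained structure.

    Only headings h1..h6 and li elements are kept; scripts and styles are
    stripped.  The flat heading stream is rebuilt into a section tree: the
    first h1 becomes the root section, h2..h6 nest by level, and each li
    attaches to its nearest preceding heading.  A second h1 is demoted to
    an "other" node (the document title is assumed unique).
    """
    if not html_text or not html_text.strip():
        raise UnusableDocumentError(f"{doc_id}: empty document")
    root = lxml_html.document_fromstring(html_text)
    etree.strip_elements(root, "script", "style", with_tail=False)

    forest: list[DomNode] = []
    stack: list[tuple[int, DomNode]] = []
    seen_h1 = False

    def attach(node: DomNode) -> None:
        (stack[-1][1].children if stack else forest).append(node)

    for el in root.iter():
        tag = el.tag.lower() if isinstance(el.tag, str) else ""
        if tag == "li":
            attach(DomNode("li", _norm_text(el.text_content())))
            continue
        if tag not in HEADING_TAGS:
            continue
        text = _norm_text(el.text_content())
        if tag == "h1":
            if seen_h1:
                log.warning("%s: multiple <h1> tags; demoting later title %r", doc_id, text)
                attach(DomNode("other", text))
                continue
            seen_h1 = True
        level = int(tag[1])
        while stack and stack[-1][0] >= level:
            stack.pop()
        node = DomNode(tag, text)
        attach(node)
        stack.append((level, node))

    if not forest:
        body_text = _norm_text(root.text_content())
        if not body_text:
            raise UnusableDocumentError(f"{doc_id}: no extractable content")
        return DomNode("other", body_text)
    if len(forest) == 1:
        return forest[0]
    return DomNode("other", "", forest)


def serialize_dom(node: DomNode) -> str:
    """Serialize the retained structure back to HTML.

    ``parse_dom_document(serialize_dom(t))`` reproduces ``t`` for any tree
    produced by :func:`parse_dom_document` (demoted titles round-trip as
    <h1> tags that get demoted again in the same position).
    """
    return _serialize(node, is_root=True)


def _serialize(node: DomNode, is_root: bool = False) -> str:
    kids = "".join(_serialize(c) for c in node.children)
    if node.tag == "other":
        if is_root:
            return _html_escape(node.text) + kids
        return f"<h1>{_html_escape(node.text)}</h1>" + kids
    if node.tag == "li":
        return f"<li>{_html_escape(node.text)}</li>" + kids
    return f"<{node.tag}>{_html_escape(node.text)}</{node.tag}>" + kids


def count_dom_nodes(root: DomNode, tag: str) -> int:
    return sum(1 for n in root.iter_nodes() if n.tag == tag)
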