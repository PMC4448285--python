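"""Shared fixture builders and independent oracles for the test suite.

Oracles here are deliberately naive (exhaustive enumeration, closed-form
transcriptions) and independent of the implementation paths they check.
"""

from __future__ import annotations

import itertools
import random

from kbharvest.corpus import DependencyEdge, DocumentMeta, ParsedSentence, Token
from kbharvest.reasoning import WeightedClause
from kbharvest.recognition import EntityMention


def make_sentence(
    words: list[str],
    edges: list[tuple[int, int, str]],
    doc_id: str = "d0",
    sent_id: str = "s0",
    lemmas: list[str] | None = None,
) -> ParsedSentence:
    lem = lemmas or [w.lower() for w in words]
    tokens = tuple(Token(i, w, lem[i], "XX") for i, w in enumerate(words))
    return ParsedSentence(
        doc_id, sent_id, tokens, tuple(DependencyEdge(g, d, l) for g, d, l in edges)
    )


def make_mention(
    start: int,
    end: int,
    entity_id: str = "E1",
    types: frozenset[str] = frozenset({"disease"}),
    doc_id: str = "d0",
    sent_id: str = "s0",
    similarity: float = 1.0,
) -> EntityMention:
    return EntityMention(doc_id, sent_id, start, end, entity_id, types, entity_id, similarity)


def meta(doc_id: str = "d0", genre: str = "scientific", source: str = "pubmed") -> DocumentMeta:
    return DocumentMeta(doc_id, genre, source)


def random_tree_sentence(rng: random.Random, n: int) -> ParsedSentence:
    """Random labeled tree over n tokens (random attachment)."""
    words = [f"w{i}" for i in range(n)]
    edges = [
        (rng.randrange(i), i, rng.choice(["dep", "nsubj", "amod", "prep"]))
        for i in range(1, n)
    ]
    return make_sentence(words, edges)


def brute_force_shortest_path(
    sentence: ParsedSentence, a: int, b: int
) -> tuple[int, ...] | None:
    """Exhaustive simple-path enumeration on the undirected graph; returns
    the shortest path from a to b, lexicographically smallest on ties."""
    adj: dict[int, set[int]] = {i: set() for i in range(len(sentence.tokens))}
    for e in sentence.edges:
        adj[e.governor].add(e.dependent)
        adj[e.dependent].add(e.governor)
    best: tuple[int, ...] | None = None

    def dfs(path: list[int]) -> None:
        nonlocal best
        cur = path[-1]
        if best is not None and len(path) > len(best):
            return
        if cur == b:
            cand = tuple(path)
            if best is None or (len(cand), cand) < (len(best), best):
                best = cand
            return
        for nxt in sorted(adj[cur]):
            if nxt not in path:
                dfs(path + [nxt])

    dfs([a])
    return best


# ---------------------------------------------------------------------------
# Max-Sat oracle
# ---------------------------------------------------------------------------

def brute_force_maxsat(clauses: list[WeightedClause]) -> float | None:
    """Exhaustive optimum soft weight over assignments satisfying all hard
    clauses; None when the hard clauses are unsatisfiable."""
    variables = sorted({v for c in clauses for v, _ in c.literals})
    best: float | None = None
    for bits in itertools.product((False, True), repeat=len(variables)):
        assign = dict(zip(variables, bits))
        ok = all(
            any(assign[v] == s for v, s in c.literals) for c in clauses if c.hard
        )
        if not ok:
            continue
        soft = sum(
            c.weight
            for c in clauses
            if not c.hard and any(assign[v] == s for v, s in c.literals)
        )
        if best is None or soft > best:
            best = soft
    return best


def hard_violations(assignment: dict, clauses: list[WeightedClause]) -> int:
    return sum(
        1
        for c in clauses
        if c.hard and not any(assignment[v] == s for v, s in c.literals)
    )


def random_maxsat_instance(
    rng: random.Random,
    max_vars: int = 12,
    unit_only: bool = False,
    allow_hard: bool = True,
) -> list[WeightedClause]:
    n = rng.randint(2, max_vars)
    variables = [("r", f"x{i}", f"y{i}") for i in range(n)]
    clauses: list[WeightedClause] = []
    for v in variables:
        clauses.append(
            WeightedClause(frozenset({(v, True)}), weight=round(rng.uniform(0.05, 1.0), 3))
        )
        if rng.random() < 0.3:
            clauses.append(
                WeightedClause(frozenset({(v, False)}), weight=round(rng.uniform(0.05, 1.0), 3))
            )
    if not unit_only:
        for _ in range(rng.randint(0, n)):
            a, b = rng.sample(variables, 2)
            clauses.append(
                WeightedClause(
                    frozenset({(a, rng.random() < 0.5), (b, rng.random() < 0.5)}),
                    weight=round(rng.uniform(0.05, 1.0), 3),
                )
            )
    if allow_hard:
        for _ in range(rng.randint(0, n // 2)):
            a, b = rng.sample(variables, 2)
            # all-negative hard clauses are always jointly satisfiable
            clauses.append(WeightedClause(frozenset({(a, False), (b, False)}), hard=True))
    return clauses


# ---------------------------------------------------------------------------
# Statistics oracles (formula transcriptions)
# ---------------------------------------------------------------------------

def wilson_oracle(k: int, n: int, alpha: float) -> tuple[float, float]:
    from scipy.stats import norm

    z = norm.ppf(1.0 - alpha / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = (z / denom) * ((p * (1 - p) / n + z * z / (4 * n * n)) ** 0.5)
    return center - half, center + half


def fleiss_kappa_oracle(matrix: list[list[int]]) -> float:
    n_items = len(matrix)
    raters = sum(matrix[0])
    p_j = [sum(row[j] for row in matrix) / (n_items * raters) for j in range(len(matrix[0]))]
    p_i = [
        (sum(c * c for c in row) - raters) / (raters * (raters - 1)) for row in matrix
    ]
    p_bar = sum(p_i) / n_items
    p_e = sum(p * p for p in p_j)
    return (p_bar - p_e) / (1.0 - p_e)
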