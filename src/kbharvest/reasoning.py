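"""Consistency reasoning over fact candidates via weighted Max-Sat.

Candidates are first filtered by relation type signatures (a cheap hard
constraint applied as a pre-filter, shrinking the hypothesis space before
the NP-hard step).  The survivors, mutual-exclusion constraints, and seed
facts are encoded as weighted clauses:

  * per candidate f: a soft unit clause (f) with the candidate weight,
  * per instantiated exclusion between candidates f, g: HARD (~f | ~g),
  * per seed fact present among candidates: HARD unit (f).

The weighted Max-Sat instance is solved approximately with the
dominating-unit-clause (DUC) preprocessing rule followed by Johnson's
greedy expected-weight heuristic.  Hard clauses are honored by unit
propagation after every assignment rather than by literal infinite
weights: infinite weights on both sides of the greedy comparison would
make it degenerate, while propagation keeps the greedy score a pure
soft-weight expectation and never violates a satisfiable hard clause of
the binary-exclusion / unit form produced here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .analysis import FactCandidate
from .recognition import SemanticTypeHierarchy
from .relations import ExclusionConstraint, TypeSignature

log = logging.getLogger(__name__)

FactKey = tuple[str, str, str]  # (relation, left_entity, right_entity)


class InfeasibilityError(RuntimeError):
    """Mutually contradictory hard clauses."""


@dataclass(frozen=True)
class WeightedClause:
    """Signed disjunction over fact hypotheses; soft weight or hard flag."""

    literals: frozenset[tuple[FactKey, bool]]
    weight: float = 0.0
    hard: bool = False

    def __post_init__(self) -> None:
        if not self.literals:
            raise ValueError("clause must have at least one literal")
        variables = [v for v, _ in self.literals]
        if len(set(variables)) != len(variables):
            raise ValueError("clause contains a literal and its negation")
        if not self.hard and self.weight <= 0.0:
            raise ValueError("soft clause weight must be positive")


@dataclass(frozen=True)
class ReasonerResult:
    accepted: frozenset[FactKey]
    rejected: frozenset[FactKey]
    satisfied_weight: float


# ---------------------------------------------------------------------------
# Type checking
# ---------------------------------------------------------------------------

def check_type_signature(
    candidate: FactCandidate,
    signatures: Mapping[str, TypeSignature],
    entity_types: Mapping[str, frozenset[str]],
    hierarchy: SemanticTypeHierarchy,
) -> tuple[bool, str]:
    """Pass iff the left entity holds a domain type and the right entity a
    range type, where holding a descendant of a signature type counts."""
    sig = signatures.get(candidate.relation)
    if sig is None:
        raise KeyError(f"no type signature for relation {candidate.relation!r}")

    def holds(entity: str, allowed: frozenset[str]) -> bool:
        for t in entity_types.get(entity, frozenset()):
            if set(hierarchy.ancestors_or_self(t)) & allowed:
                return True
        return False

    if not holds(candidate.left_entity, sig.domain_types):
        return False, f"left entity {candidate.left_entity} lacks a domain type of {candidate.relation}"
    if not holds(candidate.right_entity, sig.range_types):
        return False, f"right entity {candidate.right_entity} lacks a range type of {candidate.relation}"
    return True, "ok"


def filter_by_type_signature(
    candidates: Sequence[FactCandidate],
    signatures: Mapping[str, TypeSignature],
    entity_types: Mapping[str, frozenset[str]],
    hierarchy: SemanticTypeHierarchy,
) -> tuple[list[FactCandidate], list[tuple[FactKey, str]]]:
    kept: list[FactCandidate] = []
    pruned: list[tuple[FactKey, str]] = []
    for c in candidates:
        ok, reason = check_type_signature(c, signatures, entity_types, hierarchy)
        (kept.append(c) if ok else pruned.append((c.key, reason)))
    return kept, pruned


# ---------------------------------------------------------------------------
# Clause grounding
# ---------------------------------------------------------------------------

def ground_clauses(
    candidates: Sequence[FactCandidate],
    exclusions: Sequence[ExclusionConstraint] = (),
    seeds: Sequence[FactKey] = (),
) -> list[WeightedClause]:
    """Instantiate soft unit clauses, hard exclusions, and hard seed units.

    Raises :class:`InfeasibilityError` when an exclusion instantiates
    against two seed-pinned facts.
    """
    keys = {c.key for c in candidates}
    seed_pinned = keys & set(seeds)
    clauses: list[WeightedClause] = [
        WeightedClause(frozenset({(c.key, True)}), weight=c.weight)
        for c in sorted(candidates, key=lambda c: c.key)
    ]
    seen_pairs: set[frozenset[FactKey]] = set()
    for excl in exclusions:
        for key in sorted(keys):
            rel, x, y = key
            if rel != excl.relation_a:
                continue
            partner: FactKey = (
                (excl.relation_b, x, y)
                if excl.argument_map == "same"
                else (excl.relation_b, y, x)
            )
            if partner not in keys or partner == key:
                continue
            pair = frozenset({key, partner})
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            if key in seed_pinned and partner in seed_pinned:
                raise InfeasibilityError(
                    f"exclusion {excl.relation_a}/{excl.relation_b} grounds against "
                    f"seed-pinned facts {key} and {partner}"
                )
            clauses.append(
                WeightedClause(frozenset({(key, False), (partner, False)}), hard=True)
            )
    for key in sorted(seed_pinned):
        clauses.append(WeightedClause(frozenset({(key, True)}), hard=True))
    return clauses


# ---------------------------------------------------------------------------
# DUC + Johnson approximate weighted Max-Sat
# ---------------------------------------------------------------------------

class _Solver:
    def __init__(self, clauses: Sequence[WeightedClause]) -> None:
        self.assignment: dict[FactKey, bool] = {}
        self.satisfied_weight = 0.0
        # mutable clause state: [set_of_literals, weight, hard]
        self.active: list[list] = [
            [set(c.literals), c.weight, c.hard] for c in clauses
        ]
        self.hard_weight = sum(c.weight for c in clauses if not c.hard) + 1.0

    def assign(self, var: FactKey, value: bool) -> None:
        self.assignment[var] = value
        remaining = []
        for lits, w, hard in self.active:
            if (var, value) in lits:
                if not hard:
                    self.satisfied_weight += w
                continue
            if (var, not value) in lits:
                lits.discard((var, not value))
                if not lits:
                    if hard:
                        raise InfeasibilityError(
                            f"hard clause falsified while assigning {var}"
                        )
                    continue  # soft clause unsatisfiable; dropped
            remaining.append([lits, w, hard])
        self.active = remaining

    def propagate_hard_units(self) -> None:
        while True:
            unit = next(
                (lits for lits, _, hard in self.active if hard and len(lits) == 1),
                None,
            )
            if unit is None:
                return
            var, sign = next(iter(unit))
            self.assign(var, sign)

    def duc_pass(self) -> None:
        """Fix literals whose unit-clause weight dominates the total weight
        of clauses containing their negation; repeat to fixpoint."""
        while True:
            unit_w: dict[tuple[FactKey, bool], float] = {}
            against: dict[tuple[FactKey, bool], float] = {}
            for lits, w, hard in self.active:
                cw = self.hard_weight if hard else w
                if len(lits) == 1:
                    lit = next(iter(lits))
                    unit_w[lit] = unit_w.get(lit, 0.0) + cw
                for var, sign in lits:
                    neg = (var, not sign)
                    against[neg] = against.get(neg, 0.0) + cw
            fixed = False
            for lit in sorted(unit_w):
                if lit[0] in self.assignment:
                    continue
                if unit_w[lit] >= against.get(lit, 0.0):
                    self.assign(*lit)
                    self.propagate_hard_units()
                    fixed = True
                    break
            if not fixed:
                return

    def _expected_soft(self, var: FactKey, value: bool) -> float:
        total = 0.0
        for lits, w, hard in self.active:
            if hard:
                continue
            if (var, value) in lits:
                total += w
            elif (var, not value) in lits:
                u = len(lits) - 1
                if u > 0:
                    total += w * (1.0 - 2.0 ** -u)
            else:
                total += w * (1.0 - 2.0 ** -len(lits))
        return total

    def johnson_pass(self) -> None:
        incident: dict[FactKey, float] = {}
        variables: set[FactKey] = set()
        for lits, w, hard in self.active:
            for var, _ in lits:
                variables.add(var)
                if not hard:
                    incident[var] = incident.get(var, 0.0) + w
        order = sorted(variables, key=lambda v: (-incident.get(v, 0.0), v))
        for var in order:
            if var in self.assignment:
                continue
            forced = next(
                (
                    sign
                    for lits, _, hard in self.active
                    if hard and len(lits) == 1
                    for v, sign in lits
                    if v == var
                ),
                None,
            )
            if forced is not None:
                self.assign(var, forced)
            else:
                self.assign(var, self._expected_soft(var, True) >= self._expected_soft(var, False))
            self.propagate_hard_units()


def solve_weighted_maxsat(
    clauses: Sequence[WeightedClause],
) -> tuple[dict[FactKey, bool], float]:
    """Approximate weighted Max-Sat: DUC preprocessing + Johnson's greedy.

    Returns a total assignment over the clause variables and the total
    weight of satisfied soft clauses.  Deterministic.  Raises
    :class:`InfeasibilityError` on contradictory hard clauses.
    """
    solver = _Solver(clauses)
    solver.propagate_hard_units()
    solver.duc_pass()
    solver.johnson_pass()
    # variables only in dropped clauses: default to False (rejected)
    for c in clauses:
        for var, _ in c.literals:
            solver.assignment.setdefault(var, False)
    assert not solver.active, "all clauses must be resolved by a total assignment"
    return solver.assignment, solver.satisfied_weight


def extract_accepted_facts(
    assignment: Mapping[FactKey, bool],
    candidates: Sequence[FactCandidate],
    satisfied_weight: float = 0.0,
) -> ReasonerResult:
    accepted = frozenset(c.key for c in candidates if assignment.get(c.key, False))
    rejected = frozenset(c.key for c in candidates) - accepted
    return ReasonerResult(accepted, rejected, satisfied_weight)


def run_reasoner(
    candidates: Sequence[FactCandidate],
    signatures: Mapping[str, TypeSignature],
    entity_types: Mapping[str, frozenset[str]],
    hierarchy: SemanticTypeHierarchy,
    exclusions: Sequence[ExclusionConstraint] = (),
    seeds: Sequence[FactKey] = (),
) -> tuple[ReasonerResult, list[FactCandidate], list[tuple[FactKey, str]]]:
    """Type-filter, ground, solve; returns (result, surviving candidates, pruned)."""
    kept, pruned = filter_by_type_signature(candidates, signatures, entity_types, hierarchy)
    if not kept:
        return ReasonerResult(frozenset(), frozenset(), 0.0), [], pruned
    clauses = ground_clauses(kept, exclusions, seeds)
    assignment, weight = solve_weighted_maxsat(clauses)
    return extract_accepted_facts(assignment, kept, weight), kept, pruned
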