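"""Consistency reasoner: type checks, grounding, DUC+Johnson Max-Sat."""

import random

import pytest

from kbharvest.analysis import FactCandidate, PatternOccurrence
from kbharvest.reasoning import (
    InfeasibilityError,
    WeightedClause,
    check_type_signature,
    extract_accepted_facts,
    ground_clauses,
    run_reasoner,
    solve_weighted_maxsat,
)
from kbharvest.relations import DEFAULT_EXCLUSIONS, DEFAULT_SIGNATURES, ExclusionConstraint
from kbharvest.synthetic import default_hierarchy

from .helpers import brute_force_maxsat, hard_violations, random_maxsat_instance


def cand(rel, left, right, weight=0.5):
    support = (PatternOccurrence(("p",), left, right, "d0", "s0"),)
    return FactCandidate(rel, left, right, weight, support)


ENTITY_TYPES = {
    "dis": frozenset({"disease"}),
    "dis_leaf": frozenset({"disease.a"}),
    "org": frozenset({"organ"}),
    "drug": frozenset({"drug"}),
    "sym": frozenset({"symptom"}),
}


@pytest.fixture(scope="module")
def hier():
    return default_hierarchy()


class TestTypeSignature:
    def test_disease_organ_passes_affects(self, hier):
        ok, _ = check_type_signature(cand("affects", "dis", "org"), DEFAULT_SIGNATURES, ENTITY_TYPES, hier)
        assert ok

    def test_disease_drug_fails_affects(self, hier):
        ok, reason = check_type_signature(cand("affects", "dis", "drug"), DEFAULT_SIGNATURES, ENTITY_TYPES, hier)
        assert not ok and "range" in reason

    def test_descendant_type_passes(self, hier):
        # leaf subtype of disease accepted wherever disease is: hierarchy-walk oracle
        ok, _ = check_type_signature(cand("causes", "dis_leaf", "dis"), DEFAULT_SIGNATURES, ENTITY_TYPES, hier)
        assert ok
        assert "disease" in hier.ancestors_or_self("disease.a")

    def test_unknown_relation_is_error(self, hier):
        with pytest.raises(KeyError):
            check_type_signature(cand("frobs", "dis", "org"), DEFAULT_SIGNATURES, ENTITY_TYPES, hier)


class TestGrounding:
    def test_no_constraints_yields_soft_units(self):
        clauses = ground_clauses([cand("treats", "a", "b"), cand("causes", "c", "d")])
        assert len(clauses) == 2
        assert all(not c.hard and len(c.literals) == 1 for c in clauses)

    def test_side_effect_treats_exclusion_grounds_hard_clause(self):
        cands = [cand("sideEffect", "s", "d"), cand("treats", "d", "s")]
        clauses = ground_clauses(cands, DEFAULT_EXCLUSIONS)
        hard = [c for c in clauses if c.hard]
        assert len(hard) == 1
        assert hard[0].literals == frozenset(
            {(("sideEffect", "s", "d"), False), (("treats", "d", "s"), False)}
        )

    def test_clause_count_is_candidates_plus_exclusions_plus_seeds(self):
        rng = random.Random(2)
        cands = [cand("sideEffect", f"s{i}", f"d{i}") for i in range(5)]
        cands += [cand("treats", f"d{i}", f"s{i}") for i in range(3)]
        seeds = [("sideEffect", "s4", "d4")]
        clauses = ground_clauses(cands, DEFAULT_EXCLUSIONS, seeds)
        assert len(clauses) == len(cands) + 3 + 1

    def test_seed_pinned_conflict_is_infeasible(self):
        cands = [cand("sideEffect", "s", "d"), cand("treats", "d", "s")]
        seeds = [("sideEffect", "s", "d"), ("treats", "d", "s")]
        with pytest.raises(InfeasibilityError, match="seed-pinned"):
            ground_clauses(cands, DEFAULT_EXCLUSIONS, seeds)

    def test_contradictory_literal_clause_rejected(self):
        v = ("treats", "a", "b")
        with pytest.raises(ValueError, match="negation"):
            WeightedClause(frozenset({(v, True), (v, False)}), weight=1.0)


class TestSolver:
    def test_conflict_free_accepts_everything(self):
        cands = [cand("treats", "a", "b", 0.4), cand("causes", "c", "d", 0.9)]
        clauses = ground_clauses(cands)
        assignment, weight = solve_weighted_maxsat(clauses)
        assert all(assignment.values())
        assert weight == pytest.approx(1.3)

    def test_weight_dominance_resolves_exclusion(self):
        f = cand("sideEffect", "s", "d", 0.9)
        g = cand("treats", "d", "s", 0.4)
        clauses = ground_clauses([f, g], DEFAULT_EXCLUSIONS)
        assignment, weight = solve_weighted_maxsat(clauses)
        assert assignment[f.key] is True
        assert assignment[g.key] is False
        assert weight == pytest.approx(0.9)

    def test_hard_seed_unit_forces_acceptance(self):
        f = cand("sideEffect", "s", "d", 0.1)
        g = cand("treats", "d", "s", 0.9)
        clauses = ground_clauses([f, g], DEFAULT_EXCLUSIONS, seeds=[f.key])
        assignment, _ = solve_weighted_maxsat(clauses)
        assert assignment[f.key] is True and assignment[g.key] is False

    def test_contradictory_hard_units_infeasible(self):
        v = ("treats", "a", "b")
        clauses = [
            WeightedClause(frozenset({(v, True)}), hard=True),
            WeightedClause(frozenset({(v, False)}), hard=True),
        ]
        with pytest.raises(InfeasibilityError):
            solve_weighted_maxsat(clauses)

    def test_matches_exhaustive_optimum_without_hard_clauses(self):
        rng = random.Random(0)
        for _ in range(40):
            clauses = random_maxsat_instance(rng, max_vars=8, unit_only=True, allow_hard=False)
            assignment, weight = solve_weighted_maxsat(clauses)
            assert weight == pytest.approx(brute_force_maxsat(clauses))

    def test_half_optimal_and_sound_on_random_instances(self):
        rng = random.Random(1)
        for _ in range(60):
            clauses = random_maxsat_instance(rng, max_vars=10)
            assignment, weight = solve_weighted_maxsat(clauses)
            assert hard_violations(assignment, clauses) == 0
            opt = brute_force_maxsat(clauses)
            assert weight >= 0.5 * opt - 1e-9

    def test_deterministic(self):
        rng = random.Random(9)
        clauses = random_maxsat_instance(rng, max_vars=12)
        first = solve_weighted_maxsat(clauses)
        assert solve_weighted_maxsat(list(clauses)) == first


class TestReasonerEndToEnd:
    def test_accepted_set_satisfies_all_exclusions(self, hier):
        rng = random.Random(4)
        types = {}
        cands = []
        for i in range(15):
            s, d = f"s{i % 5}", f"d{i % 4}"
            types[s] = frozenset({"symptom"})
            types[d] = frozenset({"drug"})
            rel = rng.choice(["sideEffect", "treats"])
            pair = (s, d) if rel == "sideEffect" else (d, s)
            key = (rel, *pair)
            if any(c.key == key for c in cands):
                continue
            cands.append(cand(rel, *pair, weight=round(rng.uniform(0.1, 0.9), 2)))
        result, kept, _ = run_reasoner(cands, DEFAULT_SIGNATURES, types, hier, DEFAULT_EXCLUSIONS)
        for rel, x, y in result.accepted:
            if rel == "sideEffect":
                assert ("treats", y, x) not in result.accepted

    def test_removing_exclusions_never_shrinks_accepted(self, hier):
        types = {"s": frozenset({"symptom"}), "d": frozenset({"drug"})}
        cands = [cand("sideEffect", "s", "d", 0.8), cand("treats", "d", "s", 0.7)]
        with_excl, _, _ = run_reasoner(cands, DEFAULT_SIGNATURES, types, hier, DEFAULT_EXCLUSIONS)
        without, _, _ = run_reasoner(cands, DEFAULT_SIGNATURES, types, hier, ())
        assert with_excl.accepted <= without.accepted

    def test_type_filter_prunes_before_solving(self, hier):
        cands = [cand("affects", "dis", "drug"), cand("affects", "dis", "org")]
        result, kept, pruned = run_reasoner(cands, DEFAULT_SIGNATURES, ENTITY_TYPES, hier)
        assert [k for k, _ in pruned] == [("affects", "dis", "drug")]
        assert result.accepted == {("affects", "dis", "org")}

    def test_result_partitions_hypotheses(self):
        cands = [cand("treats", "a", "b"), cand("treats", "c", "d")]
        assignment = {cands[0].key: True, cands[1].key: False}
        result = extract_accepted_facts(assignment, cands, 0.5)
        assert result.accepted | result.rejected == {c.key for c in cands}
        assert not result.accepted & result.rejected
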