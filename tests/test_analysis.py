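"""Pattern analysis: seed index, mining, confidence, scoring, candidates."""

import itertools
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from kbharvest.analysis import (
    FactCandidate,
    PatternOccurrence,
    SeedFact,
    SeedPattern,
    build_fact_candidates,
    build_seed_index,
    compute_all_confidences,
    compute_confidence,
    is_subsequence,
    mine_frequent_subsequences,
    read_seed_facts,
    score_pattern,
    select_seed_patterns,
    token_set_jaccard,
    write_seed_facts,
)
from kbharvest.relations import DEFAULT_SEED_COUNTS
from kbharvest.synthetic import CorpusSpec, generate_corpus


def occ(pattern, left="L", right="R", doc="d0", sent="s0"):
    return PatternOccurrence(tuple(pattern), left, right, doc, sent)


class TestSeedIndex:
    def test_single_relation_has_empty_cx(self):
        idx = build_seed_index([SeedFact("treats", "a", "b"), SeedFact("treats", "c", "d")])
        assert idx.cx("treats") == frozenset()
        assert idx.sx("treats") == {("a", "b"), ("c", "d")}

    def test_reference_seed_counts_total_467(self):
        corpus = generate_corpus(CorpusSpec(rng_seed=1))
        assert len(corpus.seeds) == sum(DEFAULT_SEED_COUNTS.values()) == 467
        idx = build_seed_index(corpus.seeds)
        assert sum(len(idx.sx(r)) for r in idx.relations) == 467

    def test_unknown_relation_rejected(self):
        with pytest.raises(ValueError, match="unknown relation"):
            build_seed_index([SeedFact("frobnicates", "a", "b")])

    def test_sx_cx_partition_by_exhaustive_scan(self):
        rng = random.Random(3)
        seeds = [
            SeedFact(rng.choice(["treats", "causes", "affects"]), f"e{rng.randrange(6)}", f"e{rng.randrange(6)}")
            for _ in range(30)
        ]
        idx = build_seed_index(seeds)
        for rel in idx.relations:
            sx, cx = idx.sx(rel), idx.cx(rel)
            assert sx & cx == frozenset()
            assert sx | cx == idx.all_pairs
            for pair in idx.all_pairs:  # membership scan oracle
                in_rel = any(s.pair == pair and s.relation == rel for s in seeds)
                assert (pair in sx) == in_rel

    def test_ordered_pairs(self):
        idx = build_seed_index([SeedFact("treats", "a", "b")])
        assert ("b", "a") not in idx.sx("treats")


class TestMining:
    def test_risk_factors_subsequence_found(self):
        occurrences = [
            occ(["known", "risk", "factors"], doc="d0"),
            occ(["have", "risk", "factors"], doc="d1"),
            occ(["children", "risk", "factors"], doc="d2"),
        ]
        mined = mine_frequent_subsequences(occurrences, 3)
        assert mined[("risk", "factors")] == 3

    def test_unsatisfiable_support_empty(self):
        assert mine_frequent_subsequences([occ(["a", "b"])], 2) == {}

    def test_matches_bruteforce_enumeration(self):
        rng = random.Random(1)
        vocab = ["a", "b", "c", "d"]
        for _ in range(10):
            occurrences = [
                occ([rng.choice(vocab) for _ in range(rng.randint(1, 4))], doc=f"d{i}")
                for i in range(rng.randint(1, 5))
            ]
            mined = mine_frequent_subsequences(occurrences, 1)
            # brute force: count occurrences containing each possible subsequence
            counts = {}
            for o in occurrences:
                subs = set()
                for k in range(1, len(o.pattern) + 1):
                    for idxs in itertools.combinations(range(len(o.pattern)), k):
                        subs.add(tuple(o.pattern[i] for i in idxs))
                for s in subs:
                    counts[s] = counts.get(s, 0) + 1
            assert mined == counts

    @given(st.lists(st.sampled_from("abc"), max_size=4), st.lists(st.sampled_from("abc"), max_size=6))
    def test_is_subsequence_matches_bruteforce(self, q, p):
        brute = any(
            list(q) == [p[i] for i in idxs]
            for k in range(len(q) + 1)
            for idxs in itertools.combinations(range(len(p)), k)
        ) or not q
        assert is_subsequence(q, p) == brute


class TestConfidence:
    def seeds(self):
        return build_seed_index(
            [
                SeedFact("createsRisk", "ob", "db"),
                SeedFact("createsRisk", "ob", "as"),
                SeedFact("createsRisk", "wd", "as"),
                SeedFact("affects", "ha", "tg"),
                SeedFact("affects", "pc", "ht"),
                SeedFact("isSymptom", "an", "sa"),
            ]
        )

    def test_pure_cooccurrence_confidence_one(self):
        occurrences = [
            occ(["known", "risk", "factor"], "ob", "db", doc="d0"),
            occ(["have", "risk", "factor"], "ob", "as", doc="d1"),
            occ(["risk", "factor", "for"], "wd", "as", doc="d2"),
        ]
        assert compute_confidence(("risk", "factor"), "createsRisk", occurrences, self.seeds()) == 1.0

    def test_split_cooccurrence_two_thirds_one_third(self):
        occurrences = [
            occ(["occur", "anywhere"], "ha", "tg", doc="d0"),
            occ(["occur", "near"], "pc", "ht", doc="d1"),
            occ(["occur", "patient"], "an", "sa", doc="d2"),
        ]
        idx = self.seeds()
        assert compute_confidence(("occur",), "affects", occurrences, idx) == pytest.approx(2 / 3)
        assert compute_confidence(("occur",), "isSymptom", occurrences, idx) == pytest.approx(1 / 3)

    def test_no_seed_cooccurrence_undefined(self):
        occurrences = [occ(["occur"], "x", "y")]
        assert compute_confidence(("occur",), "affects", occurrences, self.seeds()) is None

    def test_counting_is_per_distinct_sentence(self):
        # two occurrences in the same sentence count once
        occurrences = [
            occ(["occur", "anywhere"], "ha", "tg", doc="d0"),
            occ(["occur", "near"], "ha", "tg", doc="d0"),
            occ(["occur", "patient"], "an", "sa", doc="d1"),
        ]
        idx = self.seeds()
        assert compute_confidence(("occur",), "affects", occurrences, idx) == pytest.approx(1 / 2)

    def test_confidences_sum_to_one_over_relations(self):
        rng = random.Random(7)
        pairs = {"createsRisk": ("ob", "db"), "affects": ("ha", "tg"), "isSymptom": ("an", "sa")}
        occurrences = [
            occ(["occur", "thing"], *pairs[rng.choice(list(pairs))], doc=f"d{i}")
            for i in range(12)
        ]
        idx = self.seeds()
        confs = compute_all_confidences([("occur",)], occurrences, idx)
        total = sum(confs.get((("occur",), r), 0.0) for r in idx.relations)
        assert total == pytest.approx(1.0)

    def test_compute_all_matches_single(self):
        occurrences = [
            occ(["occur", "anywhere"], "ha", "tg", doc="d0"),
            occ(["occur", "patient"], "an", "sa", doc="d1"),
        ]
        idx = self.seeds()
        confs = compute_all_confidences([("occur",), ("anywhere",)], occurrences, idx)
        for (q, rel), c in confs.items():
            assert c == compute_confidence(q, rel, occurrences, idx)


class TestSelection:
    def test_strictly_greater_than_threshold(self):
        confs = {
            (("a",), "treats"): 0.31,
            (("b",), "treats"): 0.30,
            (("c",), "treats"): 0.29,
        }
        kept = select_seed_patterns(confs, 0.3)
        assert [(sp.tokens, sp.confidence) for sp in kept] == [(("a",), 0.31)]

    def test_one_subsequence_may_seed_two_relations(self):
        confs = {(("occur",), "affects"): 2 / 3, (("occur",), "isSymptom"): 1 / 3}
        kept = select_seed_patterns(confs, 0.3)
        assert {(sp.tokens, sp.relation) for sp in kept} == {
            (("occur",), "affects"),
            (("occur",), "isSymptom"),
        }

    def test_refilter_oracle_on_random_confidences(self):
        rng = random.Random(11)
        confs = {((f"w{i}",), "treats"): round(rng.random(), 3) for i in range(50)}
        kept = select_seed_patterns(confs, 0.3)
        expected = {k for k, v in confs.items() if v > 0.3}
        assert {(sp.tokens, sp.relation) for sp in kept} == expected


class TestScoring:
    Q = [
        SeedPattern(("risk", "factor"), "createsRisk", 1.0),
        SeedPattern(("progress",), "createsRisk", 0.5),
        SeedPattern(("occur",), "affects", 2 / 3),
    ]

    def test_identical_pattern_scores_confidence(self):
        w, rel = score_pattern(("risk", "factor"), self.Q)
        assert (w, rel) == (1.0, "createsRisk")

    def test_no_overlap_yields_no_candidate(self):
        assert score_pattern(("zzz",), self.Q) is None

    def test_generalized_match(self):
        # "which progresses to" lemmatized contains "progress"
        w, rel = score_pattern(("which", "progress", "to"), self.Q)
        assert rel == "createsRisk"
        assert w == pytest.approx((1 / 3) * 0.5)

    def test_exhaustive_max_oracle(self):
        rng = random.Random(13)
        vocab = ["a", "b", "c", "d", "e"]
        for _ in range(30):
            p = tuple(rng.sample(vocab, rng.randint(1, 4)))
            got = score_pattern(p, self.Q)
            best = max(
                (token_set_jaccard(p, q.tokens) * q.confidence for q in self.Q),
                default=0.0,
            )
            if best == 0.0:
                assert got is None
            else:
                assert got[0] == pytest.approx(best)


class TestCandidates:
    Q = [SeedPattern(("treat",), "treats", 0.6)]

    def test_single_support_identity(self):
        cands = build_fact_candidates([occ(["treat"], "d", "s")], self.Q)
        assert len(cands) == 1 and cands[0].weight == pytest.approx(0.6)

    def test_noisy_or_closed_form(self):
        Q = [SeedPattern(("treat",), "treats", 0.5)]
        cands = build_fact_candidates(
            [occ(["treat"], "d", "s", doc="d0"), occ(["treat"], "d", "s", doc="d1")], Q
        )
        assert cands[0].weight == pytest.approx(0.75)  # 1 - 0.5*0.5

    def test_aggregation_monotone(self):
        one = build_fact_candidates([occ(["treat"], "d", "s", doc="d0")], self.Q)[0]
        two = build_fact_candidates(
            [occ(["treat"], "d", "s", doc="d0"), occ(["treat", "x"], "d", "s", doc="d1")],
            self.Q,
        )[0]
        assert two.weight >= one.weight
        assert len(two.support) == 2

    def test_generalization_assigns_relation(self):
        Q = [SeedPattern(("progress",), "createsRisk", 0.5)]
        cands = build_fact_candidates(
            [
                occ(["which", "progress", "to"], "ob", "di", doc="d0"),
                occ(["still", "progress", "to"], "wa", "sk", doc="d1"),
            ],
            Q,
        )
        assert {c.relation for c in cands} == {"createsRisk"}
        assert {c.key[1:] for c in cands} == {("ob", "di"), ("wa", "sk")}

    def test_candidate_invariants_enforced(self):
        with pytest.raises(ValueError):
            FactCandidate("treats", "a", "b", 0.0, (occ(["x"]),))
        with pytest.raises(ValueError):
            FactCandidate("treats", "a", "b", 0.5, ())


class TestSeedFactIO:
    def test_tsv_round_trip(self, tmp_path):
        seeds = [SeedFact("treats", "a", "b"), SeedFact("causes", "c", "d")]
        path = tmp_path / "seeds.tsv"
        write_seed_facts(seeds, path)
        assert read_seed_facts(path) == seeds
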