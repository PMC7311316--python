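"""Confidence classification, other-hit restriction, split joining."""

import itertools

import pytest

from gapseek.candidate_scoring import (
    Candidate,
    CandidateOrigin,
    OtherHit,
    RelevantRegion,
    classify_blast_candidate,
    classify_hmm_candidate,
    evaluate_split_join,
    find_other_hit,
    score_step,
)
from gapseek.config import EngineConfig
from gapseek.engine import analyze_genome
from gapseek.homology_search import AlignmentHit, HmmHit
from gapseek.reference_db import ProteinStatus, StepQuerySet
from gapseek.tiers import Confidence

CHAR = ProteinStatus.CHARACTERIZED
CUR = ProteinStatus.CURATED_ONLY


def hit(identity=50.0, coverage=0.9, bits=200.0, qid="q", sid="s",
        q_start=1, q_end=200, qlen=200, slen=1000):
    s_end = int(round(coverage * slen))
    return AlignmentHit(
        query_id=qid, subject_id=sid, percent_identity=identity,
        bit_score=bits, e_value=1e-30,
        q_start=q_start, q_end=q_end, s_start=1, s_end=s_end,
        query_length=qlen, subject_length=slen,
    )


def hmm_hit(coverage=0.9, bits=100.0):
    return HmmHit(
        query_id="q", hmm_id="h", bit_score=bits,
        q_start=1, q_end=200,
        hmm_start=1, hmm_end=int(round(coverage * 1000)), model_length=1000,
    )


def other(bits=100.0, identity=50.0, coverage=0.9):
    return OtherHit("o", bits, identity, coverage)


# ---------------------------------------------------------------------------
# independent, table-driven restatement of the printed classification rules

def oracle_blast(identity, coverage, bits, other_bits, characterized, has_other):
    rules = [
        (
            Confidence.HIGH,
            lambda: characterized and identity > 40 and coverage > 0.80
            and (not has_other or bits - other_bits >= 10),
        ),
        (Confidence.MEDIUM, lambda: identity > 40 and coverage > 0.70),
        (
            Confidence.MEDIUM,
            lambda: identity > 30 and coverage > 0.80
            and (not has_other or bits > other_bits),
        ),
        (Confidence.LOW, lambda: coverage >= 0.50),
    ]
    applicable = [tier for tier, ok in rules if ok()]
    return max(applicable) if applicable else None


def oracle_hmm(coverage, has_other, other_identity, other_coverage):
    if coverage >= 0.80 and (
        not has_other or other_identity < 40 or other_coverage < 0.75
    ):
        return Confidence.HIGH
    return Confidence.MEDIUM


class TestClassifyBlast:
    @pytest.mark.parametrize(
        "identity,coverage,status,oth,expected",
        [
            (85, 0.95, CHAR, None, Confidence.HIGH),
            # fails the +10 margin; passes 40/70 regardless-of-other
            (45, 0.95, CHAR, other(bits=196.0), Confidence.MEDIUM),
            # fails "bit score higher than other", passes 50% coverage
            (35, 0.85, CHAR, other(bits=250.0), Confidence.LOW),
            # curated-only can never be high confidence
            (45, 0.95, CUR, None, Confidence.MEDIUM),
            (35, 0.85, CHAR, None, Confidence.MEDIUM),
            (32, 0.55, CHAR, None, Confidence.LOW),
            (35, 0.45, CHAR, None, None),
        ],
    )
    def test_documented_examples(self, identity, coverage, status, oth, expected):
        got = classify_blast_candidate(hit(identity, coverage, bits=200.0), status, oth)
        assert got == expected

    @pytest.mark.parametrize(
        "identity,coverage,expected",
        [
            # boundary pinning: "over 40%" is strict, "at least 50%" is not
            (40.0, 0.95, Confidence.MEDIUM),
            (40.1, 0.95, Confidence.HIGH),
            (41.0, 0.80, Confidence.MEDIUM),
            (41.0, 0.801, Confidence.HIGH),
            (30.0, 0.95, Confidence.LOW),
            (30.1, 0.95, Confidence.MEDIUM),
            (31.0, 0.50, Confidence.LOW),
            (31.0, 0.499, None),
        ],
    )
    def test_threshold_boundaries(self, identity, coverage, expected):
        got = classify_blast_candidate(hit(identity, coverage), CHAR, None)
        assert got == expected

    def test_margin_boundary_is_inclusive(self):
        h = hit(identity=60, coverage=0.9, bits=110.0)
        assert classify_blast_candidate(h, CHAR, other(bits=100.0)) == Confidence.HIGH
        assert classify_blast_candidate(h, CHAR, other(bits=100.1)) == Confidence.MEDIUM

    def test_agrees_with_oracle_on_grid(self):
        coverages = [0.45, 0.55, 0.65, 0.75, 0.85, 0.95, 1.0]
        for identity in range(29, 102, 4):
            for cov in coverages:
                for margin in (-15, -5, 0, 5, 15):
                    for status in (CHAR, CUR):
                        for has_other in (False, True):
                            oth = other(bits=200.0 - margin) if has_other else None
                            got = classify_blast_candidate(
                                hit(identity, cov, bits=200.0), status, oth
                            )
                            want = oracle_blast(
                                identity, cov, 200.0, 200.0 - margin,
                                status is CHAR, has_other,
                            )
                            assert got == want, (identity, cov, margin, status, has_other)

    def test_monotone_in_identity_and_coverage(self):
        """With everything else fixed, raising identity or coverage never
        lowers the tier."""
        rank = {None: -1, Confidence.LOW: 0, Confidence.MEDIUM: 1, Confidence.HIGH: 2}
        for status in (CHAR, CUR):
            for oth in (None, other(bits=195.0), other(bits=250.0)):
                for cov in [0.45 + 0.05 * i for i in range(12)]:
                    tiers = [
                        rank[classify_blast_candidate(hit(i, cov, bits=200.0), status, oth)]
                        for i in range(30, 101, 2)
                    ]
                    assert tiers == sorted(tiers)
                for identity in range(30, 101, 5):
                    tiers = [
                        rank[classify_blast_candidate(
                            hit(identity, 0.45 + 0.05 * i, bits=200.0), status, oth)]
                        for i in range(12)
                    ]
                    assert tiers == sorted(tiers)


class TestClassifyHmm:
    @pytest.mark.parametrize(
        "coverage,oth,expected",
        [
            (0.95, None, Confidence.HIGH),
            (0.95, other(identity=55, coverage=0.90), Confidence.MEDIUM),
            (0.60, None, Confidence.MEDIUM),
            (0.95, other(identity=35, coverage=0.90), Confidence.HIGH),
            (0.95, other(identity=55, coverage=0.70), Confidence.HIGH),
        ],
    )
    def test_documented_examples(self, coverage, oth, expected):
        assert classify_hmm_candidate(hmm_hit(coverage), oth) == expected

    def test_agrees_with_oracle_on_grid(self):
        for cov in [0.5, 0.7, 0.79, 0.80, 0.9, 1.0]:
            for has_other in (False, True):
                for oi in (30, 39, 40, 41, 60):
                    for oc in (0.5, 0.74, 0.75, 0.9):
                        oth = other(identity=oi, coverage=oc) if has_other else None
                        got = classify_hmm_candidate(hmm_hit(cov), oth)
                        assert got == oracle_hmm(cov, has_other, oi, oc)


class TestFindOtherHit:
    def _qs(self, members=("REF",), ignored=()):
        qs = StepQuerySet(step_id="s")
        from gapseek.reference_db import ProteinRecord

        for m in members:
            qs.characterized.append(
                ProteinRecord(m, "M" + "A" * 120, "d", (), CHAR, "x")
            )
        qs.ignored = set(ignored)
        return qs

    def test_fusion_other_half_hit_outside_region_discarded(self):
        """A huge hit covering only the other half of a fusion overlaps 0%
        of the region and must be ignored."""
        region = RelevantRegion("fus", 1, 200)  # the X half
        y_hit = hit(identity=95, bits=500, qid="fus", sid="Y",
                    q_start=201, q_end=400, qlen=400)
        assert find_other_hit("fus", region, self._qs(), [y_hit]) is None

    def test_ignored_subject_discarded(self):
        region = RelevantRegion("q", 1, 200)
        competing = hit(identity=60, bits=300, sid="IGN")
        qs = self._qs(ignored=("IGN",))
        assert find_other_hit("q", region, qs, [competing]) is None

    def test_max_bit_score_survivor_wins(self):
        region = RelevantRegion("q", 1, 200)
        a = hit(bits=120, sid="A")
        b = hit(bits=95, sid="B")
        got = find_other_hit("q", region, self._qs(), [b, a])
        assert got.subject_id == "A" and got.bit_score == 120

    def test_step_members_never_count_as_other(self):
        region = RelevantRegion("q", 1, 200)
        assert find_other_hit("q", region, self._qs(members=("REF",)),
                              [hit(bits=400, sid="REF")]) is None

    def test_partial_overlap_threshold(self):
        region = RelevantRegion("q", 1, 100)
        # overlaps 49 of 100 -> discarded; 51 of 100 -> kept
        low = hit(bits=100, sid="A", q_start=52, q_end=200, qlen=200)
        high = hit(bits=100, sid="B", q_start=50, q_end=200, qlen=200)
        assert find_other_hit("q", region, self._qs(), [low]) is None
        assert find_other_hit("q", region, self._qs(), [high]).subject_id == "B"

    def test_region_outside_protein_errors(self):
        region = RelevantRegion("q", 150, 500)
        with pytest.raises(ValueError, match="outside"):
            find_other_hit("q", region, self._qs(), [hit(sid="A", qlen=200)])


def part(qid, s_start, s_end, bits=300.0, identity=100.0, slen=1000):
    return AlignmentHit(
        query_id=qid, subject_id="REF", percent_identity=identity,
        bit_score=bits, e_value=1e-40,
        q_start=1, q_end=s_end - s_start + 1,
        s_start=s_start, s_end=s_end,
        query_length=s_end - s_start + 1, subject_length=slen,
    )


class TestSplitJoining:
    def test_clean_bisection_joins_with_full_coverage(self):
        a, b = part("n", 1, 520), part("c", 505, 1000)
        join = evaluate_split_join(a, b, None, None)
        assert join is not None
        assert join.combined_coverage == 1.0
        assert join.percent_identity == 100.0

    def test_excessive_overlap_rejected(self):
        # overlap 101 > 20% of the 321-residue span
        a, b = part("n", 1, 300), part("c", 200, 520)
        assert evaluate_split_join(a, b, None, None) is None

    def test_low_combined_coverage_rejected(self):
        a, b = part("n", 1, 300), part("c", 600, 660)
        assert evaluate_split_join(a, b, None, None) is None

    def test_insufficient_margin_over_other_rejected(self):
        a, b = part("n", 1, 520), part("c", 505, 1000)
        assert evaluate_split_join(a, b, other(bits=295.0), None) is None
        assert evaluate_split_join(a, b, other(bits=290.0), None) is not None

    def test_same_protein_not_a_split(self):
        a, b = part("x", 1, 520), part("x", 505, 1000)
        assert evaluate_split_join(a, b, None, None) is None

    def test_combined_identity_is_span_weighted(self):
        a = part("n", 1, 500, identity=100.0)
        b = part("c", 501, 1000, identity=80.0)
        join = evaluate_split_join(a, b, None, None)
        assert join.percent_identity == pytest.approx(90.0)


class TestScoreStep:
    def _cand(self, tier, bits=100.0, pid="p"):
        return Candidate(
            step_id="s", parts=(pid,), origin=CandidateOrigin.BLAST,
            confidence=tier, percent_identity=50, coverage=0.9,
            bit_score=bits, subject_id="r",
        )

    def test_best_candidate_tier_wins(self):
        sr = score_step("s", [self._cand(Confidence.MEDIUM),
                              self._cand(Confidence.HIGH),
                              self._cand(Confidence.LOW)])
        assert sr.confidence == Confidence.HIGH

    def test_no_candidates_is_low_confidence(self):
        sr = score_step("s", [])
        assert sr.confidence == Confidence.LOW and sr.candidates == []

    def test_candidates_sorted_by_tier_then_bits(self):
        sr = score_step("s", [
            self._cand(Confidence.HIGH, bits=280, pid="b"),
            self._cand(Confidence.LOW, bits=500, pid="c"),
            self._cand(Confidence.HIGH, bits=310, pid="a"),
        ])
        assert [c.bit_score for c in sr.candidates] == [310, 280, 500]


class TestFusionAndSplitProperties:
    def test_planted_fusion_high_for_both_steps(self, mini_universe, mini_result):
        fus = [
            (d.pathway_id, d.step_id)
            for d in mini_universe.directives
            if d.genome_id == "G00" and d.kind == "fusion"
        ]
        assert len(fus) == 2
        for pid, sid in fus:
            assert mini_result.step_results[pid][sid].confidence == Confidence.HIGH

    def test_region_rule_is_what_rescues_fusions(self, mini_universe, mini_result):
        """Disabling the 50%-region restriction lets each half's reference
        count against the other half, demoting at least one of the pair."""
        u = mini_universe
        res2 = analyze_genome(
            "G00", u.proteomes["G00"], u.pathways, u.db,
            config=EngineConfig(min_region_overlap=0.0),
        )
        fus = [
            (d.pathway_id, d.step_id)
            for d in u.directives if d.genome_id == "G00" and d.kind == "fusion"
        ]
        demoted = sum(
            1 for pid, sid in fus
            if res2.step_results[pid][sid].confidence
            < mini_result.step_results[pid][sid].confidence
        )
        assert demoted >= 1

    def test_planted_split_reaches_intact_tier(self, mini_universe, mini_result):
        split = next(
            d for d in mini_universe.directives
            if d.genome_id == "G00" and d.kind == "split"
        )
        sr = mini_result.step_results[split.pathway_id][split.step_id]
        assert sr.confidence == Confidence.HIGH
        top = sr.candidates[0]
        assert top.origin is CandidateOrigin.SPLIT
        assert len(top.parts) == 2
        assert top.coverage >= 0.70
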