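"""Candidate construction and confidence classification.

A *candidate* is a protein from the analyzed genome (or a joined pair of
proteins) proposed to carry out a step.  Its confidence tier depends on
three axes: percent identity to the reference protein, coverage **of the
reference protein** (subject side; for HMM hits, of the model), and the
margin over the *other hit* — the best-scoring alignment of the candidate
to a characterized protein with a different function.

Other-hit computation is restricted to the candidate's *relevant region*
(the span matched by the step hit): conflicting alignments overlapping
less than half of that region are disregarded.  This is what rescues
fusion proteins — the alignment of the other half of a fusion to its own
reference does not count against the half being scored.

Classification rules (alignment-based candidates):

* HIGH — characterized subject, identity > 40%, subject coverage > 80%,
  and bit score at least 10 bits above the other hit (no other hit counts
  as satisfied).
* MEDIUM — identity > 40% and coverage > 70% (regardless of the other
  hit), or identity > 30% and coverage > 80% with a bit score strictly
  above the other hit's.
* LOW — coverage >= 50% (the search already enforced >=30% identity).

HMM-based candidates above the trusted cutoff are HIGH when model coverage
is >= 80% and the other hit is absent, under 40% identity or under 75%
coverage; otherwise MEDIUM.

Split proteins: two distinct proteins aligning to the same reference are
joined when each part clears the other hit by >= 10 bits, the subject-side
overlap of the two alignments is at most 20% of either span, and the
combined subject coverage is >= 70%.  The joined candidate replaces the
parts only if it reaches a strictly higher tier than either part alone.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .config import DEFAULT_CONFIG, EngineConfig
from .homology_search import AlignmentHit, HmmHit
from .reference_db import ProteinStatus, StepQuerySet
from .tiers import Confidence


class CandidateOrigin(enum.Enum):
    BLAST = "blast"
    HMM = "hmm"
    SPLIT = "split"


@dataclass(frozen=True)
class OtherHit:
    """Best surviving alignment to a protein with another function."""

    subject_id: str
    bit_score: float
    percent_identity: float
    subject_coverage: float


@dataclass(frozen=True)
class RelevantRegion:
    """1-based inclusive span of the candidate matched by the step hit."""

    protein_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Candidate:
    step_id: str
    parts: tuple[str, ...]  # 1 protein id, or 2 for a joined split
    origin: CandidateOrigin
    confidence: Confidence
    percent_identity: float
    coverage: float  # subject coverage (model coverage for HMM hits)
    bit_score: float
    subject_id: str
    other_hit: OtherHit | None = None
    part_hits: tuple[AlignmentHit, ...] = ()

    def sort_key(self):
        return (-self.confidence.value, -self.bit_score, self.parts)


@dataclass
class StepResult:
    step_id: str
    confidence: Confidence
    candidates: list[Candidate] = field(default_factory=list)


def find_other_hit(
    candidate_protein: str,
    region: RelevantRegion,
    step_queries: StepQuerySet,
    all_db_hits: Sequence[AlignmentHit],
    config: EngineConfig = DEFAULT_CONFIG,
) -> OtherHit | None:
    """Best-scoring conflicting hit overlapping the relevant region.

    ``all_db_hits`` are this protein's alignments against the full
    characterized database.  Hits whose subject matches the step or is in
    the step's ignore set are disregarded, as are hits whose query-side
    span overlaps less than ``config.min_region_overlap`` of the region.
    """
    if region.start < 1 or region.length < 1:
        raise ValueError(f"relevant region {region} out of bounds")
    excluded = step_queries.member_ids | step_queries.ignored
    best: OtherHit | None = None
    best_key = None
    for hit in all_db_hits:
        if hit.query_id != candidate_protein:
            continue
        if region.end > hit.query_length:
            raise ValueError(
                f"relevant region {region} outside protein of length {hit.query_length}"
            )
        if hit.subject_id in excluded:
            continue
        overlap = min(hit.q_end, region.end) - max(hit.q_start, region.start) + 1
        if overlap < config.min_region_overlap * region.length:
            continue
        key = (hit.bit_score, hit.subject_id)
        if best is None or key[0] > best_key[0] or (key[0] == best_key[0] and key[1] < best_key[1]):
            best = OtherHit(
                subject_id=hit.subject_id,
                bit_score=hit.bit_score,
                percent_identity=hit.percent_identity,
                subject_coverage=hit.subject_coverage,
            )
            best_key = key
    return best


def classify_blast_candidate(
    hit: AlignmentHit,
    subject_status: ProteinStatus,
    other: OtherHit | None,
    config: EngineConfig = DEFAULT_CONFIG,
) -> Confidence | None:
    """Tier an alignment-based candidate, or ``None`` if it fails even the
    low-confidence coverage rule.  Threshold strictness follows the rule
    text: "over 40%" is strict, "at least 50%" is inclusive."""
    identity = hit.percent_identity
    coverage = hit.subject_coverage
    if (
        subject_status is ProteinStatus.CHARACTERIZED
        and identity > config.high_identity
        and coverage > config.high_coverage
        and (other is None or hit.bit_score >= other.bit_score + config.high_bit_margin)
    ):
        return Confidence.HIGH
    if identity > config.medium_identity_strong and coverage > config.medium_coverage_strong:
        return Confidence.MEDIUM
    if (
        identity > config.medium_identity_weak
        and coverage > config.medium_coverage_weak
        and (other is None or hit.bit_score > other.bit_score)
    ):
        return Confidence.MEDIUM
    if coverage >= config.low_coverage:
        return Confidence.LOW
    return None


def classify_hmm_candidate(
    hit: HmmHit,
    other: OtherHit | None,
    config: EngineConfig = DEFAULT_CONFIG,
) -> Confidence:
    """Tier a profile-HMM candidate (already above the trusted cutoff)."""
    if hit.model_coverage >= config.hmm_high_coverage and (
        other is None
        or other.percent_identity < config.hmm_other_identity
        or other.subject_coverage < config.hmm_other_coverage
    ):
        return Confidence.HIGH
    return Confidence.MEDIUM


@dataclass(frozen=True)
class SplitJoin:
    """Combined metrics of a candidate joined from two part alignments."""

    percent_identity: float
    combined_coverage: float
    bit_score: float  # sum of part bit scores


def evaluate_split_join(
    hit_a: AlignmentHit,
    hit_b: AlignmentHit,
    other_a: OtherHit | None,
    other_b: OtherHit | None,
    config: EngineConfig = DEFAULT_CONFIG,
) -> SplitJoin | None:
    """Test whether two part alignments to one subject may be joined.

    Conditions: distinct query proteins; each part's bit score at least
    ``split_bit_margin`` above its own other hit; subject-coordinate
    overlap at most ``split_max_overlap`` of either alignment's span; and
    combined subject coverage at least ``split_min_coverage``.  Combined
    identity is the span-weighted mean of the part identities.
    """
    if hit_a.query_id == hit_b.query_id:
        return None
    if hit_a.subject_id != hit_b.subject_id:
        return None
    for hit, other in ((hit_a, other_a), (hit_b, other_b)):
        if other is not None and hit.bit_score < other.bit_score + config.split_bit_margin:
            return None
    span_a = hit_a.s_end - hit_a.s_start + 1
    span_b = hit_b.s_end - hit_b.s_start + 1
    overlap = max(0, min(hit_a.s_end, hit_b.s_end) - max(hit_a.s_start, hit_b.s_start) + 1)
    if overlap > config.split_max_overlap * span_a or overlap > config.split_max_overlap * span_b:
        return None
    union = span_a + span_b - overlap
    combined_coverage = union / hit_a.subject_length
    if combined_coverage < config.split_min_coverage:
        return None
    identity = (
        hit_a.percent_identity * span_a + hit_b.percent_identity * span_b
    ) / (span_a + span_b)
    return SplitJoin(
        percent_identity=identity,
        combined_coverage=combined_coverage,
        bit_score=hit_a.bit_score + hit_b.bit_score,
    )


def join_split_candidates(
    step_id: str,
    hit_a: AlignmentHit,
    hit_b: AlignmentHit,
    other_a: OtherHit | None,
    other_b: OtherHit | None,
    subject_status: ProteinStatus,
    part_tiers: tuple[Confidence | None, Confidence | None],
    config: EngineConfig = DEFAULT_CONFIG,
) -> Candidate | None:
    """Build a SPLIT candidate if joining succeeds *and* the joined tier
    strictly beats both parts' tiers (else the parts stand on their own)."""
    join = evaluate_split_join(hit_a, hit_b, other_a, other_b, config)
    if join is None:
        return None
    pseudo = AlignmentHit(
        query_id="+".join(sorted((hit_a.query_id, hit_b.query_id))),
        subject_id=hit_a.subject_id,
        percent_identity=join.percent_identity,
        bit_score=join.bit_score,
        e_value=min(hit_a.e_value, hit_b.e_value),
        q_start=1,
        q_end=1,
        s_start=1,
        s_end=max(1, round(join.combined_coverage * hit_a.subject_length)),
        query_length=1,
        subject_length=hit_a.subject_length,
    )
    # Both parts already cleared the +10-bit margin over their own other
    # hits, so the margin clause of the high-confidence rule is satisfied.
    tier = classify_blast_candidate(pseudo, subject_status, None, config)
    if tier is None:
        return None
    best_part = max((t for t in part_tiers if t is not None), default=None)
    if best_part is not None and tier <= best_part:
        return None
    parts = tuple(sorted((hit_a.query_id, hit_b.query_id)))
    ordered = (hit_a, hit_b) if parts[0] == hit_a.query_id else (hit_b, hit_a)
    return Candidate(
        step_id=step_id,
        parts=parts,
        origin=CandidateOrigin.SPLIT,
        confidence=tier,
        percent_identity=join.percent_identity,
        coverage=join.combined_coverage,
        bit_score=join.bit_score,
        subject_id=hit_a.subject_id,
        other_hit=max(
            (o for o in (other_a, other_b) if o is not None),
            key=lambda o: o.bit_score,
            default=None,
        ),
        part_hits=ordered,
    )


def score_step(step_id: str, candidates: Iterable[Candidate]) -> StepResult:
    """Step confidence = best candidate tier; LOW when there are no
    candidates at all (so gapped pathways still get considered)."""
    ordered = sorted(candidates, key=Candidate.sort_key)
    if not ordered:
        return StepResult(step_id=step_id, confidence=Confidence.LOW, candidates=[])
    return StepResult(step_id=step_id, confidence=ordered[0].confidence, candidates=ordered)
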