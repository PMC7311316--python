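"""Path scoring, best-path selection, and requirement warnings.

A pathway's primary score is the lowest confidence tier of any step on the
path.  Ties break on a secondary score weighting low, medium and high
confidence steps at -2, -0.1 and +1; remaining ties prefer the longer
path, then the first path in deterministic expansion order.  The secondary
score is carried as a scaled integer (weights -20, -1, +10) so 0.1
accumulation can never reorder ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .candidate_scoring import StepResult
from .pathway_model import (
    ExpandedPath,
    PathwayDefinition,
    Polarity,
    Requirement,
    expand_paths_detailed,
)
from .tiers import Confidence

# secondary-score weights, scaled x10 to stay in integers
_WEIGHT_X10 = {Confidence.LOW: -20, Confidence.MEDIUM: -1, Confidence.HIGH: 10}


@dataclass
class PathResult:
    pathway_id: str
    step_ids: tuple[str, ...]
    confidences: tuple[Confidence, ...]
    primary_confidence: Confidence
    secondary_score_x10: int
    rules_used: frozenset[str] = frozenset()

    @property
    def secondary_score(self) -> float:
        return self.secondary_score_x10 / 10.0

    @property
    def length(self) -> int:
        return len(self.step_ids)

    @property
    def gaps(self) -> list[str]:
        """Steps on this path below high confidence."""
        return [s for s, c in zip(self.step_ids, self.confidences) if c < Confidence.HIGH]


def score_path(confidences: Sequence[Confidence]) -> tuple[Confidence, float, int]:
    """(primary, secondary, length) for an ordered list of step tiers."""
    if not confidences:
        raise ValueError("cannot score an empty path")
    primary = min(confidences)
    secondary = sum(_WEIGHT_X10[c] for c in confidences)
    return primary, secondary / 10.0, len(confidences)


def _path_result(
    pathway_id: str, path: ExpandedPath, step_results: Mapping[str, StepResult]
) -> PathResult:
    confs = tuple(step_results[s].confidence for s in path.step_ids)
    return PathResult(
        pathway_id=pathway_id,
        step_ids=path.step_ids,
        confidences=confs,
        primary_confidence=min(confs),
        secondary_score_x10=sum(_WEIGHT_X10[c] for c in confs),
        rules_used=path.rules_used,
    )


def all_path_results(
    pathway: PathwayDefinition,
    step_results: Mapping[str, StepResult],
    cap: int = 10_000,
) -> list[PathResult]:
    paths = expand_paths_detailed(pathway, cap=cap)
    missing = {s for p in paths for s in p.step_ids} - set(step_results)
    if missing:
        raise KeyError(f"no step results for {sorted(missing)}")
    return [_path_result(pathway.pathway_id, p, step_results) for p in paths]


def best_path(
    pathway: PathwayDefinition,
    step_results: Mapping[str, StepResult],
    cap: int = 10_000,
) -> PathResult:
    """Select the best expanded path: maximize primary tier, then the
    secondary score, then path length; a residual tie goes to the earliest
    path in expansion order."""
    results = all_path_results(pathway, step_results, cap=cap)
    best = results[0]
    for r in results[1:]:
        if (
            r.primary_confidence.value,
            r.secondary_score_x10,
            r.length,
        ) > (
            best.primary_confidence.value,
            best.secondary_score_x10,
            best.length,
        ):
            best = r
    return best


@dataclass
class PathwayOutcome:
    pathway_id: str
    best: PathResult
    all_paths: list[PathResult]
    warnings: list[str] = field(default_factory=list)

    @property
    def gaps(self) -> list[str]:
        return self.best.gaps


@dataclass
class KnownGapFlag:
    pathway_id: str
    step_id: str
    supported_by: tuple[str, ...]  # cataloged genome ids


@dataclass
class GenomeResult:
    genome_id: str
    pathways: dict[str, PathwayOutcome]
    step_results: dict[str, dict[str, StepResult]]  # pathway -> step -> result
    warnings: list[str] = field(default_factory=list)
    known_gaps: list[KnownGapFlag] = field(default_factory=list)

    @property
    def gap_list(self) -> list[tuple[str, str]]:
        """(pathway, step) pairs on best paths below high confidence."""
        out = []
        for pid in sorted(self.pathways):
            for sid in self.pathways[pid].gaps:
                out.append((pid, sid))
        return out


def check_requirements(
    result: GenomeResult,
    pathways: Sequence[PathwayDefinition],
) -> list[str]:
    """Warnings for violated inter-pathway requirements.

    A requirement only fires when its scope (the pathway itself, or one of
    its rules) is actually used by the selected best path.  MUST_BE_PRESENT
    is violated when the required step is below medium confidence;
    MUST_NOT_BE_PRESENT when the required step lies on the best path of its
    own pathway (mutually exclusive route selections).
    """
    warnings: list[str] = []
    for defn in pathways:
        outcome = result.pathways.get(defn.pathway_id)
        if outcome is None:
            continue
        for req in defn.requirements:
            scope_active = (
                req.scope == defn.pathway_id or req.scope in outcome.best.rules_used
            )
            if not scope_active:
                continue
            target_steps = result.step_results.get(req.required_pathway, {})
            if req.required_step not in target_steps:
                warnings.append(
                    f"{defn.pathway_id}: requirement target "
                    f"{req.required_pathway}.{req.required_step} was not analyzed"
                )
                continue
            if req.polarity is Polarity.MUST_BE_PRESENT:
                conf = target_steps[req.required_step].confidence
                if conf < Confidence.MEDIUM:
                    warnings.append(
                        f"{defn.pathway_id}: requires {req.required_pathway}."
                        f"{req.required_step} (scope {req.scope}) but it is {conf}"
                    )
            else:
                other = result.pathways.get(req.required_pathway)
                if other is not None and req.required_step in other.best.step_ids:
                    warnings.append(
                        f"{defn.pathway_id}: conflicting route — scope {req.scope} "
                        f"selected together with {req.required_pathway}."
                        f"{req.required_step} on its best path"
                    )
    return warnings
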