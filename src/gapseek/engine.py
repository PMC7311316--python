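"""End-to-end genome analysis: search, score, solve, report.

The pipeline mirrors the method it implements:

1. resolve every step's matchers against the reference database;
2. search the proteome against all characterized + curated reference
   sequences (one pass; >=30% identity, E < 0.01) and against the profile
   HMMs any step requires (trusted cutoffs);
3. for every (step, protein) hit, restrict the conflicting-hit search to
   the candidate's relevant region, classify the candidate's confidence,
   and attempt split-protein joins on low-coverage hits to one reference;
4. expand each pathway's alternatives, pick the best path, list its gaps,
   and check inter-pathway requirements.

Steps are scored independently of each other — a single protein may be a
candidate for several steps (this is what makes fusion handling work).
"""

from __future__ import annotations

import itertools
import json
import pathlib
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import SeqIO

from .candidate_scoring import (
    Candidate,
    CandidateOrigin,
    OtherHit,
    RelevantRegion,
    StepResult,
    classify_blast_candidate,
    classify_hmm_candidate,
    find_other_hit,
    join_split_candidates,
    score_step,
)
from .config import DEFAULT_CONFIG, EngineConfig
from .homology_search import AlignmentHit, get_backend, search_hmms
from .path_solver import (
    GenomeResult,
    PathwayOutcome,
    all_path_results,
    best_path,
    check_requirements,
)
from .pathway_model import PathwayDefinition
from .reference_db import ProteinStatus, ReferenceDatabase, resolve_step_queries
from .tiers import Confidence

__all__ = ["analyze_genome", "read_proteome", "result_to_dict", "write_outputs"]


def read_proteome(path) -> dict[str, str]:
    """Load a protein FASTA as an ordered id -> sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate protein id {rec.id} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def _step_candidates(
    pathway_id: str,
    step_id: str,
    qs,
    proteome: Mapping[str, str],
    hits_by_query: Mapping[str, list[AlignmentHit]],
    hmm_hits_by_id: Mapping[str, list],
    status_by_id: Mapping[str, ProteinStatus],
    config: EngineConfig,
) -> list[Candidate]:
    member_ids = qs.member_ids
    candidates: list[Candidate] = []
    best_by_protein: dict[str, Candidate] = {}
    # hits of each candidate protein to the characterized database, used
    # for the conflicting-hit ("other hit") test
    def char_hits(protein: str) -> list[AlignmentHit]:
        return [
            h
            for h in hits_by_query.get(protein, [])
            if status_by_id.get(h.subject_id) is ProteinStatus.CHARACTERIZED
        ]

    step_hits: dict[str, list[AlignmentHit]] = {}
    for protein, hits in hits_by_query.items():
        relevant = [h for h in hits if h.subject_id in member_ids]
        if relevant:
            step_hits[protein] = relevant

    for protein in sorted(step_hits):
        best: Candidate | None = None
        for hit in step_hits[protein]:
            region = RelevantRegion(protein, hit.q_start, hit.q_end)
            other = find_other_hit(protein, region, qs, char_hits(protein), config)
            tier = classify_blast_candidate(
                hit, status_by_id[hit.subject_id], other, config
            )
            if tier is None:
                continue
            cand = Candidate(
                step_id=step_id,
                parts=(protein,),
                origin=CandidateOrigin.BLAST,
                confidence=tier,
                percent_identity=hit.percent_identity,
                coverage=hit.subject_coverage,
                bit_score=hit.bit_score,
                subject_id=hit.subject_id,
                other_hit=other,
            )
            if best is None or cand.sort_key() < best.sort_key():
                best = cand
        if best is not None:
            best_by_protein[protein] = best
            candidates.append(best)

    # HMM candidates
    for hmm in qs.hmms:
        for hit in hmm_hits_by_id.get(hmm.hmm_id, []):
            protein = hit.query_id
            region = RelevantRegion(protein, hit.q_start, hit.q_end)
            other = find_other_hit(protein, region, qs, char_hits(protein), config)
            tier = classify_hmm_candidate(hit, other, config)
            cand = Candidate(
                step_id=step_id,
                parts=(protein,),
                origin=CandidateOrigin.HMM,
                confidence=tier,
                percent_identity=0.0,
                coverage=hit.model_coverage,
                bit_score=hit.bit_score,
                subject_id=hit.hmm_id,
                other_hit=other,
            )
            candidates.append(cand)
            prev = best_by_protein.get(protein)
            if prev is None or cand.sort_key() < prev.sort_key():
                best_by_protein[protein] = cand

    # split-protein joining: low-coverage alignments of two different
    # proteins tiling the same reference sequence
    by_subject: dict[str, dict[str, AlignmentHit]] = {}
    for protein, hits in step_hits.items():
        for hit in hits:
            if hit.subject_coverage >= config.split_min_coverage:
                continue
            slot = by_subject.setdefault(hit.subject_id, {})
            prev = slot.get(protein)
            if prev is None or hit.bit_score > prev.bit_score:
                slot[protein] = hit
    best_join_by_pair: dict[tuple[str, str], Candidate] = {}
    for subject in sorted(by_subject):
        per_protein = by_subject[subject]
        for pa, pb in itertools.combinations(sorted(per_protein), 2):
            ha, hb = per_protein[pa], per_protein[pb]
            ra = RelevantRegion(pa, ha.q_start, ha.q_end)
            rb = RelevantRegion(pb, hb.q_start, hb.q_end)
            oa = find_other_hit(pa, ra, qs, char_hits(pa), config)
            ob = find_other_hit(pb, rb, qs, char_hits(pb), config)
            tier_a = best_by_protein[pa].confidence if pa in best_by_protein else None
            tier_b = best_by_protein[pb].confidence if pb in best_by_protein else None
            cand = join_split_candidates(
                step_id, ha, hb, oa, ob, status_by_id[subject],
                (tier_a, tier_b), config,
            )
            if cand is not None:
                prev = best_join_by_pair.get((pa, pb))
                if prev is None or cand.sort_key() < prev.sort_key():
                    best_join_by_pair[(pa, pb)] = cand
    candidates.extend(best_join_by_pair[p] for p in sorted(best_join_by_pair))
    return candidates


def analyze_genome(
    genome_id: str,
    proteome: Mapping[str, str],
    pathways: Sequence[PathwayDefinition],
    db: ReferenceDatabase,
    config: EngineConfig = DEFAULT_CONFIG,
    backend=None,
) -> GenomeResult:
    """Analyze one proteome against a pathway set and reference database."""
    if backend is None:
        backend = get_backend(config.backend)
    status_by_id = {pid: rec.status for pid, rec in db.records.items()}

    # resolve step queries once per (pathway, step)
    queries: dict[str, dict[str, object]] = {}
    query_warnings: list[str] = []
    needed_hmms: set[str] = set()
    for defn in pathways:
        queries[defn.pathway_id] = {}
        for sid, step in defn.steps.items():
            qs = resolve_step_queries(step, db)
            queries[defn.pathway_id][sid] = qs
            query_warnings.extend(f"{defn.pathway_id}: {w}" for w in qs.warnings)
            needed_hmms.update(h.hmm_id for h in qs.hmms)

    subjects = db.sequences()
    hits_by_query: dict[str, list[AlignmentHit]] = {}
    hmm_hits_by_id: dict[str, list] = {}
    if proteome and subjects:
        all_hits = backend.search(
            proteome, subjects,
            min_identity=config.min_identity, max_evalue=config.max_evalue,
        )
        for hit in all_hits:
            hits_by_query.setdefault(hit.query_id, []).append(hit)
    if proteome and needed_hmms:
        profiles = [db.hmm_profiles[h] for h in sorted(needed_hmms) if h in db.hmm_profiles]
        for hit in search_hmms(proteome, profiles):
            hmm_hits_by_id.setdefault(hit.hmm_id, []).append(hit)

    step_results: dict[str, dict[str, StepResult]] = {}
    for defn in pathways:
        step_results[defn.pathway_id] = {}
        for sid in defn.steps:
            cands = _step_candidates(
                defn.pathway_id, sid, queries[defn.pathway_id][sid],
                proteome, hits_by_query, hmm_hits_by_id, status_by_id, config,
            )
            step_results[defn.pathway_id][sid] = score_step(sid, cands)

    outcomes: dict[str, PathwayOutcome] = {}
    for defn in pathways:
        results = all_path_results(defn, step_results[defn.pathway_id], cap=config.expansion_cap)
        chosen = best_path(defn, step_results[defn.pathway_id], cap=config.expansion_cap)
        outcomes[defn.pathway_id] = PathwayOutcome(
            pathway_id=defn.pathway_id, best=chosen, all_paths=results
        )

    result = GenomeResult(
        genome_id=genome_id,
        pathways=outcomes,
        step_results=step_results,
        warnings=list(query_warnings),
    )
    result.warnings.extend(check_requirements(result, pathways))
    return result


# ---------------------------------------------------------------------------
# serialization

def _candidate_dict(c: Candidate) -> dict:
    d = {
        "parts": list(c.parts),
        "origin": c.origin.value,
        "confidence": str(c.confidence),
        "percent_identity": round(c.percent_identity, 1),
        "coverage": round(c.coverage, 3),
        "bit_score": round(c.bit_score, 1),
        "subject_id": c.subject_id,
    }
    if c.other_hit is not None:
        d["other_hit"] = {
            "subject_id": c.other_hit.subject_id,
            "bit_score": round(c.other_hit.bit_score, 1),
            "percent_identity": round(c.other_hit.percent_identity, 1),
            "coverage": round(c.other_hit.subject_coverage, 3),
        }
    return d


def result_to_dict(result: GenomeResult) -> dict:
    out = {
        "genome_id": result.genome_id,
        "pathways": {},
        "warnings": sorted(result.warnings),
        "known_gaps": [
            {
                "pathway_id": f.pathway_id,
                "step_id": f.step_id,
                "supported_by": list(f.supported_by),
            }
            for f in result.known_gaps
        ],
    }
    for pid in sorted(result.pathways):
        outcome = result.pathways[pid]
        steps = {}
        for sid in sorted(result.step_results[pid]):
            sr = result.step_results[pid][sid]
            steps[sid] = {
                "confidence": str(sr.confidence),
                "top_candidate": _candidate_dict(sr.candidates[0]) if sr.candidates else None,
                "n_candidates": len(sr.candidates),
            }
        out["pathways"][pid] = {
            "best_path": list(outcome.best.step_ids),
            "best_path_confidences": [str(c) for c in outcome.best.confidences],
            "primary_confidence": str(outcome.best.primary_confidence),
            "secondary_score": outcome.best.secondary_score,
            "n_paths": len(outcome.all_paths),
            "gaps": outcome.gaps,
            "steps": steps,
        }
    return out


def write_outputs(
    result: GenomeResult,
    out_dir,
    config: EngineConfig = DEFAULT_CONFIG,
    input_digests: Mapping[str, str] | None = None,
    timings: Mapping[str, float] | None = None,
) -> None:
    """Write results.json, candidates.tsv, summary.tsv and run_record.json.

    Result files are byte-deterministic for identical inputs and config;
    provenance (timings, version) goes to run_record.json only.
    """
    d = pathlib.Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "results.json", "w") as fh:
        json.dump(result_to_dict(result), fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(d / "candidates.tsv", "w") as fh:
        fh.write(
            "pathway_id\tstep_id\tconfidence\tparts\torigin\tpercent_identity\t"
            "coverage\tbit_score\tsubject_id\tother_subject\tother_bits\n"
        )
        for pid in sorted(result.step_results):
            for sid in sorted(result.step_results[pid]):
                for c in result.step_results[pid][sid].candidates:
                    other_s = c.other_hit.subject_id if c.other_hit else ""
                    other_b = f"{c.other_hit.bit_score:.1f}" if c.other_hit else ""
                    fh.write(
                        f"{pid}\t{sid}\t{c.confidence}\t{'+'.join(c.parts)}\t"
                        f"{c.origin.value}\t{c.percent_identity:.1f}\t"
                        f"{c.coverage:.3f}\t{c.bit_score:.1f}\t{c.subject_id}\t"
                        f"{other_s}\t{other_b}\n"
                    )
    with open(d / "summary.tsv", "w") as fh:
        fh.write("pathway_id\tprimary_confidence\tbest_path\tn_gaps\tgaps\n")
        for pid in sorted(result.pathways):
            o = result.pathways[pid]
            fh.write(
                f"{pid}\t{o.best.primary_confidence}\t{' '.join(o.best.step_ids)}\t"
                f"{len(o.gaps)}\t{' '.join(o.gaps)}\n"
            )
    from . import __version__

    record = {
        "tool_version": __version__,
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "input_digests": dict(input_digests or {}),
        "timings_s": {k: round(v, 3) for k, v in (timings or {}).items()},
        "warnings": sorted(result.warnings),
    }
    with open(d / "run_record.json", "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
        fh.write("\n")
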