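"""Marker-gene relatedness and known-gap annotation.

Some steps look missing in a genome yet the organism is known to grow in
minimal medium — the gap reflects unknown biology, not a missing
capability.  A catalog records such *known gaps* per reference organism.
When a newly analyzed genome is *related* to a cataloged organism that has
the same gap, the gap is marked as known.

Relatedness is measured on single-copy ribosomal marker proteins: for each
marker present in both genomes, the two proteins are globally aligned;
hits with >=50% identity and >=70% coverage are retained, one-to-one hits
only.  Genomes are related when there are at least 10 retained hits and
their median identity is at least 75% — roughly family-level relatedness.
"""

from __future__ import annotations

import pathlib
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pyhmmer
from Bio import SeqIO

from .config import DEFAULT_CONFIG, EngineConfig
from .homology_search import global_align_identity, load_hmms, search_hmms
from .path_solver import GenomeResult, KnownGapFlag


@dataclass
class MarkerProfile:
    """One protein per ribosomal marker; multi-hit markers are dropped."""

    genome_id: str
    domain: str  # "bacteria" | "archaea"
    markers: dict[str, tuple[str, str]]  # hmm_id -> (protein_id, sequence)


@dataclass
class KnownGapCatalog:
    entries: list[tuple[str, str, str]]  # (genome_id, pathway_id, step_id)
    profiles: dict[str, MarkerProfile]

    def __post_init__(self) -> None:
        missing = {g for g, _, _ in self.entries} - set(self.profiles)
        if missing:
            raise ValueError(f"catalog genomes without marker profiles: {sorted(missing)}")


@dataclass
class RelatednessResult:
    retained_hits: int
    median_identity: float  # 0 when no hits
    related: bool


def extract_markers(
    proteome: Mapping[str, str],
    marker_hmms: Sequence[pyhmmer.plan7.HMM],
    genome_id: str = "",
    domain: str = "bacteria",
) -> MarkerProfile:
    """Identify marker proteins by profile search above trusted cutoffs.

    A marker hit by two or more proteins is ambiguous (possible paralogy or
    contamination) and is dropped entirely.
    """
    markers: dict[str, tuple[str, str]] = {}
    if proteome:
        hits = search_hmms(proteome, marker_hmms)
        by_hmm: dict[str, list[str]] = {}
        for h in hits:
            by_hmm.setdefault(h.hmm_id, []).append(h.query_id)
        for hmm_id, prots in by_hmm.items():
            uniq = sorted(set(prots))
            if len(uniq) == 1:
                markers[hmm_id] = (uniq[0], proteome[uniq[0]])
    return MarkerProfile(genome_id=genome_id, domain=domain, markers=markers)


def relatedness(
    query: MarkerProfile,
    reference: MarkerProfile,
    config: EngineConfig = DEFAULT_CONFIG,
) -> RelatednessResult:
    """Compare two marker profiles; see module docstring for the rule.

    Profiles from different domains (bacteria vs archaea) use different
    marker sets and are reported unrelated without alignment.
    """
    if query.domain != reference.domain:
        return RelatednessResult(0, 0.0, False)
    candidate_hits: list[tuple[str, str, float]] = []  # (q_protein, r_protein, identity)
    for hmm_id in sorted(set(query.markers) & set(reference.markers)):
        q_id, q_seq = query.markers[hmm_id]
        r_id, r_seq = reference.markers[hmm_id]
        ga = global_align_identity(q_seq, r_seq)
        if (
            ga.percent_identity >= config.related_min_identity
            and ga.coverage >= config.related_min_coverage
        ):
            candidate_hits.append((q_id, r_id, ga.percent_identity))
    # one-to-one filter: a protein participating in more than one hit
    # invalidates all of its hits
    from collections import Counter

    q_count = Counter(h[0] for h in candidate_hits)
    r_count = Counter(h[1] for h in candidate_hits)
    retained = [
        h for h in candidate_hits if q_count[h[0]] == 1 and r_count[h[1]] == 1
    ]
    if not retained:
        return RelatednessResult(0, 0.0, False)
    median = float(statistics.median(h[2] for h in retained))
    related = (
        len(retained) >= config.related_min_hits
        and median >= config.related_min_median
    )
    return RelatednessResult(len(retained), median, related)


def mark_known_gaps(
    result: GenomeResult,
    catalog: KnownGapCatalog,
    query_profile: MarkerProfile,
    config: EngineConfig = DEFAULT_CONFIG,
) -> GenomeResult:
    """Flag gaps on best paths that a related cataloged organism shares.

    Mutates and returns ``result``; each flag carries the supporting
    cataloged genome id(s), sorted.
    """
    related_genomes = [
        gid
        for gid in sorted(catalog.profiles)
        if relatedness(query_profile, catalog.profiles[gid], config).related
    ]
    entry_set = {(g, p, s) for g, p, s in catalog.entries}
    flags: list[KnownGapFlag] = []
    for pathway_id, step_id in result.gap_list:
        support = tuple(
            g for g in related_genomes if (g, pathway_id, step_id) in entry_set
        )
        if support:
            flags.append(KnownGapFlag(pathway_id, step_id, support))
    result.known_gaps = flags
    return result


# ---------------------------------------------------------------------------
# catalog persistence: known_gaps.tsv + markers/<genome>.faa + marker hmms

def write_catalog(catalog: KnownGapCatalog, directory) -> None:
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "known_gaps.tsv", "w") as fh:
        fh.write("genome_id\tpathway_id\tstep_id\n")
        for g, p, s in sorted(catalog.entries):
            fh.write(f"{g}\t{p}\t{s}\n")
    md = d / "markers"
    md.mkdir(exist_ok=True)
    for gid in sorted(catalog.profiles):
        prof = catalog.profiles[gid]
        with open(md / f"{gid}.faa", "w") as fh:
            for hmm_id in sorted(prof.markers):
                pid, seq = prof.markers[hmm_id]
                fh.write(f">{hmm_id}|{pid} domain={prof.domain}\n{seq}\n")


def read_catalog(directory) -> KnownGapCatalog:
    d = pathlib.Path(directory)
    tsv = d / "known_gaps.tsv"
    if not tsv.exists():
        raise FileNotFoundError(f"no known_gaps.tsv in {d}")
    entries: list[tuple[str, str, str]] = []
    with open(tsv) as fh:
        fh.readline()
        for line in fh:
            g, p, s = line.rstrip("\n").split("\t")
            entries.append((g, p, s))
    profiles: dict[str, MarkerProfile] = {}
    for faa in sorted((d / "markers").glob("*.faa")):
        gid = faa.stem
        markers: dict[str, tuple[str, str]] = {}
        domain = "bacteria"
        for rec in SeqIO.parse(str(faa), "fasta"):
            hmm_id, pid = rec.id.split("|", 1)
            for tok in rec.description.split():
                if tok.startswith("domain="):
                    domain = tok.split("=", 1)[1]
            markers[hmm_id] = (pid, str(rec.seq))
        profiles[gid] = MarkerProfile(genome_id=gid, domain=domain, markers=markers)
    return KnownGapCatalog(entries=entries, profiles=profiles)
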