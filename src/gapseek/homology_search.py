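"""Protein-vs-protein and protein-vs-profile homology search.

This module defines the search contract used by the rest of the engine:

* :func:`search_proteins` — local alignment of every query against every
  subject, returning only hits with at least ``min_identity`` percent
  identity and an E-value below ``max_evalue`` (defaults 30% / 0.01).
* :func:`search_hmms` — profile-HMM search; only hits at or above each
  model's curator-set trusted cutoff are returned.
* :func:`global_align_identity` — end-to-end alignment identity, used for
  marker-gene relatedness and for fixture verification.

Two interchangeable protein-search backends satisfy the same contract: a
built-in Smith–Waterman scorer (BLOSUM62, affine 11/1 gaps, Karlin–Altschul
style bit scores and E-values) that keeps the test suite self-contained and
deterministic, and an adapter around NCBI ``blastp`` for realistic-scale
use.  Hit ordering is deterministic everywhere: by query id, then
descending bit score, then subject id.

Percent identity is computed over alignment columns (internal gap columns
included in the denominator); coverage of a sequence is the aligned span
divided by its full length.  For global alignments, terminal gap columns
are excluded from the identity denominator.
"""

from __future__ import annotations

import math
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pyhmmer
from Bio import Align
from Bio.Align import substitution_matrices

# Gapped Karlin-Altschul parameters for BLOSUM62 with 11/1 affine gaps.
_KA_LAMBDA = 0.267
_KA_K = 0.041
_LN2 = math.log(2.0)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class AlignmentHit:
    """One local pairwise alignment passing the search thresholds.

    Coordinates are 1-based inclusive.  ``subject_coverage`` (the fraction
    of the subject spanned by the alignment) is the coverage axis used by
    every confidence rule.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    bit_score: float
    e_value: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    query_length: int
    subject_length: int

    @property
    def subject_coverage(self) -> float:
        return (self.s_end - self.s_start + 1) / self.subject_length

    @property
    def query_coverage(self) -> float:
        return (self.q_end - self.q_start + 1) / self.query_length


@dataclass(frozen=True)
class HmmHit:
    """One profile-HMM hit at or above the model's trusted cutoff."""

    query_id: str
    hmm_id: str
    bit_score: float
    q_start: int
    q_end: int
    hmm_start: int
    hmm_end: int
    model_length: int

    @property
    def model_coverage(self) -> float:
        return (self.hmm_end - self.hmm_start + 1) / self.model_length


@dataclass(frozen=True)
class GlobalAlignment:
    """Identity/coverage summary of an end-to-end alignment."""

    percent_identity: float
    coverage: float  # min of the two per-sequence aligned-span fractions


class BackendUnavailableError(RuntimeError):
    """Raised when a requested search backend cannot run."""


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = mode
    return aligner


def _alignment_stats(a: str, b: str, alignment) -> tuple[int, int, int, int, int, int, int]:
    """Return (identities, ncols, qs, qe, ss, se, internal_gaps) for one
    alignment, coordinates 1-based inclusive over the aligned span and gap
    columns counted only inside that span."""
    q_blocks, s_blocks = alignment.aligned
    if len(q_blocks) == 0:
        raise ValueError("empty alignment")
    identities = 0
    matched = 0
    for (qb, qe), (sb, se) in zip(q_blocks, s_blocks):
        matched += qe - qb
        for i in range(qe - qb):
            if a[qb + i] == b[sb + i]:
                identities += 1
    qs, qe = int(q_blocks[0][0]), int(q_blocks[-1][1])
    ss, se = int(s_blocks[0][0]), int(s_blocks[-1][1])
    span_q = qe - qs
    span_s = se - ss
    gaps = (span_q - matched) + (span_s - matched)
    ncols = matched + gaps
    return identities, ncols, qs + 1, qe, ss + 1, se, gaps


class BuiltinAligner:
    """Deterministic all-vs-all Smith–Waterman search backend.

    Scores with BLOSUM62 and affine 11/1 gaps; converts raw scores to bits
    with fixed Karlin–Altschul parameters and reports a size-scaled
    E-value ``E = m * n * 2**(-bits)``.  The calibration is conventional
    rather than load-bearing: callers assert threshold classifications on
    clearly separated inputs.
    """

    name = "builtin"

    def __init__(self) -> None:
        self._aligner = _make_aligner("local")

    def _align_pair(self, qid: str, q: str, sid: str, s: str) -> AlignmentHit | None:
        alignments = self._aligner.align(q, s)
        try:
            best = alignments[0]
        except IndexError:
            return None
        if best.score <= 0:
            return None
        try:
            ident, ncols, qs, qe, ss, se, _ = _alignment_stats(q, s, best)
        except ValueError:
            return None
        bits = (_KA_LAMBDA * best.score - math.log(_KA_K)) / _LN2
        evalue = len(q) * len(s) * math.pow(2.0, -bits) if bits < 500 else 0.0
        return AlignmentHit(
            query_id=qid,
            subject_id=sid,
            percent_identity=float(100.0 * ident / ncols),
            bit_score=round(bits, 1),
            e_value=evalue,
            q_start=qs,
            q_end=qe,
            s_start=ss,
            s_end=se,
            query_length=len(q),
            subject_length=len(s),
        )

    def search(
        self,
        queries: Mapping[str, str],
        subjects: Mapping[str, str],
        min_identity: float = 30.0,
        max_evalue: float = 0.01,
    ) -> list[AlignmentHit]:
        hits: list[AlignmentHit] = []
        for qid, q in queries.items():
            for sid, s in subjects.items():
                hit = self._align_pair(qid, q, sid, s)
                if hit is None:
                    continue
                if hit.percent_identity >= min_identity and hit.e_value < max_evalue:
                    hits.append(hit)
        hits.sort(key=lambda h: (h.query_id, -h.bit_score, h.subject_id))
        return hits


class BlastBackend:
    """Adapter around NCBI ``blastp`` satisfying the same search contract."""

    name = "blastp"

    def __init__(self, blastp: str = "blastp", makeblastdb: str = "makeblastdb") -> None:
        self.blastp = blastp
        self.makeblastdb = makeblastdb
        if shutil.which(blastp) is None or shutil.which(makeblastdb) is None:
            raise BackendUnavailableError(
                f"external backend '{self.name}' unavailable: "
                f"{blastp}/{makeblastdb} not on PATH"
            )

    def search(
        self,
        queries: Mapping[str, str],
        subjects: Mapping[str, str],
        min_identity: float = 30.0,
        max_evalue: float = 0.01,
    ) -> list[AlignmentHit]:
        with tempfile.TemporaryDirectory() as tmp:
            qpath = os.path.join(tmp, "q.faa")
            spath = os.path.join(tmp, "s.faa")
            for path, seqs in ((qpath, queries), (spath, subjects)):
                with open(path, "w") as fh:
                    for sid, seq in seqs.items():
                        fh.write(f">{sid}\n{seq}\n")
            subprocess.run(
                [self.makeblastdb, "-in", spath, "-dbtype", "prot"],
                check=True, capture_output=True,
            )
            fields = (
                "qseqid sseqid pident bitscore evalue "
                "qstart qend sstart send qlen slen"
            )
            proc = subprocess.run(
                [
                    self.blastp, "-query", qpath, "-db", spath,
                    "-outfmt", f"6 {fields}", "-evalue", str(max_evalue),
                    "-max_target_seqs", "500", "-num_threads", "1",
                ],
                check=True, capture_output=True, text=True,
            )
        best: dict[tuple[str, str], AlignmentHit] = {}
        for line in proc.stdout.splitlines():
            f = line.rstrip("\n").split("\t")
            hit = AlignmentHit(
                query_id=f[0], subject_id=f[1],
                percent_identity=float(f[2]), bit_score=float(f[3]),
                e_value=float(f[4]),
                q_start=int(f[5]), q_end=int(f[6]),
                s_start=int(f[7]), s_end=int(f[8]),
                query_length=int(f[9]), subject_length=int(f[10]),
            )
            if hit.percent_identity < min_identity or hit.e_value >= max_evalue:
                continue
            key = (hit.query_id, hit.subject_id)
            if key not in best or hit.bit_score > best[key].bit_score:
                best[key] = hit
        hits = sorted(best.values(), key=lambda h: (h.query_id, -h.bit_score, h.subject_id))
        return hits


def get_backend(name: str):
    if name == "builtin":
        return BuiltinAligner()
    if name in ("blastp", "blast"):
        return BlastBackend()
    raise BackendUnavailableError(f"unknown search backend '{name}'")


def search_proteins(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    min_identity: float = 30.0,
    max_evalue: float = 0.01,
    backend=None,
) -> list[AlignmentHit]:
    """Search every query against every subject.

    Every returned hit satisfies ``percent_identity >= min_identity`` and
    ``e_value < max_evalue``.  Raises ``ValueError`` on an empty query or
    subject set (an empty search is almost always a caller bug).
    """
    if not queries:
        raise ValueError("empty query set")
    if not subjects:
        raise ValueError("empty subject set")
    if backend is None:
        backend = BuiltinAligner()
    return backend.search(queries, subjects, min_identity=min_identity, max_evalue=max_evalue)


# ---------------------------------------------------------------------------
# profile HMMs

_ALPHABET = pyhmmer.easel.Alphabet.amino()


def load_hmms(paths: Iterable) -> list[pyhmmer.plan7.HMM]:
    """Read HMMER3 profiles; every profile must carry a trusted cutoff."""
    hmms: list[pyhmmer.plan7.HMM] = []
    for path in paths:
        with pyhmmer.plan7.HMMFile(str(path)) as fh:
            for hmm in fh:
                if hmm.cutoffs.trusted is None:
                    name = hmm.name
                    name = name.decode() if isinstance(name, bytes) else str(name)
                    raise ValueError(
                        f"profile {name} in {path} has no trusted cutoff (TC line)"
                    )
                hmms.append(hmm)
    return hmms


def search_hmms(
    queries: Mapping[str, str],
    hmms: Sequence[pyhmmer.plan7.HMM],
) -> list[HmmHit]:
    """Search sequences with profiles, keeping hits at/above trusted cutoffs.

    One hit is reported per (query, profile) pair: the best-scoring domain
    supplies the coordinates, the full-sequence score the bit score.
    """
    if not hmms:
        return []
    for hmm in hmms:
        if hmm.cutoffs.trusted is None:
            raise ValueError(f"profile {hmm.name.decode()} has no trusted cutoff")
    digital = [
        pyhmmer.easel.TextSequence(name=qid.encode(), sequence=seq).digitize(_ALPHABET)
        for qid, seq in queries.items()
    ]
    out: list[HmmHit] = []
    for top_hits in pyhmmer.hmmsearch(hmms, digital, bit_cutoffs="trusted", cpus=1):
        name = top_hits.query.name
        hmm_name = name.decode() if isinstance(name, bytes) else str(name)
        model_length = top_hits.query.M
        for hit in top_hits:
            if not hit.included:
                continue
            dom = max(hit.domains, key=lambda d: d.score)
            ali = dom.alignment
            hname = hit.name
            out.append(
                HmmHit(
                    query_id=hname.decode() if isinstance(hname, bytes) else str(hname),
                    hmm_id=hmm_name,
                    bit_score=round(hit.score, 1),
                    q_start=dom.env_from,
                    q_end=dom.env_to,
                    hmm_start=ali.hmm_from,
                    hmm_end=ali.hmm_to,
                    model_length=model_length,
                )
            )
    out.sort(key=lambda h: (h.query_id, -h.bit_score, h.hmm_id))
    return out


# ---------------------------------------------------------------------------
# global alignment

_GLOBAL_ALIGNER = _make_aligner("global")


def global_align_identity(a: str, b: str) -> GlobalAlignment:
    """End-to-end alignment identity and coverage of two sequences.

    Identity is computed over alignment columns excluding terminal gaps;
    coverage is the smaller of the two aligned-span fractions.  Symmetric
    in its arguments.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    best = _GLOBAL_ALIGNER.align(a, b)[0]
    ident, ncols, qs, qe, ss, se, _ = _alignment_stats(a, b, best)
    cov_a = (qe - qs + 1) / len(a)
    cov_b = (se - ss + 1) / len(b)
    return GlobalAlignment(
        percent_identity=float(100.0 * ident / ncols),
        coverage=float(min(cov_a, cov_b)),
    )
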