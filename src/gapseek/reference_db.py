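"""Reference database of characterized/curated proteins and profile HMMs.

Two pools of reference sequences back the engine.  *Characterized* proteins
have experimental evidence for their function and are the only basis for
high-confidence calls.  *Curated-only* proteins carry curated enzyme
annotations without experimental evidence; they can support at most medium
confidence.  Profile HMMs (with curator trusted cutoffs) describe protein
families.

On disk a database directory holds ``proteins.faa`` (all sequences),
``proteins.tsv`` (protein_id, status, source_db, ec_numbers, description)
and ``hmms/*.hmm`` (HMMER3 text profiles with TC lines).
"""

from __future__ import annotations

import enum
import pathlib
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .homology_search import global_align_identity, load_hmms
from .pathway_model import Matcher, MatcherKind, StepDefinition

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class ProteinStatus(enum.Enum):
    CHARACTERIZED = "characterized"
    CURATED_ONLY = "curated_only"


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str
    description: str
    ec_numbers: tuple[str, ...]
    status: ProteinStatus
    source_db: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence.upper()) - _VALID_AA
        if bad:
            raise ValueError(f"{self.protein_id}: invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class HMMRecord:
    hmm_id: str
    model_length: int
    trusted_cutoff: float
    ec_numbers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.model_length < 1:
            raise ValueError(f"{self.hmm_id}: model_length must be >= 1")
        if not (self.trusted_cutoff == self.trusted_cutoff and abs(self.trusted_cutoff) < float("inf")):
            raise ValueError(f"{self.hmm_id}: trusted cutoff must be finite")


@dataclass
class StepQuerySet:
    """The concrete reference objects a step's matchers resolve to."""

    step_id: str
    characterized: list[ProteinRecord] = field(default_factory=list)
    curated_only: list[ProteinRecord] = field(default_factory=list)
    hmms: list[HMMRecord] = field(default_factory=list)
    ignored: set[str] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    @property
    def member_ids(self) -> set[str]:
        return {r.protein_id for r in self.characterized} | {
            r.protein_id for r in self.curated_only
        }


# ---------------------------------------------------------------------------
# description filters

_UNCHAR_PATTERNS = [
    re.compile(r"^uncharacterized", re.I),
    re.compile(r"^uncharacterized protein$", re.I),
    re.compile(r"^DUF\d+ family protein$", re.I),
    re.compile(r"^PF\d+ family protein$", re.I),
    re.compile(r"^UPF\d+ family protein$", re.I),
]
_PUTATIVE_SOURCES = {"ecocyc", "charprotdb"}
_PROBABLY_SOURCES = {"charprotdb"}
_PUTATIVE_RE = re.compile(r"^(putative|protein)\b", re.I)
_PROBABLY_RE = re.compile(r"^probably\b", re.I)


def is_uncharacterized(description: str, source_db: str) -> bool:
    """Description-based filter for records with no usable annotation.

    Removes descriptions beginning with "uncharacterized" or matching the
    family-placeholder patterns ("uncharacterized protein", "DUFnnnn family
    protein", "PFnnnnn family protein", "UPFnnnnn family protein").  For
    EcoCyc and CharProtDB sources, descriptions beginning with "putative"
    or "protein" are also removed; for CharProtDB, "probably" as well.
    All matching is case-insensitive.
    """
    desc = description.strip()
    for pat in _UNCHAR_PATTERNS:
        if pat.search(desc):
            return True
    src = source_db.lower()
    if src in _PUTATIVE_SOURCES and _PUTATIVE_RE.search(desc):
        return True
    if src in _PROBABLY_SOURCES and _PROBABLY_RE.search(desc):
        return True
    return False


def filter_uncharacterized(
    records: Iterable[ProteinRecord], source_db: str | None = None
) -> list[ProteinRecord]:
    """Drop records whose descriptions mark them as uncharacterized.

    ``source_db`` overrides each record's own source when given (useful
    when filtering a batch known to come from one source database).
    """
    return [
        r for r in records
        if not is_uncharacterized(r.description, source_db or r.source_db)
    ]


# ---------------------------------------------------------------------------
# curated-subset construction

def build_curated_subset(
    records: Sequence[ProteinRecord], cluster_identity: float = 0.60
) -> list[ProteinRecord]:
    """Greedy centroid clustering at ``cluster_identity`` global identity,
    splitting EC-heterogeneous clusters, one representative per cluster.

    Records are visited longest-first (ties by protein_id) so centroids are
    deterministic; a record joins the first centroid it matches at or above
    the identity threshold.  Clusters whose members carry different EC
    assignments are split by EC tuple.  The representative of each final
    cluster is the member with the lexicographically smallest protein_id.
    """
    if not records:
        return []
    for r in records:
        if not r.ec_numbers:
            raise ValueError(f"{r.protein_id}: curated subset requires EC annotations")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.protein_id))
    centroids: list[ProteinRecord] = []
    clusters: dict[str, list[ProteinRecord]] = {}
    for rec in ordered:
        home = None
        for cen in centroids:
            ga = global_align_identity(rec.sequence, cen.sequence)
            if ga.percent_identity >= 100.0 * cluster_identity:
                home = cen
                break
        if home is None:
            centroids.append(rec)
            clusters[rec.protein_id] = [rec]
        else:
            clusters[home.protein_id].append(rec)

    representatives: list[ProteinRecord] = []
    for members in clusters.values():
        by_ec: dict[tuple[str, ...], list[ProteinRecord]] = {}
        for m in members:
            by_ec.setdefault(tuple(sorted(m.ec_numbers)), []).append(m)
        for sub in by_ec.values():
            representatives.append(min(sub, key=lambda r: r.protein_id))
    representatives.sort(key=lambda r: r.protein_id)
    return representatives


# ---------------------------------------------------------------------------
# matcher resolution

def ec_matches(pattern: str, ec: str) -> bool:
    """Component-wise EC comparison; '-' or a missing trailing component in
    either side matches any completion."""
    pp = pattern.split(".")
    ep = ec.split(".")
    for a, b in zip(pp, ep):
        if a in ("-", "") or b in ("-", ""):
            continue
        if a != b:
            return False
    return True


def term_matches(term: str, description: str) -> bool:
    """Case-insensitive term match with both ends at word boundaries.

    A word boundary is a transition between ``[A-Za-z0-9]`` and any other
    character or the string edge, so "hisF" matches "... subunit HisF" but
    not "HisFG fusion".
    """
    pattern = r"(?<![A-Za-z0-9])" + re.escape(term) + r"(?![A-Za-z0-9])"
    return re.search(pattern, description, re.IGNORECASE) is not None


class ReferenceDatabase:
    """In-memory reference database; see module docstring for disk layout."""

    def __init__(
        self,
        records: Sequence[ProteinRecord],
        hmm_records: Sequence[HMMRecord] = (),
        hmm_profiles: Mapping[str, object] | None = None,
    ) -> None:
        self.records: dict[str, ProteinRecord] = {}
        for r in records:
            if r.protein_id in self.records:
                raise ValueError(f"duplicate protein id {r.protein_id}")
            self.records[r.protein_id] = r
        self.hmm_records: dict[str, HMMRecord] = {h.hmm_id: h for h in hmm_records}
        # hmm_id -> pyhmmer.plan7.HMM, when profiles are available
        self.hmm_profiles = dict(hmm_profiles or {})

    @property
    def characterized(self) -> list[ProteinRecord]:
        return [r for r in self.records.values() if r.status is ProteinStatus.CHARACTERIZED]

    @property
    def curated_only(self) -> list[ProteinRecord]:
        return [r for r in self.records.values() if r.status is ProteinStatus.CURATED_ONLY]

    def sequences(self, status: ProteinStatus | None = None) -> dict[str, str]:
        return {
            r.protein_id: r.sequence
            for r in self.records.values()
            if status is None or r.status is status
        }

    # -- persistence --------------------------------------------------------

    def write(self, directory) -> None:
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "proteins.faa", "w") as fh:
            for pid in sorted(self.records):
                fh.write(f">{pid}\n{self.records[pid].sequence}\n")
        with open(d / "proteins.tsv", "w") as fh:
            fh.write("protein_id\tstatus\tsource_db\tec_numbers\tdescription\n")
            for pid in sorted(self.records):
                r = self.records[pid]
                fh.write(
                    f"{pid}\t{r.status.value}\t{r.source_db}\t"
                    f"{','.join(r.ec_numbers)}\t{r.description}\n"
                )
        if self.hmm_profiles:
            hd = d / "hmms"
            hd.mkdir(exist_ok=True)
            for hid in sorted(self.hmm_profiles):
                with open(hd / f"{hid}.hmm", "wb") as fh:
                    self.hmm_profiles[hid].write(fh)
            with open(d / "hmms.tsv", "w") as fh:
                fh.write("hmm_id\tmodel_length\ttrusted_cutoff\tec_numbers\n")
                for hid in sorted(self.hmm_records):
                    h = self.hmm_records[hid]
                    fh.write(
                        f"{hid}\t{h.model_length}\t{h.trusted_cutoff}\t"
                        f"{','.join(h.ec_numbers)}\n"
                    )

    @classmethod
    def read(cls, directory) -> "ReferenceDatabase":
        d = pathlib.Path(directory)
        faa, tsv = d / "proteins.faa", d / "proteins.tsv"
        if not faa.exists() or not tsv.exists():
            raise FileNotFoundError(
                f"reference database at {d} must contain proteins.faa and proteins.tsv"
            )
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(faa), "fasta")}
        records = []
        with open(tsv) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                pid = row["protein_id"]
                if pid not in seqs:
                    raise ValueError(f"{pid} in proteins.tsv but not in proteins.faa")
                records.append(
                    ProteinRecord(
                        protein_id=pid,
                        sequence=seqs[pid],
                        description=row["description"],
                        ec_numbers=tuple(e for e in row["ec_numbers"].split(",") if e),
                        status=ProteinStatus(row["status"]),
                        source_db=row["source_db"],
                    )
                )
        hmm_records: list[HMMRecord] = []
        profiles: dict[str, object] = {}
        hmm_dir = d / "hmms"
        if hmm_dir.is_dir():
            ec_by_id: dict[str, tuple[str, ...]] = {}
            meta = d / "hmms.tsv"
            if meta.exists():
                with open(meta) as fh:
                    hdr = fh.readline().rstrip("\n").split("\t")
                    for line in fh:
                        row = dict(zip(hdr, line.rstrip("\n").split("\t")))
                        ec_by_id[row["hmm_id"]] = tuple(
                            e for e in row["ec_numbers"].split(",") if e
                        )
            for hmm in load_hmms(sorted(hmm_dir.glob("*.hmm"))):
                name = hmm.name
                hid = name.decode() if isinstance(name, bytes) else str(name)
                profiles[hid] = hmm
                hmm_records.append(
                    HMMRecord(
                        hmm_id=hid,
                        model_length=hmm.M,
                        trusted_cutoff=float(hmm.cutoffs.trusted[0]),
                        ec_numbers=ec_by_id.get(hid, ()),
                    )
                )
        return cls(records, hmm_records, profiles)


def resolve_step_queries(step: StepDefinition, db: ReferenceDatabase) -> StepQuerySet:
    """Resolve a step's matchers against the database.

    EC matchers select records (and HMMs) annotated with the EC; term
    matchers select records whose description contains the term at word
    boundaries; curated/uniprot matchers select by id; hmm matchers select
    profiles by id.  Ignore matchers populate the ignored id set — hits to
    those proteins are disregarded when looking for conflicting functions.
    A matcher selecting nothing yields a warning, not an error.  Pure
    function of (step, db).
    """
    qs = StepQuerySet(step_id=step.step_id)
    seen: set[str] = set()

    def select(matcher: Matcher) -> list[str]:
        ids: list[str] = []
        if matcher.kind is MatcherKind.EC:
            for pid in sorted(db.records):
                if any(ec_matches(matcher.value, ec) for ec in db.records[pid].ec_numbers):
                    ids.append(pid)
        elif matcher.kind is MatcherKind.TERM:
            for pid in sorted(db.records):
                if term_matches(matcher.value, db.records[pid].description):
                    ids.append(pid)
        elif matcher.kind in (MatcherKind.CURATED_ID, MatcherKind.UNIPROT):
            if matcher.value in db.records:
                ids.append(matcher.value)
        return ids

    for matcher in step.matchers:
        if matcher.kind is MatcherKind.HMM:
            if matcher.value in db.hmm_records:
                qs.hmms.append(db.hmm_records[matcher.value])
            else:
                qs.warnings.append(
                    f"step {step.step_id}: hmm matcher {matcher.value!r} selects nothing"
                )
            continue
        ids = select(matcher)
        if matcher.kind is MatcherKind.EC:
            for hid in sorted(db.hmm_records):
                if any(ec_matches(matcher.value, ec) for ec in db.hmm_records[hid].ec_numbers):
                    if all(h.hmm_id != hid for h in qs.hmms):
                        qs.hmms.append(db.hmm_records[hid])
        if not ids and matcher.kind is not MatcherKind.EC:
            qs.warnings.append(
                f"step {step.step_id}: matcher {matcher.to_text()} selects nothing"
            )
        for pid in ids:
            if pid in seen:
                continue
            seen.add(pid)
            rec = db.records[pid]
            if rec.status is ProteinStatus.CHARACTERIZED:
                qs.characterized.append(rec)
            else:
                qs.curated_only.append(rec)

    for matcher in step.ignore:
        if matcher.kind is MatcherKind.HMM:
            continue
        for pid in select(matcher):
            qs.ignored.add(pid)
    return qs
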