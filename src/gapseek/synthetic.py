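"""Synthetic test universes with a known answer key.

Generates every input the engine consumes — reference database, pathway
definitions, proteomes with planted orthologs/fusions/splits/decoys, toy
ribosomal-marker profiles, a known-gap catalog — at toy scale, with
controlled sequence identities and an engine-independent answer key.

Planting directives and the tiers they force
--------------------------------------------
* ``ortholog`` at >40% identity, full length -> HIGH confidence;
  at 30-40% identity -> MEDIUM (weak rule: >30% identity, >80% coverage).
* ``fusion`` concatenates the reference proteins of two steps into one
  genome protein -> HIGH for both steps (the region rule shields each
  half from the other's reference).
* ``split`` bisects one reference into two genome proteins at a
  breakpoint fraction in (0.3, 0.7) -> joined, HIGH (the tier the intact
  protein would get).
* ``decoy`` plants an ortholog at ~45% identity *and* adds a
  characterized other-function protein nearly identical to the genome
  protein -> the +10-bit margin fails, the candidate lands on MEDIUM.
* ``absent`` plants nothing -> the step is LOW (no candidates at all).

Background sequences are i.i.d. uniform over the 20 amino acids;
mutations are substitution-only so identity and coverage vary
independently.  Everything derives from one integer seed; the same seed
yields byte-identical fixture files.
"""

from __future__ import annotations

import dataclasses
import datetime
import itertools
import pathlib
import statistics
from dataclasses import dataclass, field

import numpy as np
import pyhmmer

from .homology_search import AMINO_ACIDS, BuiltinAligner, global_align_identity
from .known_gaps import KnownGapCatalog, MarkerProfile, write_catalog
from .pathway_model import PathwayDefinition, parse_pathway_file
from .reference_db import ProteinRecord, ProteinStatus, ReferenceDatabase
from .tiers import Confidence

_ALPHABET = pyhmmer.easel.Alphabet.amino()
_EPOCH = datetime.datetime(2020, 1, 1)

# identity targets (fractions) for each directive kind
HIGH_IDENTITY = 0.75
MEDIUM_IDENTITY = 0.34
DECOY_IDENTITY = 0.45


@dataclass(frozen=True)
class PlantDirective:
    genome_id: str
    pathway_id: str
    step_id: str
    kind: str  # ortholog | fusion | split | decoy | absent
    identity: float = 1.0
    partner_pathway: str = ""
    partner_step: str = ""
    breakpoint: float = 0.5

    def __post_init__(self) -> None:
        if self.kind == "ortholog" and not 0.15 <= self.identity <= 1.0:
            raise ValueError(f"identity target {self.identity} outside [0.15, 1.0]")
        if self.kind == "split" and not 0.2 < self.breakpoint < 0.8:
            raise ValueError(f"breakpoint {self.breakpoint} outside (0.2, 0.8)")


@dataclass
class FixtureSpec:
    seed: int
    genome_count: int = 5
    marker_count: int = 12
    # per-genome marker identity targets relative to the shared ancestral set
    marker_identities: tuple[float, ...] = (1.0, 0.95, 0.85, 0.60, 0.95)
    n_background: int = 4
    directives: list[PlantDirective] | None = None  # None -> seeded random plan


@dataclass
class AnswerKey:
    """Expected outcomes, derived from the directives and the documented
    rules without running the engine."""

    # genome -> (pathway, step) -> tier
    step_tiers: dict[str, dict[tuple[str, str], Confidence]] = field(default_factory=dict)
    # genome -> pathway -> expected best path
    best_paths: dict[str, dict[str, tuple[str, ...]]] = field(default_factory=dict)
    # genome -> [(pathway, step)] on best paths, below HIGH
    gaps: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    # (genome_a, genome_b) -> expected related?
    relatedness: dict[tuple[str, str], bool] = field(default_factory=dict)
    # genome -> [(pathway, step, supporting genomes)]
    known_gaps: dict[str, list[tuple[str, str, tuple[str, ...]]]] = field(default_factory=dict)
    # realized identities of planted orthologs: (genome, pathway, step) -> %
    realized_identities: dict[tuple[str, str, str], float] = field(default_factory=dict)


@dataclass
class Universe:
    spec: FixtureSpec
    db: ReferenceDatabase
    pathways: list[PathwayDefinition]
    pathway_texts: dict[str, str]
    proteomes: dict[str, dict[str, str]]
    marker_hmms: list
    marker_profiles: dict[str, MarkerProfile]
    catalog: KnownGapCatalog | None
    key: AnswerKey
    directives: list[PlantDirective]


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def mutate_to_identity(
    seq: str,
    target: float,
    rng: np.random.Generator,
    tolerance: float = 3.0,
    max_attempts: int = 80,
) -> tuple[str, float]:
    """Substitution-only mutant whose realized global-alignment identity is
    within ``tolerance`` points of ``100 * target``.

    Returns (mutant, realized identity in percent).  Raises ``ValueError``
    on targets outside [0.15, 1.0] or sequences shorter than 100 residues,
    and ``RuntimeError`` if the target is unreachable within the attempt
    budget.
    """
    if not 0.15 <= target <= 1.0:
        raise ValueError(f"identity target {target} outside [0.15, 1.0]")
    if len(seq) < 100:
        raise ValueError("sequence too short to mutate controllably (< 100 aa)")
    if target >= 1.0:
        return seq, 100.0
    n = len(seq)
    goal = 100.0 * target
    k = int(round((1.0 - target) * n))
    for _ in range(max_attempts):
        k = max(1, min(n, k))
        positions = rng.choice(n, size=k, replace=False)
        arr = list(seq)
        for i in positions:
            choices = AMINO_ACIDS.replace(arr[i], "")
            arr[i] = choices[rng.integers(0, len(choices))]
        mutant = "".join(arr)
        realized = global_align_identity(seq, mutant).percent_identity
        if abs(realized - goal) <= tolerance:
            return mutant, realized
        # too similar -> mutate more; too diverged -> mutate less
        step = int(round(abs(realized - goal) * n / 100 * 0.6)) or 1
        k += step if realized > goal else -step
    raise RuntimeError(f"could not reach identity target {target} within {max_attempts} attempts")


_LOCAL_ALIGNER = BuiltinAligner()


def _plant_ortholog(
    ref: str, target: float, rng: np.random.Generator, tolerance: float
) -> tuple[str, float]:
    """Mutant that *presents* as a full-length ortholog to the local
    aligner.

    At ~34% identity a local alignment can trim diverged termini below
    the 80% coverage the confidence rules assume of a full-length
    ortholog, so candidates are re-drawn until the local alignment spans
    >=85% of the reference and its identity sits safely inside the band
    the directive targets.
    """
    for _ in range(50):
        seq, realized = mutate_to_identity(ref, target, rng, tolerance=tolerance)
        hit = _LOCAL_ALIGNER._align_pair("q", seq, "r", ref)
        if hit is None or hit.subject_coverage < 0.85:
            continue
        local_identity = hit.percent_identity
        if target < 0.40:
            if 30.5 < local_identity < 39.5:
                return seq, realized
        elif local_identity > 41.0:
            return seq, realized
    raise RuntimeError(f"could not plant a full-length ortholog at identity {target}")


# ---------------------------------------------------------------------------
# toy pathway set: 3 pathways, 12 steps, with a subpathway and variants

_PATHWAY_LAYOUT: list[tuple[str, list[str], list[str]]] = [
    # (pathway_id, step_ids, rule lines)
    ("ser", ["serA", "serC", "serB"], ["all = serA serC serB"]),
    ("met", ["metB", "metC", "metZ", "metE"],
     ["trans = metB metC | metZ", "all = trans metE"]),
    ("arg", ["argA", "argB", "argD", "argE", "argG"],
     ["acet = argA argB", "succ = argD argE", "all = acet argG | succ argG"]),
]

# steps present on every expansion of their pathway — safe spots for a
# shared planted gap
_MANDATORY_STEPS = [("ser", "serA"), ("ser", "serC"), ("ser", "serB"),
                    ("met", "metE"), ("arg", "argG")]


def _all_steps() -> list[tuple[str, str]]:
    return [(pid, sid) for pid, steps, _ in _PATHWAY_LAYOUT for sid in steps]


def _pathway_texts() -> dict[str, str]:
    texts = {}
    for idx_offset, (pid, steps, rules) in enumerate(_PATHWAY_LAYOUT):
        lines = [f"pathway {pid}"]
        for sid in steps:
            i = _all_steps().index((pid, sid))
            ec = f"1.{i + 1}.{i + 1}.{i + 1}"
            lines.append(f"{sid}: synthetic enzyme for {sid} :: EC:{ec}, term:{sid}tok")
        lines.extend(rules)
        texts[pid] = "\n".join(lines) + "\n"
    return texts


def _step_ec(pathway_id: str, step_id: str) -> str:
    i = _all_steps().index((pathway_id, step_id))
    return f"1.{i + 1}.{i + 1}.{i + 1}"


def _step_length(pathway_id: str, step_id: str) -> int:
    # unique lengths so any two fusion partners differ by >= 20 residues,
    # keeping their half-alignment bit scores well separated
    return 170 + 20 * _all_steps().index((pathway_id, step_id))


# ---------------------------------------------------------------------------
# directive planning

def plan_directives(spec: FixtureSpec, rng: np.random.Generator) -> list[PlantDirective]:
    """Seeded random plan: per genome one shared absent step (the same step
    in every genome, so known-gap marking has something to find), one
    medium ortholog, one decoy, one split, one fusion pair; everything
    else a high-confidence ortholog."""
    steps = _all_steps()
    shared_absent = _MANDATORY_STEPS[rng.integers(0, len(_MANDATORY_STEPS))]
    directives: list[PlantDirective] = []
    for g in range(spec.genome_count):
        gid = f"G{g:02d}"
        rest = [s for s in steps if s != shared_absent]
        order = list(rng.permutation(len(rest)))
        picks = [rest[i] for i in order]
        medium, decoy, split_step, fus_a, fus_b = picks[:5]
        highs = picks[5:]
        directives.append(PlantDirective(gid, *shared_absent, "absent"))
        directives.append(PlantDirective(gid, *medium, "ortholog", identity=MEDIUM_IDENTITY))
        directives.append(PlantDirective(gid, *decoy, "decoy", identity=DECOY_IDENTITY))
        directives.append(
            PlantDirective(gid, *split_step, "split",
                           breakpoint=float(rng.uniform(0.33, 0.67)))
        )
        directives.append(
            PlantDirective(gid, *fus_a, "fusion",
                           partner_pathway=fus_b[0], partner_step=fus_b[1])
        )
        directives.append(
            PlantDirective(gid, *fus_b, "fusion",
                           partner_pathway=fus_a[0], partner_step=fus_a[1])
        )
        for s in highs:
            directives.append(PlantDirective(gid, *s, "ortholog", identity=HIGH_IDENTITY))
    return directives


_EXPECTED_TIER = {
    "absent": Confidence.LOW,
    "fusion": Confidence.HIGH,
    "split": Confidence.HIGH,
    "decoy": Confidence.MEDIUM,
}


def expected_tier(d: PlantDirective) -> Confidence:
    if d.kind == "ortholog":
        return Confidence.HIGH if d.identity > 0.40 else Confidence.MEDIUM
    return _EXPECTED_TIER[d.kind]


# ---------------------------------------------------------------------------
# independent best-path chooser for the answer key

def _enumerate_paths(rules: dict[str, list[list[str]]], rid: str = "all") -> list[list[str]]:
    out: list[list[str]] = []
    for inst in rules[rid]:
        partial: list[list[str]] = [[]]
        for item in inst:
            subs = _enumerate_paths(rules, item) if item in rules else [[item]]
            partial = [p + s for p in partial for s in subs]
        out.extend(partial)
    return out


def choose_best_path(
    rules: dict[str, list[list[str]]], tiers: dict[str, Confidence]
) -> list[str]:
    """Documented selection rule, restated from scratch for the key: best
    minimum tier, then sum of (-2, -0.1, +1) weights (x10 integers), then
    longer path, then first in expansion order."""
    weight = {Confidence.LOW: -20, Confidence.MEDIUM: -1, Confidence.HIGH: 10}
    best = None
    best_score = None
    for path in _enumerate_paths(rules):
        score = (
            min(tiers[s].value for s in path),
            sum(weight[tiers[s]] for s in path),
            len(path),
        )
        if best_score is None or score > best_score:
            best, best_score = path, score
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# universe construction

def build_profile(sequences: list[str], name: str, trusted_cutoff: float):
    """Build a HMMER3 profile from same-length ungapped sequences."""
    seqs = [
        pyhmmer.easel.TextSequence(name=f"t{i}".encode(), sequence=s)
        for i, s in enumerate(sequences)
    ]
    msa = pyhmmer.easel.TextMSA(name=name.encode(), sequences=seqs)
    builder = pyhmmer.plan7.Builder(_ALPHABET)
    background = pyhmmer.plan7.Background(_ALPHABET)
    hmm, _, _ = builder.build_msa(msa.digitize(_ALPHABET), background)
    hmm.cutoffs.trusted = (trusted_cutoff, trusted_cutoff)
    # pin volatile header fields so identical seeds give identical files
    hmm.creation_time = _EPOCH
    hmm.command_line = "gapseek-fixture"
    return hmm


def build_universe(spec: FixtureSpec) -> Universe:
    """Deterministically expand a spec into a full fixture universe."""
    rng = np.random.default_rng(spec.seed)
    steps = _all_steps()
    texts = _pathway_texts()
    pathways = [parse_pathway_file(texts[pid], pathway_id=pid) for pid, _, _ in _PATHWAY_LAYOUT]

    # reference proteins, one characterized per step
    refs: dict[tuple[str, str], str] = {}
    records: list[ProteinRecord] = []
    for pid, sid in steps:
        seq = random_protein(rng, _step_length(pid, sid))
        refs[(pid, sid)] = seq
        records.append(
            ProteinRecord(
                protein_id=f"REF_{pid}_{sid}",
                sequence=seq,
                description=f"synthetic enzyme for {sid} {sid}tok",
                ec_numbers=(_step_ec(pid, sid),),
                status=ProteinStatus.CHARACTERIZED,
                source_db="synthetic",
            )
        )
    # curated-only variants for two fixed steps
    for pid, sid in (("ser", "serC"), ("met", "metE")):
        mut, _ = mutate_to_identity(refs[(pid, sid)], 0.80, rng)
        records.append(
            ProteinRecord(
                protein_id=f"CUR_{pid}_{sid}",
                sequence=mut,
                description=f"synthetic curated homolog {sid}tok",
                ec_numbers=(_step_ec(pid, sid),),
                status=ProteinStatus.CURATED_ONLY,
                source_db="synthetic",
            )
        )

    directives = spec.directives if spec.directives is not None else plan_directives(spec, rng)
    for d in directives:
        if (d.pathway_id, d.step_id) not in refs:
            raise ValueError(f"directive references unknown step {d.pathway_id}.{d.step_id}")

    key = AnswerKey()
    proteomes: dict[str, dict[str, str]] = {}
    genome_ids = sorted({d.genome_id for d in directives})
    fusion_done: dict[str, set[tuple[str, str]]] = {g: set() for g in genome_ids}

    for gid in genome_ids:
        proteome: dict[str, str] = {}
        tiers: dict[tuple[str, str], Confidence] = {}
        for d in [d for d in directives if d.genome_id == gid]:
            slot = (d.pathway_id, d.step_id)
            tiers[slot] = expected_tier(d)
            ref = refs[slot]
            if d.kind == "absent":
                continue
            if d.kind == "ortholog":
                tol = 2.0 if d.identity < 0.40 else 3.0
                seq, realized = _plant_ortholog(ref, d.identity, rng, tolerance=tol)
                proteome[f"{gid}_{d.pathway_id}_{d.step_id}"] = seq
                key.realized_identities[(gid, d.pathway_id, d.step_id)] = realized
            elif d.kind == "decoy":
                seq, realized = _plant_ortholog(ref, d.identity, rng, tolerance=2.0)
                pid_name = f"{gid}_{d.pathway_id}_{d.step_id}"
                proteome[pid_name] = seq
                key.realized_identities[(gid, d.pathway_id, d.step_id)] = realized
                decoy_seq, _ = mutate_to_identity(seq, 0.95, rng)
                records.append(
                    ProteinRecord(
                        protein_id=f"DECOY_{pid_name}",
                        sequence=decoy_seq,
                        description=f"synthetic conflicting function near {pid_name}",
                        ec_numbers=(f"9.9.9.{len(records)}",),
                        status=ProteinStatus.CHARACTERIZED,
                        source_db="synthetic",
                    )
                )
            elif d.kind == "split":
                cut = int(round(d.breakpoint * len(ref)))
                proteome[f"{gid}_{d.pathway_id}_{d.step_id}_n"] = ref[:cut]
                proteome[f"{gid}_{d.pathway_id}_{d.step_id}_c"] = ref[cut:]
            elif d.kind == "fusion":
                pair = tuple(sorted([slot, (d.partner_pathway, d.partner_step)]))
                if pair in fusion_done[gid]:
                    continue
                fusion_done[gid].add(pair)
                a, b = pair
                proteome[f"{gid}_fus_{a[1]}_{b[1]}"] = refs[a] + refs[b]
            else:
                raise ValueError(f"unknown directive kind {d.kind!r}")
        # steps with no directive at all: absent, hence LOW
        for slot in steps:
            tiers.setdefault(slot, Confidence.LOW)
        for i in range(spec.n_background):
            proteome[f"{gid}_bg{i}"] = random_protein(rng, 300)
        proteomes[gid] = proteome
        key.step_tiers[gid] = dict(tiers)
        key.best_paths[gid] = {}
        key.gaps[gid] = []
        for pid, _, _ in _PATHWAY_LAYOUT:
            rules = {
                r.rule_id: [list(inst) for inst in r.instantiations]
                for r in next(p for p in pathways if p.pathway_id == pid).rules.values()
            }
            step_tiers = {sid: tiers[(pid, sid)] for (p2, sid) in steps if p2 == pid}
            best = choose_best_path(rules, step_tiers)
            key.best_paths[gid][pid] = tuple(best)
            key.gaps[gid].extend(
                (pid, sid) for sid in best if step_tiers[sid] < Confidence.HIGH
            )

    # markers
    marker_hmms = []
    marker_profiles: dict[str, MarkerProfile] = {}
    if spec.marker_count > 0:
        bases = [random_protein(rng, 160) for _ in range(spec.marker_count)]
        for m, base in enumerate(bases):
            train = []
            for _ in range(6):
                v, _r = mutate_to_identity(base, 0.90, rng)
                train.append(v)
            marker_hmms.append(build_profile(train, f"rib{m:02d}", trusted_cutoff=30.0))
        for g, gid in enumerate(genome_ids):
            ident = spec.marker_identities[g % len(spec.marker_identities)]
            markers: dict[str, tuple[str, str]] = {}
            for m, base in enumerate(bases):
                if ident >= 1.0:
                    seq = base
                else:
                    seq, _r = mutate_to_identity(base, ident, rng, tolerance=2.0)
                pid_name = f"{gid}_rib{m:02d}"
                proteomes[gid][pid_name] = seq
                markers[f"rib{m:02d}"] = (pid_name, seq)
            marker_profiles[gid] = MarkerProfile(genome_id=gid, domain="bacteria", markers=markers)
        # expected relatedness from realized identities, applying the rule
        for ga, gb in itertools.combinations(genome_ids, 2):
            idents = [
                global_align_identity(
                    marker_profiles[ga].markers[m][1], marker_profiles[gb].markers[m][1]
                ).percent_identity
                for m in marker_profiles[ga].markers
            ]
            retained = [i for i in idents if i >= 50.0]
            related = len(retained) >= 10 and statistics.median(retained) >= 75.0
            key.relatedness[(ga, gb)] = related
            key.relatedness[(gb, ga)] = related
        for gid in genome_ids:
            key.relatedness[(gid, gid)] = len(marker_profiles[gid].markers) >= 10

    # catalog: the first genome's gaps become its known-gap entries
    catalog = None
    if spec.marker_count > 0 and genome_ids:
        ref_gid = genome_ids[0]
        entries = [(ref_gid, pid, sid) for pid, sid in key.gaps[ref_gid]]
        catalog = KnownGapCatalog(
            entries=entries, profiles={ref_gid: marker_profiles[ref_gid]}
        )
        entry_set = {(p, s) for _, p, s in entries}
        for gid in genome_ids:
            flags = []
            if key.relatedness.get((gid, ref_gid), False):
                for pid, sid in key.gaps[gid]:
                    if (pid, sid) in entry_set:
                        flags.append((pid, sid, (ref_gid,)))
            key.known_gaps[gid] = flags

    hmm_records = []
    profiles = {}
    from .reference_db import HMMRecord

    for hmm in marker_hmms:
        name = hmm.name
        hid = name.decode() if isinstance(name, bytes) else str(name)
        hmm_records.append(
            HMMRecord(hmm_id=hid, model_length=hmm.M, trusted_cutoff=float(hmm.cutoffs.trusted[0]))
        )
    db = ReferenceDatabase(records, hmm_records=(), hmm_profiles={})
    return Universe(
        spec=spec,
        db=db,
        pathways=pathways,
        pathway_texts=texts,
        proteomes=proteomes,
        marker_hmms=marker_hmms,
        marker_profiles=marker_profiles,
        catalog=catalog,
        key=key,
        directives=list(directives),
    )


def write_universe(universe: Universe, directory) -> None:
    """Emit the on-disk formats the engine consumes: pathway DSL files,
    reference DB (FASTA + TSV), proteome FASTAs, marker HMMs, catalog."""
    d = pathlib.Path(directory)
    (d / "pathways").mkdir(parents=True, exist_ok=True)
    for pid in sorted(universe.pathway_texts):
        (d / "pathways" / f"{pid}.steps").write_text(universe.pathway_texts[pid])
    universe.db.write(d / "db")
    (d / "proteomes").mkdir(exist_ok=True)
    for gid in sorted(universe.proteomes):
        with open(d / "proteomes" / f"{gid}.faa", "w") as fh:
            for pid in sorted(universe.proteomes[gid]):
                fh.write(f">{pid}\n{universe.proteomes[gid][pid]}\n")
    if universe.marker_hmms:
        md = d / "markers"
        md.mkdir(exist_ok=True)
        for hmm in universe.marker_hmms:
            name = hmm.name
            hid = name.decode() if isinstance(name, bytes) else str(name)
            with open(md / f"{hid}.hmm", "wb") as fh:
                hmm.write(fh)
    if universe.catalog is not None:
        write_catalog(universe.catalog, d / "catalog")
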