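# Methods

This note records the model gapseek implements, the numerical and design
choices behind it, what the synthetic fixtures do and do not emulate, and
the known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pathway representation and expansion

A pathway is a dictionary of steps plus a dictionary of rules; each rule
lists alternative instantiations (ordered lists of step ids and rule ids),
and the rule `all` defines the pathway. Expansion inlines subpathways
recursively and takes the Cartesian product of alternatives left-to-right,
depth-first, producing a deterministic path order that the best-path
tie-break depends on. Expansion is capped (default 10,000 paths) and raises
rather than truncating: silent truncation would make the "best" path depend
on an arbitrary prefix. Real pathway sets sit far below the cap. A step may
appear more than once in one expanded path; each occurrence is scored
identically.

The rule-reference graph must be acyclic; cycles are rejected at parse time
with the offending cycle listed. Validation (report-only) flags steps not
reachable from `all`, rules never referenced, and requirements whose scope
or target does not resolve.

## Reference database

Two pools: characterized proteins (experimental evidence — the only basis
for high confidence) and curated-only proteins (curated enzyme annotation
without experimental evidence — at most medium). Records whose description
marks them as uncharacterized are filtered out: descriptions beginning with
"uncharacterized" or matching the placeholder patterns "uncharacterized
protein" / "DUFnnnn family protein" / "PFnnnnn family protein" / "UPFnnnnn
family protein" (digits required); for EcoCyc and CharProtDB sources also
descriptions beginning with "putative" or "protein", and for CharProtDB
"probably". Matching is case-insensitive; the leading-word rules require a
word boundary so "Proteinase inhibitor" survives.

The curated pool is reduced by greedy centroid clustering at 60 % global
identity (longest-first visiting order makes centroids deterministic;
clustering here is written in the package because no installed library
provides sequence clustering). EC-heterogeneous clusters are split by EC
tuple, and the representative of each final cluster is the
lexicographically smallest protein id — the source procedure picks
arbitrarily, but tests need determinism.

Matcher semantics: EC comparison is component-wise with `-` (or a missing
trailing component) as a wildcard on either side, so incomplete EC numbers
match any completion. Term matching is case-insensitive with both ends at
word boundaries, where a boundary is a transition between `[A-Za-z0-9]` and
anything else or the string edge — common regex semantics, and directly
testable against a scanning oracle. Matchers are applied uniformly to both
pools (with provenance kept separate); hits to proteins named by a step's
ignore list are disregarded only in the conflicting-hit test.

## Homology search

The search contract — every hit has ≥ 30 % identity and E < 0.01, ordering
by (query id, descending bit score, subject id) — is satisfied by two
backends. The built-in backend is Smith–Waterman via Biopython's
PairwiseAligner with BLOSUM62 and affine 11/1 gaps, the de facto standard
and fully reproducible. Raw scores are converted to bits with fixed gapped
Karlin–Altschul parameters (λ = 0.267, K = 0.041) and E = m·n·2^(−bits).
This calibration is conventional, not load-bearing: all tests assert
threshold classifications on clearly separated inputs. The optional
external backend shells out to NCBI `blastp`; a contract test checks the two
backends agree on hit presence and identity (±3 points) over a panel of
pairs spanning 15–100 % identity. Panel targets avoid the 27–33 % band:
realized identity is only controlled to ±3 points, and the panel tests
backend agreement, not boundary behaviour at the 30 % cutoff.

Percent identity is identities over alignment columns (internal gap columns
in the denominator). All coverages used by the confidence rules are
subject-side (of the reference protein, or of the HMM) — the rules speak of
covering "that protein"/"the model". Global identity (used for marker
relatedness and fixture verification) excludes terminal gap columns, the
usual convention for comparing full-length homologs of slightly different
lengths.

Profile search uses pyhmmer (`hmmsearch`) with per-model trusted cutoffs
enforced both at load time (profiles without a TC line are rejected) and at
search time. One hit is reported per (query, profile): the best domain's
envelope gives the query coordinates, its alignment span the model
coverage.

## Candidate scoring

The "other hit" of a candidate is the best-scoring alignment of that
protein to a characterized protein that neither matches the step nor is
ignored for it, restricted to hits overlapping at least 50 % of the
candidate's *relevant region* — the query span of the step hit (for HMM
candidates, the domain envelope). This restriction is what rescues fusion
proteins: the alignment of the other half to its own reference covers none
of the region being scored and is discarded. The restriction is a config
field (`min_region_overlap`), so tests can disable it and demonstrate the
fusion demotion it prevents.

Tier rules are implemented with the strictness their phrasing implies:
"over 40 %" is strict, "at least 50 %" and "at least 10 bits" are
inclusive; boundary cases are pinned in tests. An absent other hit
satisfies the margin clauses. Low confidence needs only ≥ 50 % coverage
(the search threshold already guarantees ≥ 30 % identity); whether low
confidence should also survive an other-hit comparison is not specified by
the rules' phrasing, so it does not. Curated-only subjects cap at medium
regardless of the numbers. A candidate that fails even the low rule yields
nothing.

Split joining considers, per (step, reference), the best low-coverage
(< 70 %) alignment of each distinct protein and all pairs thereof. Joining
requires: each part ≥ 10 bits above its own other hit, subject-coordinate
overlap ≤ 20 % of *either* alignment's span, and combined (union) subject
coverage ≥ 70 %. Overlap is measured on subject coordinates — the parts are
different query proteins, so query-side overlap is undefined. Combined
identity is the span-weighted mean of the part identities (the source
procedure is silent; span weighting makes the combined value the identity
of the union alignment). The joined candidate is classified with the
margin clause treated as satisfied (both parts already cleared it
individually) and kept only if its tier strictly exceeds both parts'.
Joins are evaluated against every shared reference and the best result per
protein pair is kept — evaluating references in name order and stopping at
the first success would let a curated reference (capped at medium) shadow a
characterized one (eligible for high). Three-way splits are out of scope.

## Path scoring and requirements

Step confidence = best candidate tier, low when there are no candidates at
all, so gapped pathways still compete. Primary path score = worst step
tier; ties break on the secondary score Σ(−2 low, −0.1 medium, +1 high),
then on length (longer wins), then on expansion order. The secondary score
is carried as an integer scaled ×10 — with float 0.1-accumulation, equal
secondary scores could compare unequal and break ties nondeterministically.
Subpathways contribute through their inlined steps; this is the only
reading consistent with the longer-path tie-break.

Requirements attach a (pathway, step) that must — or must not — be present
to a pathway or one of its rules. They fire only when the scope is actually
used by the selected best path. "Present" means medium-or-better
confidence; the must-not polarity warns when the target step lies on the
best path of its own pathway (mutually exclusive route selections, e.g.
transsulfuration run in both directions). Violations are warnings, never
errors: the selection itself is not changed.

## Known gaps and relatedness

Marker profiles hold one protein per ribosomal marker HMM; a marker hit by
two or more proteins is dropped entirely (paralogy/contamination).
Relatedness compares profiles marker-by-marker with global alignment,
retains hits at ≥ 50 % identity and ≥ 70 % coverage, drops any hit whose
protein participates in more than one hit (one-to-one), and calls genomes
related at ≥ 10 retained hits with median identity ≥ 75 %. Profiles from
different domains (bacteria vs archaea) use different marker sets and are
unrelated by definition. The new genome is always the query side; the
global identity measure makes per-pair identities symmetric. A gap on a
best path is flagged *known* when a related cataloged genome lists the same
(pathway, step); the flag carries the supporting genome ids.

## Synthetic fixtures

The generator emulates every input at toy scale: 3 pathways / 12 steps
(one linear, one with a two-alternative subpathway, one with two
whole-route variants), one characterized reference per step with a unique
EC and description token, curated-only variants for two steps, 12
ribosomal-marker families of length 160, and per-genome proteomes built
from planting directives. Default study conditions per genome: one shared
absent step (the same mandatory step in every genome, so the known-gap
catalog has something to match), one ortholog at 34 % identity (medium),
one decoy (45 % ortholog plus a near-identical characterized protein of
another function — the margin rule demotes it to medium), one split
(breakpoint uniform in 0.33–0.67), one fusion pair (exact concatenation of
two references; reference lengths 170 + 20·index so any two partners'
half-scores are ≥ 10 bits apart), and high-confidence orthologs at 75 %
identity elsewhere. Marker identities default to (100, 95, 85, 60, 95) %
across the five genomes, making three query genomes related to the
cataloged one and one safely unrelated.

Mutation is substitution-only, so identity and coverage vary independently;
backgrounds are i.i.d. uniform over the 20 amino acids, adequate because no
test depends on realistic composition. `mutate_to_identity` re-draws until
the realized global identity is within tolerance (±3 points by default,
tighter where a test pins values near a threshold) of the target. Planted
orthologs are additionally verified to *present* as full-length to the
local aligner (span ≥ 85 % of the reference, local identity inside the
directive's band): at ~34 % identity Smith–Waterman can trim diverged
termini below the 80 % coverage the medium rule assumes of a full-length
ortholog, which would silently change the planted condition.

The answer key is derived from the directives and the documented rules
without running the engine: tiers from the directive table, best paths from
an independent re-statement of the selection rule, relatedness from
generator-side global alignments of the planted markers. What passing
answer-key tests shows is that the engine implements the documented rules
on sequences whose ground truth is known by construction; it does not show
performance on real proteomes, where domain architecture, compositional
bias, indels and annotation noise all matter and none are simulated.

## Problem sizes and numerical choices

The test suite and acceptance script use universes of 5 genomes × ~30
proteins against a ~20-protein reference database (single-genome universes
for the fusion/split checks), 1,000 random rule graphs for the path-solver
oracle, and an exhaustive ~16,000-case grid for the classification oracle —
sizes chosen so the whole suite exercises every rule many times while
remaining a desk-scale computation. Determinism is treated as an output
contract: result files (JSON/TSVs) are byte-identical across runs for
identical inputs and config; volatile provenance (timings) is confined to
`run_record.json`. HMM fixture files pin their creation-time and
command-line header fields for the same reason.

## Limitations

* High-confidence calls are only as good as the characterized pool; the
  engine never predicts whether a capability is present, only how well each
  step is supported.
* The built-in E-value calibration is approximate; at realistic database
  sizes an external backend should be used.
* Splits of more than two parts are not detected.
* The relatedness rule is calibrated for ribosomal markers at roughly
  family-level resolution; it is not a general phylogenetic distance.
* Fixtures do not emulate indels, domain shuffling (beyond the fusion and
  split constructs), paralogous families, or realistic amino-acid
  composition.
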