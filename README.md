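# gapseek

Confidence-tiered reconstruction of biosynthetic pathways from a microbial
proteome.

## The problem

Predicting which small molecules (amino acids, vitamins, ...) a bacterium or
archaeon can synthesize from its genome sequence is unreliable in practice:
variant pathways are missing from annotation databases, many database
annotations are wrong, and best-hit annotation transfers break down on fused
and split genes. `gapseek` does not try to answer "can this organism make X?"
— instead it reconstructs, for each pathway, the *most plausible* route given
current knowledge, and highlights the **gaps**: steps on that route that
could not be confidently tied to a protein. A gap may mean a missing
capability, or it may mean undiscovered biology; to help tell these apart,
gaps that are also present in a *related* organism known to grow without the
compound are marked as **known gaps**.

It is aimed at comparative genomicists and curators who want traceable,
experimentally grounded step assignments rather than opaque presence/absence
calls.

## The model

Each pathway is a set of **steps** (one enzymatic reaction or subunit each)
combined by rules with alternative instantiations; subpathways nest inside
pathways. Expanding the distinguished `all` rule yields every concrete
alternative path. Steps are defined by matchers — EC numbers, description
terms (word-boundary, case-insensitive), curated/UniProt identifiers, or
profile-HMM ids — resolved against a reference database of
**characterized** proteins (experimental evidence; the only basis for
high-confidence calls) and **curated-only** proteins (annotation without
experimental evidence; at most medium confidence).

Candidates for a step come from local alignment (hits with ≥ 30 % identity,
E < 0.01) or from profile HMMs (hits at or above the curator's trusted
cutoff). Each candidate is checked against the full characterized database
for an **other hit** — the best-scoring alignment to a protein with a
different function that overlaps at least half of the candidate's relevant
region. Confidence is then tiered:

| tier | alignment candidates | HMM candidates |
|---|---|---|
| high | identity > 40 %, subject coverage > 80 %, bit score ≥ other + 10, characterized subject | model coverage ≥ 80 % and other hit absent, < 40 % identity or < 75 % coverage |
| medium | identity > 40 % ∧ coverage > 70 % (regardless of other); or identity > 30 % ∧ coverage > 80 % ∧ bits > other | any trusted-cutoff hit |
| low | coverage ≥ 50 % | — |

Because steps are scored independently and conflicting hits outside the
relevant region are ignored, a fusion protein is credited to both of its
steps. Conversely, two proteins whose alignments tile ≥ 70 % of one
reference with ≤ 20 % overlap (each ≥ 10 bits above its own other hit) are
joined as a **split** candidate.

A step's confidence is its best candidate's tier (low if it has none); a
path's primary score is its *worst* step. Ties break on a secondary score
(−2 / −0.1 / +1 per low/medium/high step), then on path length. Gaps are
the below-high steps on the chosen best path. Genome relatedness for
known-gap marking uses single-copy ribosomal marker proteins: related ⇔ at
least 10 one-to-one marker hits at ≥ 50 % identity / ≥ 70 % coverage with
median identity ≥ 75 %.

## Worked example

The package ships a synthetic-universe generator that emulates every input
(reference DB, pathway definitions, proteomes with planted orthologs,
fusions, splits and decoys, marker profiles, known-gap catalog) with a known
answer key:

```sh
$ gapseek make-fixtures --seed 7 --out fx
universe seed=7 -> fx
$ gapseek analyze fx/proteomes/G01.faa --pathways fx/pathways --db fx/db --out out
G01: 3 pathways, 2 gaps -> out
$ cat out/summary.tsv
pathway_id  primary_confidence  best_path        n_gaps  gaps
arg         low                 argA argB argG   1       argG
met         medium              metB metC metE   1       metE
ser         high                serA serC serB   0
```

Serine synthesis is fully high-confidence (e.g. `serA`: 75.3 % identity,
100 % coverage of its reference, 264.6 bits, no conflicting hit). The
methionine route is complete but `metE` is only medium confidence: its
candidate is 46.5 % identical to the reference with 97.6 % coverage, yet a
characterized protein with another function scores far higher (592.0 vs
204.1 bits), so the +10-bit margin for high confidence fails — exactly the
situation where substrate specificity is uncertain. `argG` has no candidate
at all (low confidence). Marking known gaps against the catalog:

```sh
$ gapseek known-gaps out/results.json --catalog fx/catalog \
    --proteome fx/proteomes/G01.faa --marker-hmms fx/markers --out out/annotated.json
1 known-gap flags -> out/annotated.json
```

G01 is related to the cataloged organism G00 (median marker identity well
above 75 %), and G00 has the same `arg`/`argG` gap, so the gap is flagged as
known — likely unknown biology rather than a missing capability.

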