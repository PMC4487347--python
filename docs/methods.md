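# Methods

## Scope and model

`evanno` is a descriptive triage tool for called coding SNVs, not a
statistical caller: it performs no inference, estimates no error rates, and
its output is a ranking plus threshold filters over per-variant evidence.
The intended use is small studies — down to a single clinical case — where
a transparent, auditable score is more informative than a calibrated model
trained on cohorts the study does not have.

The pipeline operates strictly offline.  Everything that would normally be
a live query (PubMed literature counts, COSMIC burden, gene–disease links,
functional annotation, census membership, interaction partners, tissue
expression) is a local TSV under a reference directory; the tables are the
contract, with no query expansion and no versioning of the upstream
databases.  Running the effect predictor (VEP) is likewise out of scope:
the tool exports a 4-column pileup for it and parses its tabular output.

## Coordinates and mapping

All internal genomic arithmetic is 0-based half-open (the GenePred/UCSC
convention); 1-based positions appear only in file I/O (VCF, MuTect,
pileup, VEP, reports).  A variant maps to a gene iff its position lies in
the transcript span `[tx_start, tx_end)` of ≥ 1 transcript of that gene —
UTRs and introns included, strand ignored — and is *coding* iff for ≥ 1
transcript it lies both inside `[cds_start, cds_end)` and inside an exon.
The two-stage narrowing (mapped, then coding) is deliberate: the mapped set
retains promoter-proximal and intronic variants for users who want them,
while the coding set is what proceeds to scoring.  Mapping on transcript
span rather than CDS span at the first stage is a design choice; the
separate coding stage makes the stricter predicate explicit.

Interval lookup uses one interval tree per chromosome.  The tree is an
implementation detail: the test suite requires observational identity with
an exhaustive O(V·T) per-transcript scan, including probes planted at every
interval boundary (`tx_start`, `tx_end − 1`, `tx_end`, CDS and exon edges),
which is where half-open arithmetic would first go wrong.

Variants overlapping several genes are annotated to all of them; scoring
evaluates each (variant, gene) pair and the ranking keeps the best-scoring
gene per variant (ties broken by lexically first symbol).  This avoids
silently losing an overlapping gene while keeping one row per variant in
the ranked output.

## Input handling

Only biallelic SNVs enter the pipeline.  VCF records with multi-base
alleles are counted in a skip summary, multiallelic records are split per
alternate allele and re-checked, and FILTER-failed records are dropped by
default (flag to keep).  Zygosity: `0/1` → het, `1/1` → hom-alt, missing
genotype → unknown.  MuTect call-stats rows are kept when `judgement ==
KEEP` (configurable); zygosity is het unless a `tumor_f` column reports an
allele fraction ≥ 0.9, a pragmatic hom-alt proxy for a tumor sample.

The pseudo-germline intersection keys variants by (chrom, pos, ref, alt)
only — allele identity defines "the same variant" across related samples;
zygosity, caller and sample id are deliberately ignored, and metadata in
the output comes from the first input set.

## Effect-predictor join

VEP default tabular output is aggregated from transcript rows to one record
per (variant, gene): SIFT = min over rows, PolyPhen-2 = max over rows (the
most damaging transcript wins on both scales — the conservative choice for
prioritization), consequences are unioned, the amino-acid change is taken
from the first row carrying one.  GMAF absent is kept absent, never imputed
to 0: absence from the population frequency data means the variant is
likely unreported, which the rarity channel treats as maximal rarity.

The join with called variants is an inner join on (chrom, pos, ref, alt);
unmatched records on either side are counted in a reconciliation summary
rather than silently dropped, and zero joins with nonempty inputs raises an
error suggesting chromosome-name normalization, the overwhelmingly common
cause.

Polarity classification groups residues as nonpolar {A,V,L,I,P,F,M,W,G,C},
polar-uncharged {S,T,Y,N,Q} and charged {K,R,H,D,E}; histidine sits with
the charged class per the standard biochemical grouping.  Transitions are
labelled none / gain / loss / swap; unknown letters are left unclassified
with a warning.

## Score construction

The total is an additive, unit-weighted sum of eight channels (README table
gives the formulas).  Several constants are this package's concrete
instantiation of a deliberately simple scheme, all exposed in
`FocusConfig` so alternatives are one configuration away:

- **rarity ramp `g_max = 0.05`** — a variant at 5% minor allele frequency
  is common enough to contribute nothing; the ramp is linear below that.
- **binary SIFT at 0.05** — the conventional SIFT damage call threshold;
  the channel is binary because SIFT's scale is not comparable to
  PolyPhen's probability.
- **identity PolyPhen channel** — PolyPhen-2 reports a probability-like
  score already in [0,1], so it is used as is.
- **COSMIC cap at 1 entry per residue** — per-residue burden saturates at
  one recorded somatic mutation per amino acid, preventing a handful of
  hypermutated genes from dominating.
- **log10 literature** — damps heavily published biomarker genes; 9 papers
  score 1, 99 score 2.
- **zygosity 1.0 / 0.5** — a homozygous alternate allele doubles the
  channel; unknown genotypes are treated as het rather than penalized.

Focus matching is case-insensitive substring for disease names, and
case-insensitive with non-alphanumerics stripped for process terms (so the
phrase `SignalTransduction` matches the term `Signal transduction`).  Empty
focus lists make the corresponding channel and filter inert.

Ranking sorts by total descending with a deterministic tie-break
(chromosome lexical, position ascending, alternate allele lexical), so
output is byte-stable across runs and input permutations.

## Filters

The result table is a conjunction: damage (≥ 1 predictor present and every
present predictor meeting its threshold; a disjunctive `any` mode is
available behind a flag), frequency (GMAF absent or ≤ threshold; the
default threshold 1 is a documented no-op sentinel since real frequencies
are ≤ 0.5), literature / COSMIC / disease-association counts (raw integer
counts, ≥ thresholds), census mode (0 none, 1 census members, 2 interactors
that are not members, 3 either — modes 1 and 2 partition mode 3 by
construction) and the functional focus.  Strictly tighter thresholds can
only shrink the table; this lattice law is property-tested over randomized
threshold pairs.

The COSMIC filter compares raw entry counts, not the per-residue normalized
value, matching the integer semantics of the count thresholds.

## Expression summary

Each retained gene's tissue profile is divided by its own mean, so every
emitted row has mean 1 and rows are comparable across genes with very
different absolute expression.  Genes without a profile — or with an
all-zero profile, where the normalization is undefined — are listed
separately, never zero-filled.  Rows are ordered by the best variant rank
of the gene.

## Synthetic universe

The generator emulates the twin-study design: shared germline variants in
all four samples, target-only somatic variants (also emitted as MuTect
KEEP rows, with a couple of REJECT decoys), and per-sample private noise.
Genes are tiled in disjoint 6 kb windows separated by 4 kb intergenic gaps;
transcripts (1–2 per gene, 2–4 exons) stay inside their window, which makes
the coding / genic-noncoding / intergenic position pools provably disjoint
and the manifest a complete oracle for every stage.  Positions are sampled
without replacement, preserving key uniqueness.

Default conditions: 100 shared germline and 60 target-only variants over
30 genes on 3 chromosomes, coding fraction 0.6, 3 planted drivers, 5
private calls per sample.  The driver profile is: GMAF unreported, SIFT
drawn from [0, 0.04], PolyPhen from [0.90, 0.99], a polarity-changing
amino-acid substitution, host gene with one COSMIC entry per residue, 99
focus-term publications, focus-matching disease and process annotations,
and census membership or a census interactor.  Background: GMAF from
[0.05, 0.45], SIFT [0.3, 1.0], PolyPhen [0, 0.3], sparse evidence.  These
profiles separate driver totals (≈ 8.4) from background (< 2.5) by a wide
margin, so top-k recovery tests a correct pipeline, not a lucky seed.  The
VEP-style file is written directly from ground truth (jittering per-
transcript SIFT/PolyPhen so the min/max aggregation is genuinely
exercised); it tests this package's parsing and joining, never VEP itself.

What the generator does **not** emulate: realistic mutational signatures,
linkage, sequence context, read-level errors, caller-specific artifacts, or
annotation disagreements between gene-model releases.  Passing tests
demonstrate the pipeline's algebra and bookkeeping are correct on
well-formed inputs, not that the score separates real drivers in real
exomes.

The shipped worked example is a fixed 20-variant somatic scenario (3
drivers) with the hematological focus configuration (MeSH term `leukemia`,
the disease list Myeloprolif/Leukemia/Lymphoma/Lymphocytosis/Myelodysplas
and a 27-phrase functional focus) written next to the data as `focus.cfg`.

## Problem sizes and determinism

Test and acceptance runs use deliberately modest sizes chosen as this
package's own benchmark conditions: oracle-equivalence corpora span 10³–10⁴
variants × 50–500 transcripts over 20 seeds; driver-recovery uses the
20-variant worked example and a 1000-variant universe with 10 drivers.  All
randomness flows from explicit seeds through `numpy.random.default_rng`;
every writer sorts its rows, so identical inputs give byte-identical
outputs.

## Known limitations

- SNVs only: indels, MNVs and structural variants are skipped (counted).
- Gene identity is the symbol; paralogs sharing a symbol would be merged.
- The VEP parser reads the "default" tabular dialect only (not VCF or JSON
  output), and requires the `chrom_pos_ref/alt` uploaded-variation key that
  pileup-based input produces.
- The score is unit-weighted and additive by design; it is a triage aid,
  and a high or low total carries no probabilistic guarantee either way.
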