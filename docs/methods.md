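# Methods

This note documents the models, conventions, parameters, and design
choices behind `varprio`, in the spirit of a package methods appendix. It
states no empirical result that the test suite and `scripts/acceptance.py`
do not themselves compute.

## Variant model and normalization

A variant is a single-sample small substitution or indel with 1-based
coordinates, uppercase ACGT alleles, optional read depths, and a variant
allele fraction (VAF) defined as `alt_depth / total_depth`. VAF is taken
from caller-reported read support (per-sample AD+DP in VCF, falling back
to INFO DP; `reads2/(reads1+reads2)` in VarScan tables) and never
re-derived from genotype likelihoods, because the sequencing-error filter
is defined on caller-reported allele fraction. Symbolic and structural
alternates (e.g. `<DEL>`, breakends) are outside the small-variant model
and are skipped on read with a logged count. Chromosome names are taken
verbatim; an optional alias map (`chr1`↔`1`) can be applied on read.

All knowledge-base joins key on the *normalized* representation: shared
suffix removed, shared prefix removed down to the single anchor base
indels require, and indels shifted left while the shifted representation
still matches the reference (the standard left-alignment loop: trim equal
terminal bases, extending left with the preceding reference base whenever
an allele empties). At the contig start, where no left extension exists,
the current representation is kept — it is already leftmost. The procedure
is idempotent, and the test suite checks it against a brute-force
enumeration of all equivalent representations (minimal total allele
length, then leftmost position). Reading a VCF without a reference
accessor applies only the trimming steps; full left-alignment needs the
reference, so the pipeline always passes one.

## Gene models and consequence classification

A transcript model is a set of sorted, disjoint, 1-based inclusive exon
intervals plus CDS intervals contained in them. Models whose total CDS
length is not a multiple of 3 cannot be translated reliably and are
rejected on load (logged, not fatal). Models load from GTF (via gffutils)
or a documented TSV dialect; sequence comes from an indexed FASTA (via
pyfaidx) or an in-memory accessor.

Classification of a normalized variant against one model proceeds in two
stages.

**Region.** The affected bases are: the substituted base(s) for
SNVs/MNVs; the two bases flanking the insertion point for insertions; the
deleted bases for deletions. If no affected base is inside the transcript
span the call is `intergenic`. A variant whose affected bases straddle an
exon/intron junction or the transcript edge is `splicing`; fully intronic
variants within ±2 bp of an exon boundary (the canonical splice
dinucleotides) are `splicing`, otherwise `intronic`. Fully exonic variants
outside the CDS are `utr`. A variant that overlaps the CDS only partially
— including a CDS/UTR edge inside an exon — is classified `splicing` as
well: coding reconstruction is ill-defined across any CDS boundary, and
one consistent boundary rule is preferable to special cases. (Only the
CDS/intron case is biologically a splice variant; the label is used here
as "junction-spanning".)

**Coding.** For SNVs the affected codon is translated before and after
the substitution under the standard genetic code: same amino acid →
`synonymous_snv`; new amino acid is a stop → `stopgain`; reference amino
acid was the stop → `stoploss`; otherwise `nonsynonymous_snv`. A change in
the first codon (start loss) is reported `nonsynonymous_snv`, since no
separate start-loss class is modeled. For indels the class follows length
mod 3 (`frameshift_*` when indivisible by 3); in-frame indels and MNVs are
typed by rebuilding the full mutant coding sequence — the genomic interval
`[pos, pos+len(ref)-1]` maps to a contiguous transcript-coordinate block
that is replaced by the strand-oriented alternate allele — and an in-frame
change that introduces a premature stop is reported `stopgain`. An
in-frame deletion that removes the terminal stop remains
`nonframeshift_deletion` (no stop-creation occurred).

Per variant, the call retained for filtering is the most severe across
all overlapping transcripts, with the fixed order stopgain > stoploss >
frameshift_insertion > frameshift_deletion > nonframeshift_insertion >
nonframeshift_deletion > nonsynonymous_snv > splicing > synonymous_snv >
utr > intronic > intergenic, ties broken by lexicographically smallest
transcript id. A variant overlapping nothing is `intergenic` with an
empty gene symbol.

The classifier is validated against an independent oracle that edits the
chromosome as a position-tagged base list, re-extracts the coding
sequence, translates both sequences with Biopython, and classifies from
the protein comparison; the acceptance suite requires exact agreement on
over 1000 random variant/transcript pairs on both strands. One known
asymmetry is inherent to left-aligned annotation, not to this
implementation: a deletion inside a repeat run that abuts an exon junction
left-aligns to opposite ends of the run in mirrored coordinates and can
legitimately change region class; the strand-symmetry test therefore skips
junction-adjacent repeats.

## Knowledge-base snapshots

All snapshots are local TSV files (no network access), keyed either by
normalized variant (population MAFs with `maf_1000g`/`maf_esp` columns;
known-somatic ids) or by gene symbol (drug–gene interactions with source
and curated flag; expression). Identical duplicate rows are dropped
silently (logged); duplicates with conflicting values are a load error.
Gene symbols are matched case-insensitively after trimming, with no alias
resolution — snapshot tables are assumed symbol-consistent with the gene
models. Expression aggregates multiple rows per gene by maximum, so a gene
is highly expressed if any of its entries is; the threshold is treated as
gene-level. A `compute_fpkm` helper implements
`count / ((length/1e3) * (total_mapped/1e6))` for building expression
tables from read counts on synthetic data.

## The prioritization cascade

Parameters (all exposed in `PrioritizationConfig`):

| parameter | default | units | rationale |
|---|---|---|---|
| `vaf_min` | 0.10 / 0.30 (presets) | fraction | sequencing-error floor; 10% for exome calls from homogeneous cultured cells, 30% for transcriptome calls from mixed tumor/stromal tissue |
| `maf_max` | 0.0001 | fraction | "rare" means ≤0.01% population minor allele frequency; literal reading of the printed percentage, configurable because 1% is also common practice |
| `fpkm_min` | 10.0 | FPKM | expression gate for "highly expressed" |
| `deleterious_classes` | nonsynonymous, stopgain, stoploss, frameshift ins/del | — | the deleterious set; splicing is excluded by default but configurable |
| `curated_only` | true | — | only expert-curated drug–gene interactions count |
| `maf_combine` | either | — | removal if above threshold in either database (OR); the conservative rarity reading of an ambiguous conjunction, configurable to AND |

Boundary conventions follow the defining wording: the VAF filter is a
*minimum* (inclusive ≥), the MAF and FPKM filters are *greater than*
(strict). A variant with missing VAF cannot attest to the minimum and is
removed; a variant missing from both MAF snapshots is rare (absence from
population catalogs is evidence of rarity); a gene absent from the
expression table is not highly expressed.

Druggability is per-gene, not per-allele: the interaction source is
gene-keyed, so a loss-of-function variant in a tumor suppressor is flagged
druggable exactly as the source reports it — interpreting actionability is
deliberately left to the user. Drug counts are distinct drug *names*
across the druggable RD variants (sources retained in the detail output);
whether a published "potential drugs" count means names or gene–drug pairs
is ambiguous, and distinct names is the choice here. Gene and COSMIC-id
lists in reports are sorted. The expression stage is optional: without an
expression table only the expression-filtered outputs are absent.

## Shared-mutation comparison

For each category (RD, RDD, and their highly-expressed subsets) a gene is
*shared* when at least one sample of each declared group carries a
category-qualifying variant matching at the chosen level: gene symbol,
exact normalized variant, or COSMIC id (id matching ignores position; an
id mapping to multiple variant keys is logged). With no groups declared,
an item is shared when at least two distinct samples carry it. Per gene
and group, a multi-hit flag marks ≥2 mutated group members. The report
writer asserts the category nesting (druggable ⊆ RD, expressed ⊆
unexpressed) and fails loudly on inconsistent inputs.

## The synthetic-study generator

The generator emulates the *inputs* of a profiling study — called
variants with read support, gene models, database snapshots, expression
tables — not the sequencing itself: no reads, no alignment artifacts, no
caller noise model, no fusion detection (fusion lists are pass-through
strings). Passing tests therefore demonstrate the correctness of the
filtering/annotation/joining machinery on controlled inputs, not
robustness to real-world calling artifacts, symbol mismatches between
annotation sources, or population-database version drift.

A study design gives, per sample, the fourteen profile counts to plant
(RD variants, RD genes, COSMIC-tagged subsets, druggable genes/variants,
distinct drugs, and the expression-filtered versions of each). An
allocator partitions genes into four strata (druggable × expressed),
distributes variants (each gene ≥1), COSMIC tags, and disjoint per-gene
drug-name sets, raising a named error for unrealizable designs.
Reference sequence and models are generated with 3-exon genes on both
strands: each CDS starts with ATG, ends with a stop, contains no internal
stop codon, and introns are 20–40 bp (comfortably wider than twice the
splice window). Variants of a prescribed class are crafted in transcript
coordinates and verified by the classifier before emission
(`GenerationError` otherwise); planted VAFs are exact read-count ratios
(e.g. 10/100 at the preset boundary) so boundary tests are not
float-fragile.

Decoys are planted in every filter stratum: a low-VAF variant, a variant
common in each population snapshot (one per database, exercising the OR
rule), a synonymous variant, a rare variant carrying a MAF exactly at the
threshold (must be retained), a gene whose only drug link is non-curated,
a gene expressed at exactly 10 FPKM, and a highly expressed gene with no
qualifying variant. The non-curated-drug decoy is attached to a
non-druggable RD gene (it *is* rare and deleterious; only its druggability
is the decoy), so planted counts stay exact. The manifest's expected
counts are computed by direct set arithmetic over the planted objects —
independent of the cascade code — and a self-check verifies they equal the
requested design before anything is emitted. All randomness derives from
one seeded stream; the same seed and design yield byte-identical files
(the run-metadata block written by the pipeline embeds absolute input
paths and is excluded from byte-identity comparisons).

Shared-gene specifications plant one nonsynonymous variant per listed
sample in a common gene (optionally the identical variant and/or a common
COSMIC id), on top of the per-sample designs; per-sample manifest counts
are then reported from the realized objects.

## Problem sizes

The two reference study shapes are: a cell-line-like profile (31 RD
variants over 20 genes, 6 in COSMIC, 5 druggable genes with 31 distinct
drugs; 8 RD variants / 3 druggable genes / 22 drugs after expression
filtering) and a tumor-like profile kept at desk scale (45 RD variants
over 36 genes — tumor transcriptome profiles are an order of magnitude
larger, but the cascade's behavior is size-independent and the smaller
design keeps the full suite fast). Randomized checks use ~10–15-gene
genomes, ≥1000 classifier oracle pairs, 300 normalization cases, and 50
random cascade designs.

## Known limitations

- Gene-based annotation only: one consequence per variant after severity
  reduction; no multi-codon MNV decomposition, no protein-impact scores,
  no regulatory annotation.
- `splicing` is used as a catch-all junction-spanning label (see above).
- Gene symbols are the only join key between variants, drugs, and
  expression; real studies need symbol harmonization across sources.
- The generator's decoys cover each filter once; they are guards against
  vacuous filters, not a calibration of realistic error rates.
- VCF parsing reports record-level failures with a line number only as
  far as the underlying parser allows.
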