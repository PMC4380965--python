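# varprio

Tumor variant prioritization with drug–gene and expression integration.

`varprio` takes the variants called from a tumor exome or transcriptome
(VCF or VarScan tabular output), local snapshots of population
allele-frequency, known-somatic-mutation, and drug–gene-interaction
databases, and an optional gene-expression table, and produces the lists a
molecular profiling study reports:

1. **rare and deleterious (RD) variants** — variants that pass a
   sequencing-error filter on variant allele fraction (VAF), are rare in
   the population snapshots, and have a deleterious consequence class;
2. **druggable RD (RDD) variants** and the associated **potential drugs**;
3. when expression data are available, the subsets of (1) and (2) that fall
   in **highly expressed genes**, plus the drugs for those.

It also renders per-sample profile summaries (variant counts, ts/tv ratio,
COSMIC-tagged subsets, druggable genes, drug counts) and cross-sample
shared-mutation matrices for comparing, say, cell-line profiles against
primary-tumor profiles. It is aimed at translational cancer researchers
who want a desk-scale, fully reproducible re-implementation of this kind
of integrated variant-analysis cascade, testable without any external
database downloads.

## The cascade

For each sample with called variants $v$ (normalized: trimmed and
left-aligned), the engine applies, in order:

1. **VAF filter** — keep $v$ iff $\mathrm{VAF}(v) = d_{alt}/d_{tot} \ge$
   `vaf_min` (inclusive). Presets: `cell_line_exome` = 0.10 (homogeneous
   cell population), `tumor_transcriptome` = 0.30 (mixed tumor/stromal
   cells).
2. **Consequence annotation** — classify against every overlapping gene
   model (standard genetic code; splice window ±2 bp) and keep the most
   severe call: stopgain > stoploss > frameshift > nonframeshift >
   nonsynonymous > splicing > synonymous > UTR > intronic > intergenic.
3. **Rarity filter** — remove $v$ if its minor allele frequency exceeds
   `maf_max` = 0.0001 (0.01%, strict) in *either* population snapshot
   (1000 Genomes-style or ESP-style); variants absent from both are rare.
4. **Deleteriousness filter** — keep only
   {nonsynonymous_snv, stopgain, stoploss, frameshift_insertion,
   frameshift_deletion} (configurable). Survivors are the RD set; COSMIC
   ids are attached where known.
5. **Drug matching** — each RD variant's gene is joined against the
   drug–gene interaction snapshot (expert-curated entries only, by
   default). Variants with ≥1 interaction are RDD.
6. **Expression gating** — a gene with FPKM > `fpkm_min` = 10 (strict) is
   highly expressed; RD/RDD lists are re-derived within that subset.

The ts/tv ratio reported per sample is transitions (A↔G, C↔T) over
transversions among SNVs.

## Worked example

Generate a synthetic two-sample study with planted ground truth, run the
cascade on one sample, and compare the samples:

```sh
cat > design.json <<'EOF'
{"samples": [
   {"sample_id": "S1", "preset": "cell_line_exome",
    "counts": {"n_rd": 4, "n_genes_rd": 3, "n_rdd": 1,
               "n_druggable_genes": 1, "n_drugs": 2}},
   {"sample_id": "S2", "preset": "cell_line_exome",
    "counts": {"n_rd": 3, "n_genes_rd": 2}}],
 "shared_genes": [{"samples": ["S1", "S2"]}],
 "groups": {"a": ["S1"], "b": ["S2"]}}
EOF
varprio simulate --design design.json --seed 5 --outdir study/
varprio prioritize --sample-id S1 --variants study/S1.vcf \
    --transcripts study/transcripts.tsv --reference study/reference.fa \
    --frequencies study/frequencies.tsv --cosmic study/cosmic.tsv \
    --dgi study/dgi.tsv --expression study/S1.expression.tsv \
    --preset cell_line_exome --outdir profile_S1/
```

The `prioritize` command prints the per-sample counts it computed:

```json
{
  "n_druggable_genes": 1,
  "n_druggable_genes_expressed": 0,
  "n_drugs": 2,
  "n_drugs_expressed": 0,
  "n_genes_rd": 4,
  "n_genes_rd_expressed": 0,
  "n_rd": 5,
  "n_rd_cosmic": 0,
  "n_rd_cosmic_expressed": 0,
  "n_rd_expressed": 0,
  "n_rdd": 1,
  "n_rdd_cosmic": 0,
  "n_rdd_cosmic_expressed": 0,
  "n_rdd_expressed": 0,
  "n_variants": 9
}
```

Here 9 variants were read from the VCF, 5 survived as rare and deleterious
(the 4 designed for S1 plus 1 in the gene shared with S2), they fall in 4
genes, one gene is druggable with 2 curated drugs, and none of the RD genes
clears the 10-FPKM expression gate in this small design. The decoy variants
planted by the simulator (low VAF, common in a population database,
synonymous) were filtered out, each by its own stage. `profile_S1/`
contains `rd_variants.tsv`, `rdd_variants.tsv`, `drugs.tsv`, the
expression-filtered counterparts, `profile_report.{json,tsv}` and a
`run_metadata.json` block with thresholds and input checksums.

Cross-sample comparison (which genes are mutated in both groups):

```sh
varprio compare profile_S1/ profile_S2/ --group a=S1 --group b=S2 --outdir cmp/
```

writes `shared_mutations_{rd,rdd,rd_expressed,rdd_expressed}.tsv` and
prints the shared gene lists per category, with per-sample presence and
multi-hit flags. Matching can also be done per exact variant
(`--level exact_variant`) or per COSMIC id (`--level cosmic_id`).

The same functionality is available as a library; see
`varprio.prioritize.run_cascade`, `varprio.compare.shared_mutations`, and
`varprio.simulate.generate_study`.

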