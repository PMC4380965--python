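"""Deterministic synthetic-study generator with planted ground truth.

Generates every input the cascade consumes — reference sequence, gene
models, per-sample variant calls with read counts, population-MAF /
known-somatic / drug-gene snapshot tables, and per-sample expression
tables — such that running the cascade with the matching preset reproduces
a designed profile exactly. The design is expressed as the per-sample
profile counts (the shape of one summary-table column); an allocator turns
those counts into per-gene plans and raises a named error when the design
is unrealizable.

Decoys are planted in every filter stratum: a low-VAF variant, variants
common in each population database, a synonymous variant, a gene whose only
drug link is non-curated, a gene expressed at exactly the FPKM threshold,
and a highly expressed gene with no qualifying variant. Each decoy is
silently dropped by exactly one cascade stage; a filter that stopped
filtering would change the planted counts.

Everything derives from a single seeded pseudo-random stream; the same seed
and design produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import random

import pandas as pd

from .consequence import CODON_TO_AA, classify
from .errors import GenerationError
from .knowledge import CosmicTable, DgiTable, DrugGeneInteraction, ExpressionTable, FrequencyTable
from .prioritize import PRESETS
from .reference import DictReference
from .transcripts import (
    TranscriptModel,
    revcomp,
    write_transcripts_gtf,
    write_transcripts_tsv,
)
from .variants import Variant, VariantKey, normalize_variant, write_variants

log = logging.getLogger(__name__)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP = tuple(c for c in CODON_TO_AA if CODON_TO_AA[c] != "*")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

CHROM = "chr1"


# ---------------------------------------------------------------------------
# Design types


@dataclass(frozen=True)
class ProfileCounts:
    """Requested per-sample profile shape (the planted ground truth)."""

    n_rd: int = 0
    n_genes_rd: int = 0
    n_rd_cosmic: int = 0
    n_rdd: int = 0
    n_rdd_cosmic: int = 0
    n_druggable_genes: int = 0
    n_drugs: int = 0
    n_rd_expressed: int = 0
    n_genes_rd_expressed: int = 0
    n_rd_cosmic_expressed: int = 0
    n_rdd_expressed: int = 0
    n_rdd_cosmic_expressed: int = 0
    n_druggable_genes_expressed: int = 0
    n_drugs_expressed: int = 0

    @classmethod
    def cell_line_shape(cls) -> "ProfileCounts":
        """The MIA PaCa2-like column: 31 RD over 20 genes, 5 druggable."""
        return cls(
            n_rd=31, n_genes_rd=20, n_rd_cosmic=6, n_rdd=5, n_rdd_cosmic=3,
            n_druggable_genes=5, n_drugs=31, n_rd_expressed=8, n_genes_rd_expressed=5,
            n_rd_cosmic_expressed=3, n_rdd_expressed=3, n_rdd_cosmic_expressed=3,
            n_druggable_genes_expressed=3, n_drugs_expressed=22,
        )

    @classmethod
    def tumor_shape(cls) -> "ProfileCounts":
        """A primary-tumor-like column at desk scale (~1/10 size)."""
        return cls(
            n_rd=45, n_genes_rd=36, n_rd_cosmic=3, n_rdd=4, n_rdd_cosmic=1,
            n_druggable_genes=4, n_drugs=14, n_rd_expressed=15, n_genes_rd_expressed=12,
            n_rd_cosmic_expressed=1, n_rdd_expressed=3, n_rdd_cosmic_expressed=1,
            n_druggable_genes_expressed=3, n_drugs_expressed=13,
        )


@dataclass
class SampleDesign:
    sample_id: str
    counts: ProfileCounts
    preset: str = "cell_line_exome"
    fusions: list[str] = field(default_factory=list)


@dataclass
class SharedGeneSpec:
    """A gene planted with one RD variant in each listed sample."""

    samples: list[str]
    druggable: bool = False
    expressed: bool = False
    same_variant: bool = False
    cosmic: bool = False
    n_drugs: int = 1


@dataclass
class StudyDesign:
    samples: list[SampleDesign]
    shared_genes: list[SharedGeneSpec] = field(default_factory=list)
    groups: Optional[dict[str, list[str]]] = None


# ---------------------------------------------------------------------------
# Allocation: profile counts -> per-gene plans


@dataclass
class GenePlan:
    druggable: bool
    expressed: bool
    n_variants: int
    n_cosmic: int = 0
    n_drugs: int = 0
    noncurated_decoy: bool = False
    gene: str = ""


def _require(cond: bool, constraint: str) -> None:
    if not cond:
        raise GenerationError(f"unrealizable design: {constraint}")


def allocate(c: ProfileCounts) -> list[GenePlan]:
    """Turn a requested profile shape into per-gene plans, or raise."""
    for f in dataclasses.fields(c):
        _require(getattr(c, f.name) >= 0, f"{f.name} must be non-negative")
    n_de = c.n_druggable_genes_expressed
    n_dn = c.n_druggable_genes - n_de
    _require(n_dn >= 0, "n_druggable_genes_expressed <= n_druggable_genes")
    n_ne = c.n_genes_rd_expressed - n_de
    _require(n_ne >= 0, "n_druggable_genes_expressed <= n_genes_rd_expressed")
    n_nn = c.n_genes_rd - c.n_druggable_genes - n_ne
    _require(n_nn >= 0, "druggable + expressed-only genes <= n_genes_rd")

    v_de = c.n_rdd_expressed
    v_dn = c.n_rdd - v_de
    _require(v_dn >= 0, "n_rdd_expressed <= n_rdd")
    v_ne = c.n_rd_expressed - v_de
    _require(v_ne >= 0, "n_rdd_expressed <= n_rd_expressed")
    v_nn = c.n_rd - v_de - v_dn - v_ne
    _require(v_nn >= 0, "n_rdd + non-druggable expressed variants <= n_rd")

    strata = [
        ("druggable expressed", n_de, v_de, True, True),
        ("druggable non-expressed", n_dn, v_dn, True, False),
        ("non-druggable expressed", n_ne, v_ne, False, True),
        ("non-druggable non-expressed", n_nn, v_nn, False, False),
    ]
    for name, n_genes, n_vars, *_ in strata:
        _require(not (n_genes == 0 and n_vars > 0), f"{name}: variants without genes")
        _require(
            not (n_genes > 0 and n_vars < n_genes),
            f"{name}: need >= 1 variant per gene ({n_genes} genes, {n_vars} variants)",
        )

    c_de = c.n_rdd_cosmic_expressed
    _require(c_de <= v_de, "n_rdd_cosmic_expressed <= n_rdd_expressed")
    c_dn = c.n_rdd_cosmic - c_de
    _require(0 <= c_dn <= v_dn, "n_rdd_cosmic consistent with n_rdd split")
    c_ne = c.n_rd_cosmic_expressed - c_de
    _require(0 <= c_ne <= v_ne, "n_rd_cosmic_expressed consistent with expressed variants")
    c_nn = c.n_rd_cosmic - c_de - c_dn - c_ne
    _require(0 <= c_nn <= v_nn, "n_rd_cosmic consistent with variant strata")

    d_de = c.n_drugs_expressed
    d_dn = c.n_drugs - d_de
    _require(d_dn >= 0, "n_drugs_expressed <= n_drugs")
    _require(not (n_de == 0 and d_de > 0), "expressed drugs without expressed druggable genes")
    _require(not (n_de > 0 and d_de < n_de), "need >= 1 drug per expressed druggable gene")
    _require(not (n_dn == 0 and d_dn > 0), "non-expressed drugs without druggable genes")
    _require(not (n_dn > 0 and d_dn < n_dn), "need >= 1 drug per druggable gene")

    plans: list[GenePlan] = []
    for (name, n_genes, n_vars, druggable, expressed), n_cos, n_drugs in zip(
        strata, (c_de, c_dn, c_ne, c_nn), (d_de, d_dn, 0, 0)
    ):
        if n_genes == 0:
            continue
        per_gene = [n_vars // n_genes] * n_genes
        for i in range(n_vars % n_genes):
            per_gene[i] += 1
        cos = [0] * n_genes
        remaining = n_cos
        for i in range(n_genes):
            take = min(per_gene[i], remaining)
            cos[i] = take
            remaining -= take
        _require(remaining == 0, f"{name}: cannot place {remaining} cosmic tags")
        drugs = [0] * n_genes
        if druggable:
            drugs = [1] * n_genes
            drugs[0] += n_drugs - n_genes
        for i in range(n_genes):
            plans.append(
                GenePlan(
                    druggable=druggable,
                    expressed=expressed,
                    n_variants=per_gene[i],
                    n_cosmic=cos[i],
                    n_drugs=drugs[i],
                )
            )
    # reserve the non-curated-drug decoy on a non-druggable gene when possible
    for plan in plans:
        if not plan.druggable and not plan.expressed:
            plan.noncurated_decoy = True
            break
    else:
        for plan in plans:
            if not plan.druggable:
                plan.noncurated_decoy = True
                break
    return plans


# ---------------------------------------------------------------------------
# Reference and gene-model generation


def _rand_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _build_gene_region(rng: random.Random):
    """One 3-exon gene region in its own coordinates (1-based)."""
    n_codons = rng.randint(30, 60)
    cds = "ATG" + "".join(rng.choice(_NONSTOP) for _ in range(n_codons - 2)) + rng.choice(_STOPS)
    u5, u3 = _rand_dna(rng, rng.randint(8, 15)), _rand_dna(rng, rng.randint(8, 15))
    a = rng.randint(9, len(cds) - 18)
    b = rng.randint(a + 9, len(cds) - 9)
    i1, i2 = _rand_dna(rng, rng.randint(20, 40)), _rand_dna(rng, rng.randint(20, 40))
    seq = u5 + cds[:a] + i1 + cds[a:b] + i2 + cds[b:] + u3
    e1 = (1, len(u5) + a)
    e2s = e1[1] + len(i1) + 1
    e2 = (e2s, e2s + (b - a) - 1)
    e3s = e2[1] + len(i2) + 1
    e3 = (e3s, e3s + (len(cds) - b) + len(u3) - 1)
    exons = [e1, e2, e3]
    cds_ivs = [(len(u5) + 1, e1[1]), e2, (e3s, e3s + (len(cds) - b) - 1)]
    strand = rng.choice("+-")
    if strand == "-":
        L = len(seq)
        seq = revcomp(seq)
        exons = sorted((L + 1 - e, L + 1 - s) for s, e in exons)
        cds_ivs = sorted((L + 1 - e, L + 1 - s) for s, e in cds_ivs)
    return seq, exons, cds_ivs, strand


def build_genome(
    rng: random.Random, n_genes: int, chrom: str = CHROM, chrom_length: Optional[int] = None
) -> tuple[DictReference, list[TranscriptModel]]:
    """Random reference with ``n_genes`` non-overlapping multi-exon genes."""
    if n_genes < 1:
        raise GenerationError("n_genes must be >= 1")
    pieces, models = [], []
    offset = 0
    for i in range(n_genes):
        gap = _rand_dna(rng, rng.randint(30, 60))
        pieces.append(gap)
        offset += len(gap)
        seq, exons, cds_ivs, strand = _build_gene_region(rng)
        pieces.append(seq)
        models.append(
            TranscriptModel(
                transcript_id=f"TX{i:04d}",
                gene_symbol=f"GENE{i:04d}",
                chrom=chrom,
                strand=strand,
                exons=tuple((s + offset, e + offset) for s, e in exons),
                cds=tuple((s + offset, e + offset) for s, e in cds_ivs),
            )
        )
        offset += len(seq)
    pieces.append(_rand_dna(rng, rng.randint(30, 60)))
    full = "".join(pieces)
    if chrom_length is not None:
        if chrom_length < len(full):
            raise GenerationError(
                f"chrom_length {chrom_length} too short for {n_genes} genes (need {len(full)})"
            )
        full = full + _rand_dna(rng, chrom_length - len(full))
    reference = DictReference({chrom: full})
    for m in models:
        m.reference = reference
    return reference, models


def generate_reference_and_transcripts(
    seed: int,
    n_genes: int,
    outdir: str | Path,
    chrom_length: Optional[int] = None,
) -> tuple[Path, Path, Path]:
    """Write a random FASTA plus matching gene-model TSV and GTF files."""
    rng = random.Random(seed)
    reference, models = build_genome(rng, n_genes, chrom_length=chrom_length)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "reference.fa"
    _write_fasta(reference, fasta)
    tsv = outdir / "transcripts.tsv"
    gtf = outdir / "transcripts.gtf"
    write_transcripts_tsv(models, tsv)
    write_transcripts_gtf(models, gtf)
    return fasta, tsv, gtf


def _write_fasta(reference: DictReference, path: Path) -> None:
    records = [
        SeqRecord(Seq(reference.fetch(c, 1, reference.length(c))), id=c, description="")
        for c in reference.contigs()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Variant planting


class _Planter:
    """Crafts variants of a prescribed consequence class inside one gene."""

    def __init__(self, rng: random.Random, reference: DictReference, used: set[VariantKey]):
        self.rng = rng
        self.reference = reference
        self.used = used

    def _base(self, pos: int) -> str:
        return self.reference.fetch(CHROM, pos, pos)

    def _register(self, sample_id: str, pos: int, ref: str, alt: str,
                  alt_depth: int, total_depth: int) -> Variant:
        v = Variant(sample_id, CHROM, pos, ref, alt, total_depth=total_depth, alt_depth=alt_depth)
        v = normalize_variant(v, self.reference)
        return v

    def snv(self, sample_id: str, model: TranscriptModel, kind: str,
            alt_depth: int, total_depth: int) -> Variant:
        """Plant an SNV of kind synonymous/nonsynonymous/stopgain."""
        from .transcripts import build_cds

        cds_seq = build_cds(model, self.reference)
        positions = model.cds_positions()
        codon_order = list(range(1, len(cds_seq) // 3 - 1))
        self.rng.shuffle(codon_order)
        for k in codon_order:
            codon = cds_seq[3 * k : 3 * k + 3]
            offsets = [0, 1, 2]
            self.rng.shuffle(offsets)
            for off in offsets:
                alts = [b for b in _BASES if b != codon[off]]
                self.rng.shuffle(alts)
                for nb in alts:
                    new_codon = codon[:off] + nb + codon[off + 1 :]
                    aa0, aa1 = CODON_TO_AA[codon], CODON_TO_AA[new_codon]
                    ok = (
                        (kind == "synonymous" and aa0 == aa1)
                        or (kind == "nonsynonymous" and aa0 != aa1 and aa1 != "*" and aa0 != "*")
                        or (kind == "stopgain" and aa1 == "*" and aa0 != "*")
                    )
                    if not ok:
                        continue
                    i = 3 * k + off
                    pos = positions[i]
                    gref = self._base(pos)
                    galt = nb if model.strand == "+" else revcomp(nb)
                    key = VariantKey(CHROM, pos, gref, galt)
                    if key in self.used or gref == galt:
                        continue
                    self.used.add(key)
                    return self._register(sample_id, pos, gref, galt, alt_depth, total_depth)
        raise GenerationError(f"could not plant {kind} SNV in {model.gene_symbol}")

    def frameshift(self, sample_id: str, model: TranscriptModel, insertion: bool,
                   alt_depth: int, total_depth: int) -> Variant:
        """Plant a 1-bp coding frameshift (left-aligned by construction)."""
        intervals = [iv for iv in model.cds if iv[1] - iv[0] + 1 >= 10]
        self.rng.shuffle(intervals)
        want = "frameshift_insertion" if insertion else "frameshift_deletion"
        for s, e in intervals:
            candidates = list(range(s + 3, e - 3))
            self.rng.shuffle(candidates)
            for g in candidates:
                if insertion:
                    anchor = self._base(g)
                    choices = [b for b in _BASES if b != anchor]
                    self.rng.shuffle(choices)
                    ref, alt, pos = anchor, anchor + choices[0], g
                else:
                    pos = g - 1
                    ref, alt = self._base(pos) + self._base(g), self._base(pos)
                try:
                    v = self._register(sample_id, pos, ref, alt, alt_depth, total_depth)
                except Exception:
                    continue
                if v.key in self.used:
                    continue
                call = classify(v, model, self.reference)
                if call.klass != want:
                    continue
                self.used.add(v.key)
                return v
        raise GenerationError(f"could not plant {want} in {model.gene_symbol}")


def _is_transition(v: Variant) -> bool:
    return (v.ref, v.alt) in _TRANSITIONS


# ---------------------------------------------------------------------------
# Study generation


@dataclass
class StudyBundle:
    design: StudyDesign
    seed: int
    reference: DictReference
    models: list[TranscriptModel]
    variants: dict[str, list[Variant]]
    frequency_table: FrequencyTable
    cosmic_table: CosmicTable
    dgi_table: DgiTable
    expression: dict[str, ExpressionTable]
    manifest: dict
    paths: dict = field(default_factory=dict)


# deleterious classes cycled through when planting RD variants
_RD_KINDS = ("nonsynonymous", "nonsynonymous", "stopgain", "frameshift_deletion",
             "nonsynonymous", "frameshift_insertion")


def generate_study(
    seed: int, design: StudyDesign, outdir: Optional[str | Path] = None
) -> StudyBundle:
    """Generate all pipeline inputs for a designed study, plus the manifest."""
    rng = random.Random(seed)
    sample_ids = [s.sample_id for s in design.samples]
    if len(set(sample_ids)) != len(sample_ids):
        raise GenerationError("duplicate sample ids in design")
    for spec in design.shared_genes:
        unknown = [s for s in spec.samples if s not in sample_ids]
        if unknown:
            raise GenerationError(f"shared gene references unknown samples {unknown}")
    if design.groups:
        for g, members in design.groups.items():
            unknown = [s for s in members if s not in sample_ids]
            if unknown:
                raise GenerationError(f"group {g!r} references unknown samples {unknown}")

    allocations = {s.sample_id: allocate(s.counts) for s in design.samples}
    for s in design.samples:
        if s.preset not in PRESETS:
            raise GenerationError(f"sample {s.sample_id}: unknown preset {s.preset!r}")

    n_plan_genes = sum(len(p) for p in allocations.values())
    n_genes = n_plan_genes + len(design.shared_genes) + 1  # +1 decoy-only gene
    reference, models = build_genome(rng, n_genes)
    gene_iter = iter(models)
    decoy_model = next(gene_iter)

    used: set[VariantKey] = set()
    planter = _Planter(rng, reference, used)

    # assign concrete genes to plans and shared specs
    for sid in sample_ids:
        for plan in allocations[sid]:
            m = next(gene_iter)
            plan.gene = m.gene_symbol
            plan.model = m  # type: ignore[attr-defined]
    shared_models = {}
    for i, spec in enumerate(design.shared_genes):
        shared_models[i] = next(gene_iter)

    freq_rows: list[dict] = []
    cosmic_rows: list[dict] = []
    dgi_rows: list[dict] = []
    drug_counter = 0
    cosmic_counter = 500

    def next_drugs(n: int) -> list[str]:
        nonlocal drug_counter
        names = [f"DRUG{drug_counter + j:04d}" for j in range(n)]
        drug_counter += n
        return names

    def next_cosmic() -> str:
        nonlocal cosmic_counter
        cosmic_counter += 1
        return f"COSMIC{cosmic_counter}"

    variants: dict[str, list[Variant]] = {sid: [] for sid in sample_ids}
    # per-sample planted RD descriptors: (gene, druggable, expressed, cosmic_id, drug_names)
    planted: dict[str, list[tuple]] = {sid: [] for sid in sample_ids}
    expression_rows: dict[str, list[tuple[str, float]]] = {sid: [] for sid in sample_ids}

    for sample in design.samples:
        sid = sample.sample_id
        vaf_min = PRESETS[sample.preset]
        kept_depths = [(int(round(vaf_min * 100)), 100)] + [(50, 100)] * 10_000
        kept_i = 0
        kind_i = 0
        nonexpr_i = 0
        boundary_maf_used = False
        for plan in allocations[sid]:
            model = plan.model  # type: ignore[attr-defined]
            drug_names = next_drugs(plan.n_drugs) if plan.druggable else []
            if plan.druggable:
                for j, name in enumerate(drug_names):
                    dgi_rows.append(
                        {"gene": plan.gene, "drug": name,
                         "interaction_type": "inhibitor" if j % 2 == 0 else "",
                         "source": "SRC_A", "curated": "true"}
                    )
            if plan.noncurated_decoy:
                dgi_rows.append(
                    {"gene": plan.gene, "drug": f"NONCUR_{plan.gene}",
                     "interaction_type": "", "source": "SRC_X", "curated": "false"}
                )
            if plan.expressed:
                expression_rows[sid].append((plan.gene, float(rng.choice([12.5, 25.0, 150.0]))))
            else:
                # cycle the not-highly-expressed strata: exactly-at-threshold
                # (boundary decoy), clearly low, and absent from the table
                if nonexpr_i % 3 == 0:
                    expression_rows[sid].append((plan.gene, 10.0))
                elif nonexpr_i % 3 == 1:
                    expression_rows[sid].append((plan.gene, 3.0))
                nonexpr_i += 1
            for vi in range(plan.n_variants):
                kind = _RD_KINDS[kind_i % len(_RD_KINDS)]
                kind_i += 1
                alt_d, tot_d = kept_depths[kept_i]
                kept_i += 1
                if kind.startswith("frameshift"):
                    v = planter.frameshift(sid, model, kind.endswith("insertion"), alt_d, tot_d)
                else:
                    v = planter.snv(sid, model, kind, alt_d, tot_d)
                variants[sid].append(v)
                cid = None
                if vi < plan.n_cosmic:
                    cid = next_cosmic()
                    cosmic_rows.append(
                        {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                         "cosmic_id": cid}
                    )
                if not boundary_maf_used:
                    # rare-boundary decoy: MAF exactly at threshold is retained
                    freq_rows.append(
                        {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                         "maf_1000g": "0.0001", "maf_esp": ""}
                    )
                    boundary_maf_used = True
                planted[sid].append(
                    (plan.gene, plan.druggable, plan.expressed, cid, tuple(drug_names))
                )
        # decoy stratum variants, planted in the dedicated decoy gene
        decoy_specs = [
            ("low_vaf", "nonsynonymous", max(int(round(vaf_min * 100)) - 5, 0), 100),
            ("common_1kg", "nonsynonymous", 50, 100),
            ("common_esp", "nonsynonymous", 50, 100),
            ("synonymous", "synonymous", 50, 100),
        ]
        for label, kind, alt_d, tot_d in decoy_specs:
            v = planter.snv(sid, decoy_model, kind, alt_d, tot_d)
            variants[sid].append(v)
            if label == "common_1kg":
                freq_rows.append(
                    {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                     "maf_1000g": "0.001", "maf_esp": ""}
                )
            elif label == "common_esp":
                freq_rows.append(
                    {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                     "maf_1000g": "", "maf_esp": "0.001"}
                )
        # highly expressed decoy gene with no qualifying variant
        expression_rows[sid].append((decoy_model.gene_symbol, 50.0))

    # shared genes across samples
    for i, spec in enumerate(design.shared_genes):
        model = shared_models[i]
        drug_names = next_drugs(spec.n_drugs) if spec.druggable else []
        for j, name in enumerate(drug_names):
            dgi_rows.append(
                {"gene": model.gene_symbol, "drug": name,
                 "interaction_type": "inhibitor" if j % 2 == 0 else "",
                 "source": "SRC_A", "curated": "true"}
            )
        shared_variant = None
        shared_cid = next_cosmic() if spec.cosmic else None
        for sid in spec.samples:
            sample = next(s for s in design.samples if s.sample_id == sid)
            vaf = PRESETS[sample.preset]
            if spec.same_variant and shared_variant is not None:
                v = dataclasses.replace(shared_variant, sample_id=sid)
            else:
                v = planter.snv(sid, model, "nonsynonymous", 50, 100)
                if spec.same_variant:
                    shared_variant = v
                if spec.cosmic:
                    cid = shared_cid if spec.same_variant else next_cosmic()
                    cosmic_rows.append(
                        {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                         "cosmic_id": cid}
                    )
            variants[sid].append(v)
            cid_here = None
            if spec.cosmic:
                cid_here = shared_cid if spec.same_variant else cosmic_rows[-1]["cosmic_id"]
            planted[sid].append(
                (model.gene_symbol, spec.druggable, spec.expressed, cid_here, tuple(drug_names))
            )
            if spec.expressed:
                expression_rows[sid].append((model.gene_symbol, 30.0))

    frequency_table = _freq_table(freq_rows)
    cosmic_table = CosmicTable(
        {VariantKey(r["chrom"], int(r["pos"]), r["ref"], r["alt"]): r["cosmic_id"]
         for r in cosmic_rows}
    )
    dgi_table = DgiTable(
        [DrugGeneInteraction(r["gene"], r["drug"], r["interaction_type"] or None,
                             r["source"], r["curated"] == "true")
         for r in dgi_rows]
    )
    expression = {
        sid: ExpressionTable(dict(rows)) for sid, rows in expression_rows.items()
    }

    manifest = _build_manifest(seed, design, variants, planted)
    bundle = StudyBundle(
        design=design, seed=seed, reference=reference, models=models,
        variants=variants, frequency_table=frequency_table, cosmic_table=cosmic_table,
        dgi_table=dgi_table, expression=expression, manifest=manifest,
    )
    _self_check(bundle, allocations)
    if outdir is not None:
        _write_bundle(bundle, Path(outdir), freq_rows, cosmic_rows, dgi_rows, expression_rows)
    return bundle


def _freq_table(rows: list[dict]) -> FrequencyTable:
    from .knowledge import FrequencyRecord

    records = {}
    for r in rows:
        key = VariantKey(r["chrom"], int(r["pos"]), r["ref"], r["alt"])
        records[key] = FrequencyRecord(
            key=key,
            maf_1000g=float(r["maf_1000g"]) if r["maf_1000g"] else None,
            maf_esp=float(r["maf_esp"]) if r["maf_esp"] else None,
        )
    return FrequencyTable(records)


def _expected_counts(descriptors: list[tuple]) -> dict:
    """Planted-truth arithmetic over (gene, druggable, expressed, cosmic, drugs)."""

    def block(rows):
        rdd = [r for r in rows if r[1]]
        return {
            "n_rd": len(rows),
            "n_rd_cosmic": sum(1 for r in rows if r[3] is not None),
            "cosmic_ids": sorted({r[3] for r in rows if r[3] is not None}),
            "n_genes_rd": len({r[0] for r in rows}),
            "n_rdd": len(rdd),
            "n_rdd_cosmic": sum(1 for r in rdd if r[3] is not None),
            "druggable_genes": sorted({r[0] for r in rdd}),
            "n_druggable_genes": len({r[0] for r in rdd}),
            "n_drugs": len({d for r in rdd for d in r[4]}),
        }

    base = block(descriptors)
    expr = block([r for r in descriptors if r[2]])
    out = dict(base)
    for k, v in expr.items():
        out[f"{k}_expressed"] = v
    return out


def _build_manifest(seed, design, variants, planted) -> dict:
    manifest: dict = {"seed": seed, "samples": {}, "groups": design.groups}
    for sample in design.samples:
        sid = sample.sample_id
        vs = variants[sid]
        ts = sum(1 for v in vs if v.is_snv and _is_transition(v))
        tv = sum(1 for v in vs if v.is_snv and not _is_transition(v))
        expected = _expected_counts(planted[sid])
        expected["n_variants"] = len(vs)
        expected["tstv_ratio"] = (ts / tv) if tv else None
        manifest["samples"][sid] = {
            "preset": sample.preset,
            "fusions": list(sample.fusions),
            "expected": expected,
        }
    # planted shared gene sets per category, at gene level
    if design.groups:
        cat_sets = {}
        per_sample = {
            sid: {
                "rd": {r[0] for r in planted[sid]},
                "rdd": {r[0] for r in planted[sid] if r[1]},
                "rd_expressed": {r[0] for r in planted[sid] if r[2]},
                "rdd_expressed": {r[0] for r in planted[sid] if r[1] and r[2]},
            }
            for sid in variants
        }
        for cat in ("rd", "rdd", "rd_expressed", "rdd_expressed"):
            group_unions = [
                set().union(*(per_sample[s][cat] for s in members))
                for members in design.groups.values()
            ]
            cat_sets[cat] = sorted(set.intersection(*group_unions)) if group_unions else []
        manifest["shared"] = cat_sets
    return manifest


def _self_check(bundle: StudyBundle, allocations) -> None:
    """Verify requested counts are exactly realized by the planted objects."""
    for sample in bundle.design.samples:
        sid = sample.sample_id
        expected = bundle.manifest["samples"][sid]["expected"]
        shared_here = any(sid in spec.samples for spec in bundle.design.shared_genes)
        if shared_here:
            continue  # realized counts legitimately exceed the requested shape
        req = sample.counts
        for f in dataclasses.fields(req):
            if getattr(req, f.name) != expected[f.name]:
                raise GenerationError(
                    f"self-check failed for {sid}: {f.name} requested "
                    f"{getattr(req, f.name)} but realized {expected[f.name]}"
                )


def _write_bundle(bundle, outdir: Path, freq_rows, cosmic_rows, dgi_rows, expression_rows) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _write_fasta(bundle.reference, outdir / "reference.fa")
    write_transcripts_tsv(bundle.models, outdir / "transcripts.tsv")
    write_transcripts_gtf(bundle.models, outdir / "transcripts.gtf")
    rel = {
        "reference": "reference.fa",
        "transcripts_tsv": "transcripts.tsv",
        "transcripts_gtf": "transcripts.gtf",
        "frequencies": "frequencies.tsv",
        "cosmic": "cosmic.tsv",
        "dgi": "dgi.tsv",
        "samples": {},
    }
    paths = {k: str(outdir / v) for k, v in rel.items() if k != "samples"}
    paths["samples"] = {}
    pd.DataFrame(
        sorted(freq_rows, key=lambda r: (r["chrom"], int(r["pos"]), r["ref"], r["alt"])),
        columns=["chrom", "pos", "ref", "alt", "maf_1000g", "maf_esp"],
    ).to_csv(outdir / "frequencies.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(cosmic_rows, key=lambda r: (r["chrom"], int(r["pos"]), r["ref"], r["alt"])),
        columns=["chrom", "pos", "ref", "alt", "cosmic_id"],
    ).to_csv(outdir / "cosmic.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(dgi_rows, key=lambda r: (r["gene"], r["drug"], r["source"])),
        columns=["gene", "drug", "interaction_type", "source", "curated"],
    ).to_csv(outdir / "dgi.tsv", sep="\t", index=False)
    for sid, vs in bundle.variants.items():
        vcf_path = outdir / f"{sid}.vcf"
        write_variants(vs, vcf_path, format="vcf")
        expr_path = outdir / f"{sid}.expression.tsv"
        pd.DataFrame(
            sorted(expression_rows[sid]), columns=["gene", "fpkm"]
        ).to_csv(expr_path, sep="\t", index=False)
        fusions = bundle.manifest["samples"][sid]["fusions"]
        fus_path = outdir / f"{sid}.fusions.tsv"
        pd.DataFrame({"fusion": fusions}).to_csv(fus_path, sep="\t", index=False)
        paths["samples"][sid] = {
            "vcf": str(vcf_path), "expression": str(expr_path), "fusions": str(fus_path)
        }
        rel["samples"][sid] = {
            "vcf": f"{sid}.vcf", "expression": f"{sid}.expression.tsv",
            "fusions": f"{sid}.fusions.tsv",
        }
    bundle.paths = paths
    manifest = dict(bundle.manifest)
    manifest["paths"] = rel
    bundle.manifest = manifest
    with open(outdir / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
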