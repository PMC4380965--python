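"""File-level pipeline runs binding the modules together.

``run_prioritize`` reads all inputs from disk, runs the cascade for one
sample, and writes the output tables plus a run-metadata block recording
the preset, every threshold that affected the output, and input checksums
(so a run can be reproduced and audited). ``run_compare`` reads previously
written profile directories and builds the shared-mutation matrices.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import compare as compare_mod
from .errors import ConfigurationError
from .knowledge import CosmicTable, DgiTable, DrugGeneInteraction, ExpressionTable, FrequencyTable
from .prioritize import (
    AnnotatedVariant,
    CascadeResult,
    PrioritizationConfig,
    ProfileReport,
    run_cascade,
    summarize,
    write_outputs,
)
from .consequence import ConsequenceCall
from .reference import FastaReference
from .transcripts import TranscriptIndex, load_transcripts_gtf, load_transcripts_tsv
from .variants import Variant, read_varscan_table, read_vcf

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and settings for one prioritization run."""

    sample_id: str
    variants: str  # VCF or VarScan TSV path
    transcripts: str  # GTF or transcript TSV path
    reference: str  # FASTA path
    frequencies: Optional[str] = None
    cosmic: Optional[str] = None
    dgi: Optional[str] = None
    expression: Optional[str] = None
    expression_dialect: str = "plain"
    fusions: Optional[str] = None
    outdir: str = "."
    preset: str = "custom"
    variant_format: str = "auto"  # auto | vcf | varscan
    overrides: dict = field(default_factory=dict)

    def prioritization_config(self) -> PrioritizationConfig:
        return PrioritizationConfig.from_preset(self.preset, **self.overrides)

    def input_paths(self) -> dict[str, str]:
        paths = {
            "variants": self.variants,
            "transcripts": self.transcripts,
            "reference": self.reference,
        }
        for name in ("frequencies", "cosmic", "dgi", "expression", "fusions"):
            value = getattr(self, name)
            if value is not None:
                paths[name] = value
        return paths


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_variants(cfg: RunConfig, reference) -> list[Variant]:
    fmt = cfg.variant_format
    if fmt == "auto":
        fmt = "vcf" if cfg.variants.endswith((".vcf", ".vcf.gz")) else "varscan"
    if fmt == "vcf":
        return read_vcf(cfg.variants, cfg.sample_id, reference=reference)
    if fmt == "varscan":
        return read_varscan_table(cfg.variants, cfg.sample_id, reference=reference)
    raise ConfigurationError(f"unknown variant format {fmt!r}")


def _load_transcripts(path: str, reference) -> TranscriptIndex:
    if path.endswith((".gtf", ".gff")):
        models = load_transcripts_gtf(path, reference)
    else:
        models = load_transcripts_tsv(path, reference)
    return TranscriptIndex(models)


def _load_fusions(path: Optional[str]) -> list[str]:
    if path is None:
        return []
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "fusion" not in df.columns:
        raise ConfigurationError(f"fusion table {path} missing 'fusion' column")
    return [f for f in df["fusion"].tolist() if f]


def run_prioritize(cfg: RunConfig) -> tuple[CascadeResult, ProfileReport]:
    """Run the full prioritization pipeline for one sample, writing outputs."""
    for name, path in cfg.input_paths().items():
        if not Path(path).exists():
            raise ConfigurationError(f"input {name!r} not found: {path}")
    pcfg = cfg.prioritization_config()
    reference = FastaReference(cfg.reference)
    transcripts = _load_transcripts(cfg.transcripts, reference)
    variants = _load_variants(cfg, reference)
    frequencies = FrequencyTable.from_tsv(cfg.frequencies) if cfg.frequencies else None
    cosmic = CosmicTable.from_tsv(cfg.cosmic) if cfg.cosmic else None
    dgi = DgiTable.from_tsv(cfg.dgi) if cfg.dgi else None
    expression = (
        ExpressionTable.from_tsv(cfg.expression, dialect=cfg.expression_dialect)
        if cfg.expression
        else None
    )
    fusions = _load_fusions(cfg.fusions)
    result = run_cascade(
        cfg.sample_id, variants, transcripts, frequencies, cosmic, dgi, expression, pcfg,
        reference=reference,
    )
    report = summarize(result, fusions=fusions)
    outdir = Path(cfg.outdir)
    write_outputs(outdir, result, report)
    metadata = {
        "sample_id": cfg.sample_id,
        "config": pcfg.to_dict(),
        "inputs": {name: {"path": path, "sha256": _sha256(path)}
                   for name, path in sorted(cfg.input_paths().items())},
        "expression_available": result.expression_available,
    }
    with open(outdir / "run_metadata.json", "wt") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result, report


def run_bundle_sample(bundle, sample_id: str, **config_overrides) -> tuple[CascadeResult, ProfileReport]:
    """Run the cascade for one sample of an in-memory synthetic study bundle."""
    sample = next(s for s in bundle.design.samples if s.sample_id == sample_id)
    pcfg = PrioritizationConfig.from_preset(sample.preset, **config_overrides)
    index = TranscriptIndex(bundle.models)
    result = run_cascade(
        sample_id,
        bundle.variants[sample_id],
        index,
        bundle.frequency_table,
        bundle.cosmic_table,
        bundle.dgi_table,
        bundle.expression.get(sample_id),
        pcfg,
        reference=bundle.reference,
    )
    return result, summarize(result, fusions=sample.fusions)


def load_profile(profile_dir: str | Path) -> tuple[str, list[AnnotatedVariant], dict]:
    """Read one prioritization output directory back into RD variant records."""
    profile_dir = Path(profile_dir)
    report_path = profile_dir / "profile_report.json"
    rd_path = profile_dir / "rd_variants.tsv"
    if not report_path.exists() or not rd_path.exists():
        raise ConfigurationError(f"{profile_dir} is not a profile output directory")
    with open(report_path) as fh:
        report = json.load(fh)
    df = pd.read_csv(rd_path, sep="\t", dtype=str, keep_default_na=False)
    avs = []
    for _, row in df.iterrows():
        drugs = tuple(
            DrugGeneInteraction(row["gene"], d, None, "profile", True)
            for d in row["drugs"].split("|")
            if d
        )
        avs.append(
            AnnotatedVariant(
                variant=Variant(
                    sample_id=row["sample_id"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    vaf=float(row["vaf"]) if row["vaf"] != "" else None,
                ),
                consequence=ConsequenceCall(
                    gene_symbol=row["gene"],
                    transcript_id=row["transcript_id"],
                    klass=row["class"],
                    codon_change=row["codon_change"] or None,
                    aa_change=row["aa_change"] or None,
                ),
                maf_1000g=float(row["maf_1000g"]) if row["maf_1000g"] != "" else None,
                maf_esp=float(row["maf_esp"]) if row["maf_esp"] != "" else None,
                cosmic_id=row["cosmic_id"] or None,
                fpkm=float(row["fpkm"]) if row["fpkm"] != "" else None,
                highly_expressed=row["highly_expressed"] == "true",
                drugs=drugs,
            )
        )
    return report["sample_id"], avs, report


def run_compare(
    profile_dirs: Sequence[str],
    groups: Optional[dict[str, list[str]]] = None,
    level: str = "gene",
    outdir: Optional[str] = None,
) -> dict:
    """Build and write all four shared-mutation category matrices."""
    if len(profile_dirs) < 2:
        raise ConfigurationError("compare requires at least two profile directories")
    profiles: dict[str, list[AnnotatedVariant]] = {}
    configs = {}
    for d in profile_dirs:
        sid, avs, report = load_profile(d)
        profiles[sid] = avs
        meta_path = Path(d) / "run_metadata.json"
        if meta_path.exists():
            with open(meta_path) as fh:
                configs[sid] = json.load(fh).get("config")
    if len({json.dumps(c, sort_keys=True) for c in configs.values()}) > 1:
        log.warning("profiles were produced with differing configurations; proceeding")
    matrices = compare_mod.build_all_matrices(profiles, groups, level=level)
    return compare_mod.overlap_report(matrices, outdir=outdir)
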