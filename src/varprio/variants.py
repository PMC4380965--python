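"""Small-variant records, normalization, and VCF / tabular I/O.

A :class:`Variant` is one called SNV or indel with read support; the
variant allele fraction (VAF) is the fraction of reads carrying the
alternate allele, the quantity the sequencing-error filter operates on.
All knowledge-base joins key on the *normalized* representation
(:class:`VariantKey`): common suffix trimmed, common prefix trimmed down to
the single anchoring base required for indels, and indels left-aligned
against the reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd
from cyvcf2 import VCF
import pysam

from .errors import ConfigurationError, ParseError, ValidationError
from .reference import SequenceAccessor

log = logging.getLogger(__name__)

_DNA = frozenset("ACGT")

TSV_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "total_depth", "alt_depth", "vaf"]


class VariantKey(NamedTuple):
    """Join key for knowledge-base lookups: the normalized allele representation."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class Variant:
    """One called small variant (SNV or indel) with read support.

    ``pos`` is 1-based and points at the first reference base. ``vaf`` is
    computed as ``alt_depth / total_depth`` whenever both depths are known.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: Optional[int] = None
    alt_depth: Optional[int] = None
    vaf: Optional[float] = field(default=None)

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _DNA:
                raise ValidationError(f"non-ACGT allele {allele!r} at {self.chrom}:{self.pos}")
        for d in (self.total_depth, self.alt_depth):
            if d is not None and d < 0:
                raise ValidationError("depths must be non-negative")
        if self.total_depth is not None and self.alt_depth is not None:
            if self.alt_depth > self.total_depth:
                raise ValidationError(
                    f"alt_depth {self.alt_depth} > total_depth {self.total_depth}"
                )
            expected = self.alt_depth / self.total_depth if self.total_depth else None
            if self.vaf is None:
                object.__setattr__(self, "vaf", expected)
            elif expected is not None and not math.isclose(self.vaf, expected, abs_tol=1e-9):
                raise ValidationError(
                    f"vaf {self.vaf} inconsistent with {self.alt_depth}/{self.total_depth}"
                )
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"vaf {self.vaf} outside [0, 1]")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def end(self) -> int:
        """Last reference base covered (== pos for SNVs and insertions)."""
        return self.pos + len(self.ref) - 1


def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Remove shared suffix, then shared prefix (keeping one anchor base)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def trim_variant(v: Variant) -> Variant:
    """Reference-free normalization: suffix then prefix trimming only."""
    pos, ref, alt = _trim(v.pos, v.ref, v.alt)
    if (pos, ref, alt) == (v.pos, v.ref, v.alt):
        return v
    return replace(v, pos=pos, ref=ref, alt=alt)


def normalize_variant(v: Variant, reference: Optional[SequenceAccessor] = None) -> Variant:
    """Return the left-aligned minimal representation of ``v``.

    Shared suffix is trimmed, then the shared prefix down to the single
    anchor base indels require; indels are then shifted left while the
    shifted representation still matches the reference. Without a
    reference accessor only the trimming steps are applied. Idempotent.
    """
    if reference is not None:
        observed = reference.fetch(v.chrom, v.pos, v.pos + len(v.ref) - 1)
        if observed != v.ref:
            raise ValidationError(
                f"ref allele {v.ref!r} disagrees with reference {observed!r} "
                f"at {v.chrom}:{v.pos}"
            )
    pos, ref, alt = v.pos, v.ref, v.alt
    if reference is None:
        pos, ref, alt = _trim(pos, ref, alt)
    else:
        changed = True
        while changed:
            changed = False
            if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
                if (len(ref) == 1 or len(alt) == 1) and pos == 1:
                    pass  # at the contig start; cannot shift further left
                else:
                    ref, alt = ref[:-1], alt[:-1]
                    changed = True
                    if not ref or not alt:
                        pos -= 1
                        base = reference.fetch(v.chrom, pos, pos)
                        ref, alt = base + ref, base + alt
            if len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
                ref, alt = ref[1:], alt[1:]
                pos += 1
                changed = True
    if (pos, ref, alt) == (v.pos, v.ref, v.alt):
        return v
    return replace(v, pos=pos, ref=ref, alt=alt)


def _apply_alias(chrom: str, aliases: Optional[dict]) -> str:
    if aliases:
        return aliases.get(chrom, chrom)
    return chrom


def read_vcf(
    path: str | Path,
    sample_id: str,
    reference: Optional[SequenceAccessor] = None,
    chrom_aliases: Optional[dict] = None,
) -> list[Variant]:
    """Read a VCF 4.x file into normalized :class:`Variant` records.

    Multi-allelic records are split (one record per ALT allele). Depths come
    from per-sample AD+DP when present, then INFO DP combined with AD, else
    are left missing. Symbolic ALTs, breakends and other non-ACGT alleles are
    skipped with a logged count.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises plain OSError/Exception on bad headers
        raise ParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    out: list[Variant] = []
    skipped = 0
    n_header = _count_header_lines(path)
    for i, rec in enumerate(vcf):
        lineno = n_header + 1 + i
        try:
            ref = (rec.REF or "").upper()
            alts = rec.ALT or []
            sample_ad = _first_sample_format(rec, "AD")
            sample_dp = _first_sample_format(rec, "DP")
            info_dp = rec.INFO.get("DP")
            for ai, alt in enumerate(alts):
                alt = (alt or "").upper()
                if not alt or not (set(alt) <= _DNA) or not (set(ref) <= _DNA):
                    skipped += 1
                    continue
                alt_depth = None
                if sample_ad is not None and len(sample_ad) > ai + 1:
                    ad_val = sample_ad[ai + 1]
                    alt_depth = int(ad_val) if ad_val is not None and ad_val >= 0 else None
                total = None
                if sample_dp is not None and sample_dp >= 0:
                    total = int(sample_dp)
                elif info_dp is not None:
                    total = int(info_dp)
                v = Variant(
                    sample_id=sample_id,
                    chrom=_apply_alias(rec.CHROM, chrom_aliases),
                    pos=rec.POS,
                    ref=ref,
                    alt=alt,
                    total_depth=total,
                    alt_depth=alt_depth,
                )
                v = normalize_variant(v, reference) if reference is not None else trim_variant(v)
                out.append(v)
        except ValidationError:
            raise
        except Exception as exc:
            raise ParseError(f"malformed VCF record at {path} line {lineno}: {exc}") from exc
    if skipped:
        log.info("read_vcf(%s): skipped %d non-ACGT/symbolic alleles", path, skipped)
    return out


def _count_header_lines(path: str | Path) -> int:
    n = 0
    with open(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def _first_sample_format(rec, tag: str):
    try:
        arr = rec.format(tag)
    except Exception:
        return None
    if arr is None or len(arr) == 0:
        return None
    row = arr[0]
    try:
        vals = [int(x) for x in row]
    except TypeError:
        vals = [int(row)]
    vals = [v if v >= 0 else None for v in vals]  # cyvcf2 encodes missing as negatives
    if tag == "DP":
        return vals[0]
    return vals


_VARSCAN_COLUMNS = {
    "chrom": ("chrom", "chromosome"),
    "position": ("position", "pos"),
    "ref": ("ref",),
    "var": ("var", "varallele", "cons"),
    "reads1": ("reads1",),
    "reads2": ("reads2",),
}


def read_varscan_table(
    path: str | Path,
    sample_id: str,
    reference: Optional[SequenceAccessor] = None,
    chrom_aliases: Optional[dict] = None,
) -> list[Variant]:
    """Read native VarScan tabular output.

    ``reads1``/``reads2`` are reference/variant-supporting read counts;
    VAF = reads2 / (reads1 + reads2). VarScan indel notation (``+AG`` for an
    insertion after the site, ``-AG`` for a deletion of the following bases)
    is converted to anchored VCF-style alleles.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    lower = {c.lower().strip(): c for c in df.columns}
    resolved = {}
    for want, candidates in _VARSCAN_COLUMNS.items():
        for cand in candidates:
            if cand in lower:
                resolved[want] = lower[cand]
                break
        else:
            raise ConfigurationError(
                f"VarScan table {path} missing column {want!r}; expected columns "
                f"(case-insensitive): {sorted(_VARSCAN_COLUMNS)}"
            )
    out: list[Variant] = []
    for _, row in df.iterrows():
        chrom = _apply_alias(str(row[resolved["chrom"]]), chrom_aliases)
        pos = int(row[resolved["position"]])
        ref = str(row[resolved["ref"]]).upper()
        var = str(row[resolved["var"]]).upper()
        reads1 = int(row[resolved["reads1"]])
        reads2 = int(row[resolved["reads2"]])
        if var.startswith("+"):
            alt = ref + var[1:]
        elif var.startswith("-"):
            ref, alt = ref + var[1:], ref
        else:
            alt = var
        v = Variant(
            sample_id=sample_id,
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            total_depth=reads1 + reads2,
            alt_depth=reads2,
        )
        v = normalize_variant(v, reference) if reference is not None else trim_variant(v)
        out.append(v)
    return out


def read_variant_table(path: str | Path, sample_id: Optional[str] = None) -> list[Variant]:
    """Read the package's normalized-variant TSV dialect (see write_variants)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"variant table {path} missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            Variant(
                sample_id=sample_id or row["sample_id"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                total_depth=int(row["total_depth"]) if row["total_depth"] != "" else None,
                alt_depth=int(row["alt_depth"]) if row["alt_depth"] != "" else None,
                vaf=float(row["vaf"]) if row["vaf"] != "" else None,
            )
        )
    return out


def write_variants(vs: Sequence[Variant], path: str | Path, format: str = "tsv") -> None:
    """Write normalized variants as TSV or VCF; round-trips field-for-field."""
    if format == "tsv":
        _write_tsv(vs, path)
    elif format == "vcf":
        _write_vcf(vs, path)
    else:
        raise ConfigurationError(f"unknown variant output format {format!r}")


def _write_tsv(vs: Sequence[Variant], path) -> None:
    rows = []
    for v in vs:
        rows.append(
            {
                "sample_id": v.sample_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "total_depth": "" if v.total_depth is None else v.total_depth,
                "alt_depth": "" if v.alt_depth is None else v.alt_depth,
                "vaf": "" if v.vaf is None else repr(v.vaf),
            }
        )
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def _write_vcf(vs: Sequence[Variant], path) -> None:
    samples = sorted({v.sample_id for v in vs})
    if len(samples) > 1:
        raise ConfigurationError("VCF output supports exactly one sample per file")
    sample = samples[0] if samples else "SAMPLE"
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">'
    )
    contigs = {}
    for v in vs:
        contigs[v.chrom] = max(contigs.get(v.chrom, 0), v.end + 1000)
    for chrom, length in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(vs, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt), filter="PASS"
            )
            if v.total_depth is not None:
                rec.samples[sample]["DP"] = v.total_depth
                if v.alt_depth is not None:
                    rec.samples[sample]["AD"] = (v.total_depth - v.alt_depth, v.alt_depth)
            out.write(rec)


def split_by_sample(vs: Iterable[Variant]) -> dict[str, list[Variant]]:
    out: dict[str, list[Variant]] = {}
    for v in vs:
        out.setdefault(v.sample_id, []).append(v)
    return out
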