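"""Functional-consequence classification of variants against transcript models.

Given a normalized variant and a gene model, :func:`classify` assigns one of
the gene-based annotation classes the downstream deleteriousness filter
consumes: coding SNVs are typed by translating the affected codon before and
after the change under the standard genetic code; coding indels are typed by
length mod 3, with the mutant coding sequence rebuilt to detect in-frame
changes that create a premature stop (reported stopgain). Non-coding bins
follow fixed positional rules (see docs/methods.md for the exact boundary
conventions).

Region conventions. The affected genomic bases of a variant are: the
substituted base(s) for SNVs/MNVs, the two bases flanking the insertion
point for insertions, and the deleted bases for deletions. A variant whose
affected bases fall partly inside and partly outside an exon — or partly
inside and partly outside the CDS — crosses a junction and is classified
``splicing``; fully intronic variants within 2 bp of an exon boundary are
``splicing`` as well (canonical splice sites).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Data import CodonTable

from .errors import ContractError, ValidationError
from .reference import SequenceAccessor
from .transcripts import TranscriptIndex, TranscriptModel, build_cds, revcomp
from .variants import Variant, trim_variant

# Consequence classes, most severe first. Order drives the per-variant
# reduction across transcripts (ANNOVAR-style gene-based annotation).
SEVERITY_ORDER = [
    "stopgain",
    "stoploss",
    "frameshift_insertion",
    "frameshift_deletion",
    "nonframeshift_insertion",
    "nonframeshift_deletion",
    "nonsynonymous_snv",
    "splicing",
    "synonymous_snv",
    "utr",
    "intronic",
    "intergenic",
]
_RANK = {k: i for i, k in enumerate(SEVERITY_ORDER)}

CODING_CLASSES = frozenset(SEVERITY_ORDER[:7]) | {"synonymous_snv"}

SPLICE_WINDOW = 2  # bp around exon junctions treated as canonical splice sites

_table = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"


def translate(seq: str) -> str:
    """Translate a DNA string codon-by-codon; trailing partial codon dropped."""
    return "".join(CODON_TO_AA[seq[i : i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3))


@dataclass(frozen=True)
class ConsequenceCall:
    gene_symbol: str
    transcript_id: str
    klass: str
    codon_change: Optional[str] = None
    aa_change: Optional[str] = None

    def __post_init__(self):
        if self.klass not in _RANK:
            raise ValidationError(f"unknown consequence class {self.klass!r}")


def severity_rank(klass: str) -> int:
    return _RANK[klass]


def _affected_bases(v: Variant) -> list[int]:
    """Genomic bases that determine the variant's regional classification."""
    if len(v.ref) == len(v.alt):
        return list(range(v.pos, v.pos + len(v.ref)))
    if len(v.alt) > len(v.ref):  # insertion: the two bases flanking the gap
        return [v.pos, v.pos + 1]
    return list(range(v.pos + 1, v.pos + len(v.ref)))  # deletion: removed bases


def classify(
    v: Variant, t: TranscriptModel, reference: Optional[SequenceAccessor] = None
) -> ConsequenceCall:
    """Classify one normalized variant against one transcript model."""
    if trim_variant(v).key != v.key:
        raise ContractError(f"variant {v.key} is not normalized")
    if v.chrom != t.chrom:
        raise ContractError(f"variant chrom {v.chrom} != transcript chrom {t.chrom}")
    reference = reference or t.reference

    bases = _affected_bases(v)
    in_span = [p for p in bases if t.tx_start <= p <= t.tx_end]
    if not in_span:
        return ConsequenceCall(t.gene_symbol, t.transcript_id, "intergenic")
    exonic = [p for p in in_span if t.exon_contains(p)]
    intronic = [p for p in in_span if not t.exon_contains(p)]
    outside = len(in_span) < len(bases)
    if exonic and (intronic or outside):
        return ConsequenceCall(t.gene_symbol, t.transcript_id, "splicing")
    if not exonic:
        boundaries = t.exon_boundaries()
        dist = min(abs(p - b) for p in intronic for b in boundaries)
        klass = "splicing" if dist <= SPLICE_WINDOW else "intronic"
        return ConsequenceCall(t.gene_symbol, t.transcript_id, klass)
    # fully exonic
    coding = [p for p in bases if t.cds_contains(p)]
    if not coding:
        return ConsequenceCall(t.gene_symbol, t.transcript_id, "utr")
    if len(coding) < len(bases):
        return ConsequenceCall(t.gene_symbol, t.transcript_id, "splicing")
    if reference is None:
        raise ValidationError("reference accessor required for coding classification")
    return _classify_coding(v, t, reference)


def _oriented(seq: str, strand: str) -> str:
    return seq if strand == "+" else revcomp(seq)


def _classify_coding(v: Variant, t: TranscriptModel, reference: SequenceAccessor) -> ConsequenceCall:
    cds_seq = build_cds(t, reference)
    idx = t.cds_index()

    if v.is_snv:
        i = idx[v.pos]
        base = v.alt if t.strand == "+" else revcomp(v.alt)
        ci = i // 3
        ref_codon = cds_seq[ci * 3 : ci * 3 + 3]
        alt_codon = ref_codon[: i % 3] + base + ref_codon[i % 3 + 1 :]
        aa_ref, aa_alt = CODON_TO_AA[ref_codon], CODON_TO_AA[alt_codon]
        if aa_ref == aa_alt:
            klass = "synonymous_snv"
        elif aa_alt == "*":
            klass = "stopgain"
        elif aa_ref == "*":
            klass = "stoploss"
        else:
            klass = "nonsynonymous_snv"
        return ConsequenceCall(
            t.gene_symbol,
            t.transcript_id,
            klass,
            codon_change=f"{ref_codon}>{alt_codon}",
            aa_change=f"p.{aa_ref}{ci + 1}{aa_alt}",
        )

    mutant, first_idx = _mutant_cds(v, t, cds_seq, idx)
    delta = len(v.alt) - len(v.ref)
    aa_pos = first_idx // 3 + 1
    codon_change = f"c.{first_idx + 1}{_oriented(v.ref, t.strand)}>{_oriented(v.alt, t.strand)}"
    if delta != 0 and delta % 3 != 0:
        klass = "frameshift_insertion" if delta > 0 else "frameshift_deletion"
        prot = translate(cds_seq)
        aa_ref = prot[aa_pos - 1] if aa_pos - 1 < len(prot) else "?"
        return ConsequenceCall(
            t.gene_symbol, t.transcript_id, klass,
            codon_change=codon_change, aa_change=f"p.{aa_ref}{aa_pos}fs",
        )
    prot_ref = translate(cds_seq)
    prot_alt = translate(mutant)
    if _premature_stop(prot_ref, prot_alt):
        klass = "stopgain"
    elif delta == 0:
        if prot_ref == prot_alt:
            klass = "synonymous_snv"
        elif _lost_stop(prot_ref, prot_alt):
            klass = "stoploss"
        else:
            klass = "nonsynonymous_snv"
    else:
        klass = "nonframeshift_insertion" if delta > 0 else "nonframeshift_deletion"
    aa_change = (
        f"p.{aa_pos}{'ins' if delta > 0 else 'del' if delta < 0 else 'delins'}{abs(delta) // 3 or ''}"
    )
    return ConsequenceCall(
        t.gene_symbol, t.transcript_id, klass, codon_change=codon_change, aa_change=aa_change
    )


def _premature_stop(prot_ref: str, prot_alt: str) -> bool:
    """True when the mutant protein stops earlier (relative) than the original."""
    ref_stop = prot_ref.find("*")
    alt_stop = prot_alt.find("*")
    if alt_stop == -1:
        return False
    if alt_stop == len(prot_alt) - 1 and (ref_stop == -1 or ref_stop == len(prot_ref) - 1):
        return False  # terminal stop preserved
    return ref_stop == -1 or alt_stop < ref_stop or alt_stop < len(prot_alt) - 1


def _lost_stop(prot_ref: str, prot_alt: str) -> bool:
    for a, b in zip(prot_ref, prot_alt):
        if a != b:
            return a == "*"
    return False


def _mutant_cds(
    v: Variant, t: TranscriptModel, cds_seq: str, idx: dict[int, int]
) -> tuple[str, int]:
    """Apply the (fully coding) variant to the coding sequence.

    The genomic interval [pos, pos+len(ref)-1] is replaced by the alt allele;
    in transcript coordinates that is a contiguous replacement by the
    strand-oriented alt. A deletion may be anchored on a base just outside
    the CDS; then only the deleted bases are removed. Returns the mutant CDS
    and the first affected transcript index.
    """
    if v.pos in idx:
        ref_idx = sorted(idx[p] for p in range(v.pos, v.pos + len(v.ref)) if p in idx)
        i0, i1 = ref_idx[0], ref_idx[-1]
        if ref_idx != list(range(i0, i1 + 1)):  # pragma: no cover - gated by region rules
            raise ContractError("variant reference bases are not contiguous in the CDS")
        alt_tx = _oriented(v.alt, t.strand)
        mutant = cds_seq[:i0] + alt_tx + cds_seq[i1 + 1 :]
        return mutant, i0
    # anchor base outside the CDS: only possible for an anchored deletion whose
    # removed bases all lie inside the CDS
    if len(v.ref) <= len(v.alt) or v.ref[0] != v.alt[0] or len(v.alt) != 1:
        raise ContractError(
            f"unsupported coding variant shape {v.key} with anchor outside CDS"
        )
    ref_idx = sorted(idx[p] for p in range(v.pos + 1, v.pos + len(v.ref)))
    i0, i1 = ref_idx[0], ref_idx[-1]
    if ref_idx != list(range(i0, i1 + 1)):  # pragma: no cover - gated by region rules
        raise ContractError("variant reference bases are not contiguous in the CDS")
    mutant = cds_seq[:i0] + cds_seq[i1 + 1 :]
    return mutant, i0


def annotate_consequence(
    v: Variant,
    transcripts: TranscriptIndex,
    reference: Optional[SequenceAccessor] = None,
) -> ConsequenceCall:
    """Reduce per-transcript calls to the single most severe consequence.

    Ties in severity are broken by lexicographically smallest transcript_id.
    A variant overlapping no transcript is ``intergenic`` with empty gene.
    """
    bases = _affected_bases(v)
    hits = transcripts.overlapping(v.chrom, min(bases), max(bases))
    calls = [classify(v, t, reference) for t in hits]
    calls = [c for c in calls if c.klass != "intergenic"]
    if not calls:
        return ConsequenceCall("", "", "intergenic")
    return reduce_calls(calls)


def reduce_calls(calls: Iterable[ConsequenceCall]) -> ConsequenceCall:
    return min(calls, key=lambda c: (severity_rank(c.klass), c.transcript_id))
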