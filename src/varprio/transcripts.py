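"""Transcript/gene models and their loaders (GTF and a TSV dialect).

A :class:`TranscriptModel` carries the exon and CDS intervals (1-based,
inclusive, sorted, disjoint) of one transcript. Models whose total CDS
length is not a multiple of 3 cannot be translated reliably and are
rejected on load with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigurationError, ValidationError
from .reference import SequenceAccessor

log = logging.getLogger(__name__)

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_sorted_disjoint(ivs: Sequence[Interval], label: str) -> None:
    for s, e in ivs:
        if s > e:
            raise ValidationError(f"{label} interval ({s}, {e}) has start > end")
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise ValidationError(f"{label} intervals overlap or are unsorted: {ivs}")


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]
    reference: Optional[SequenceAccessor] = None
    _cds_positions: Optional[list[int]] = field(default=None, repr=False, compare=False)
    _cds_index: Optional[dict[int, int]] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = tuple(sorted(tuple(iv) for iv in self.exons))
        self.cds = tuple(sorted(tuple(iv) for iv in self.cds))
        _check_sorted_disjoint(self.exons, "exon")
        _check_sorted_disjoint(self.cds, "CDS")
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValidationError(
                    f"CDS interval ({cs}, {ce}) of {self.transcript_id} not inside an exon"
                )
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"CDS length {self.cds_length} of {self.transcript_id} not a multiple of 3"
            )

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def exon_contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def cds_contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases in transcription (5'->3') order."""
        if self._cds_positions is None:
            pos = [p for s, e in self.cds for p in range(s, e + 1)]
            if self.strand == "-":
                pos.reverse()
            self._cds_positions = pos
        return self._cds_positions

    def cds_index(self) -> dict[int, int]:
        """Map genomic position -> 0-based index into the coding sequence."""
        if self._cds_index is None:
            self._cds_index = {p: i for i, p in enumerate(self.cds_positions())}
        return self._cds_index

    def exon_boundaries(self) -> list[int]:
        return [b for s, e in self.exons for b in (s, e)]


def build_cds(t: TranscriptModel, reference: Optional[SequenceAccessor] = None) -> str:
    """Extract the coding sequence of ``t`` in 5'->3' orientation.

    Concatenates the CDS interval sequences in genomic order and
    reverse-complements the result for minus-strand models. Warns (does not
    fail) when the model is incomplete, i.e. the sequence does not start
    with ATG or end in a stop codon.
    """
    ref = reference or t.reference
    if ref is None:
        raise ValidationError(f"no reference accessor available for {t.transcript_id}")
    parts = [ref.fetch(t.chrom, s, e) for s, e in t.cds]
    seq = "".join(parts)
    if t.strand == "-":
        seq = revcomp(seq)
    if not seq.startswith("ATG") or seq[-3:] not in ("TAA", "TAG", "TGA"):
        log.warning("transcript %s CDS is incomplete (no ATG start or stop end)", t.transcript_id)
    return seq


class TranscriptIndex:
    """Interval index of transcript models, queryable per chromosome."""

    def __init__(self, models: Iterable[TranscriptModel]):
        self._trees: dict[str, IntervalTree] = {}
        self.models: list[TranscriptModel] = []
        for m in models:
            self.models.append(m)
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            tree.addi(m.tx_start, m.tx_end + 1, m)

    def overlapping(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end + 1)]
        return sorted(hits, key=lambda m: m.transcript_id)


_TSV_COLUMNS = [
    "transcript_id",
    "gene",
    "chrom",
    "strand",
    "exon_starts",
    "exon_ends",
    "cds_starts",
    "cds_ends",
]


def _parse_int_list(text: str) -> list[int]:
    return [int(x) for x in str(text).split(",") if str(x).strip() != ""]


def load_transcripts_tsv(
    path: str | Path, reference: Optional[SequenceAccessor] = None
) -> list[TranscriptModel]:
    """Load the documented TSV dialect (1-based inclusive coordinate lists)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"transcript table {path} missing columns {missing}")
    models, rejected = [], 0
    for _, row in df.iterrows():
        exons = tuple(zip(_parse_int_list(row["exon_starts"]), _parse_int_list(row["exon_ends"])))
        cds = tuple(zip(_parse_int_list(row["cds_starts"]), _parse_int_list(row["cds_ends"])))
        try:
            models.append(
                TranscriptModel(
                    transcript_id=row["transcript_id"],
                    gene_symbol=row["gene"],
                    chrom=row["chrom"],
                    strand=row["strand"],
                    exons=exons,
                    cds=cds,
                    reference=reference,
                )
            )
        except ValidationError as exc:
            rejected += 1
            log.warning("rejecting transcript %s: %s", row["transcript_id"], exc)
    if rejected:
        log.warning("rejected %d invalid transcript models from %s", rejected, path)
    return models


def load_transcripts_gtf(
    path: str | Path, reference: Optional[SequenceAccessor] = None
) -> list[TranscriptModel]:
    """Load exon/CDS features from a GTF file (gene_name + transcript_id attributes)."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx_ids = feat.attributes.get("transcript_id")
        if not tx_ids:
            raise ConfigurationError(f"GTF {path}: feature without transcript_id at line {feat}")
        tx = tx_ids[0]
        gene = (feat.attributes.get("gene_name") or feat.attributes.get("gene_id") or [tx])[0]
        entry = by_tx.setdefault(
            tx, {"gene": gene, "chrom": feat.seqid, "strand": feat.strand, "exons": [], "cds": []}
        )
        target = "exons" if feat.featuretype == "exon" else "cds"
        entry[target].append((feat.start, feat.end))
    models, rejected = [], 0
    for tx in sorted(by_tx):
        entry = by_tx[tx]
        try:
            models.append(
                TranscriptModel(
                    transcript_id=tx,
                    gene_symbol=entry["gene"],
                    chrom=entry["chrom"],
                    strand=entry["strand"],
                    exons=tuple(entry["exons"]),
                    cds=tuple(entry["cds"]),
                    reference=reference,
                )
            )
        except ValidationError as exc:
            rejected += 1
            log.warning("rejecting transcript %s: %s", tx, exc)
    if rejected:
        log.warning("rejected %d invalid transcript models from %s", rejected, path)
    return models


def write_transcripts_tsv(models: Sequence[TranscriptModel], path: str | Path) -> None:
    rows = []
    for m in models:
        rows.append(
            {
                "transcript_id": m.transcript_id,
                "gene": m.gene_symbol,
                "chrom": m.chrom,
                "strand": m.strand,
                "exon_starts": ",".join(str(s) for s, _ in m.exons),
                "exon_ends": ",".join(str(e) for _, e in m.exons),
                "cds_starts": ",".join(str(s) for s, _ in m.cds),
                "cds_ends": ",".join(str(e) for _, e in m.cds),
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_transcripts_gtf(models: Sequence[TranscriptModel], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_symbol}"; gene_name "{m.gene_symbol}"; transcript_id "{m.transcript_id}";'
            for s, e in m.exons:
                fh.write(f"{m.chrom}\tvarprio\texon\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}\n")
            for s, e in m.cds:
                fh.write(f"{m.chrom}\tvarprio\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t{attrs}\n")
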