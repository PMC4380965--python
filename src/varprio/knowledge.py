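"""Local knowledge-base snapshots: population MAFs, known somatic mutations,
drug-gene interactions, and gene expression.

These stand in for desk-local snapshots of the public resources the
prioritization cascade consults (1000 Genomes / ESP allele frequencies, a
COSMIC-style somatic catalogue, a DGIdb-style drug-gene interaction table,
and Cufflinks-style FPKM output). All variant-keyed tables must contain
normalized alleles; gene symbols are matched case-insensitively after
trimming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, LoadError
from .variants import VariantKey

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyRecord:
    key: VariantKey
    maf_1000g: Optional[float] = None
    maf_esp: Optional[float] = None


@dataclass(frozen=True)
class DrugGeneInteraction:
    gene_symbol: str
    drug_name: str
    interaction_type: Optional[str]
    source: str
    curated: bool


@dataclass(frozen=True)
class ExpressionRecord:
    gene_symbol: str
    fpkm: float


def _norm_gene(g: str) -> str:
    return str(g).strip().upper()


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"table {path} missing columns {missing}")
    return df


def _dedupe(df: pd.DataFrame, path) -> pd.DataFrame:
    before = len(df)
    df = df.drop_duplicates()
    if len(df) < before:
        log.info("%s: dropped %d duplicate identical rows", path, before - len(df))
    return df


class FrequencyTable:
    """Population minor-allele-frequency lookup keyed by normalized variant."""

    def __init__(self, records: Mapping[VariantKey, FrequencyRecord]):
        self._records = dict(records)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyTable":
        df = _dedupe(_read_tsv(path, ["chrom", "pos", "ref", "alt", "maf_1000g", "maf_esp"]), path)
        records: dict[VariantKey, FrequencyRecord] = {}
        for _, row in df.iterrows():
            key = VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            rec = FrequencyRecord(
                key=key,
                maf_1000g=float(row["maf_1000g"]) if row["maf_1000g"] != "" else None,
                maf_esp=float(row["maf_esp"]) if row["maf_esp"] != "" else None,
            )
            if key in records and records[key] != rec:
                raise LoadError(f"{path}: conflicting duplicate frequency records for {key}")
            records[key] = rec
        return cls(records)

    def get(self, key: VariantKey) -> Optional[FrequencyRecord]:
        return self._records.get(key)

    def __len__(self) -> int:
        return len(self._records)


class CosmicTable:
    """Known-somatic-mutation lookup (COSMIC-style ids keyed by variant)."""

    def __init__(self, ids: Mapping[VariantKey, str]):
        self._ids = dict(ids)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CosmicTable":
        df = _dedupe(_read_tsv(path, ["chrom", "pos", "ref", "alt", "cosmic_id"]), path)
        ids: dict[VariantKey, str] = {}
        for _, row in df.iterrows():
            key = VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            if key in ids and ids[key] != row["cosmic_id"]:
                raise LoadError(f"{path}: conflicting duplicate cosmic records for {key}")
            ids[key] = row["cosmic_id"]
        return cls(ids)

    def get(self, key: VariantKey) -> Optional[str]:
        return self._ids.get(key)

    def __len__(self) -> int:
        return len(self._ids)


_TRUTHY = {"true", "1", "yes", "t", "y"}
_FALSY = {"false", "0", "no", "f", "n"}


def _parse_bool(text: str, path) -> bool:
    t = str(text).strip().lower()
    if t in _TRUTHY:
        return True
    if t in _FALSY:
        return False
    raise LoadError(f"{path}: cannot parse curated flag {text!r}")


class DgiTable:
    """Drug-gene interaction lookup by gene, optionally curated-only."""

    def __init__(self, interactions: Sequence[DrugGeneInteraction]):
        self._by_gene: dict[str, list[DrugGeneInteraction]] = {}
        seen: dict[tuple, DrugGeneInteraction] = {}
        for it in interactions:
            k = (_norm_gene(it.gene_symbol), it.drug_name, it.source)
            if k in seen:
                if seen[k] != it:
                    raise LoadError(f"conflicting duplicate DGI rows for {k}")
                continue
            seen[k] = it
            self._by_gene.setdefault(_norm_gene(it.gene_symbol), []).append(it)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DgiTable":
        df = _dedupe(_read_tsv(path, ["gene", "drug", "interaction_type", "source", "curated"]), path)
        rows = [
            DrugGeneInteraction(
                gene_symbol=row["gene"],
                drug_name=row["drug"],
                interaction_type=row["interaction_type"] or None,
                source=row["source"],
                curated=_parse_bool(row["curated"], path),
            )
            for _, row in df.iterrows()
        ]
        return cls(rows)

    def interactions(self, gene: str, curated_only: bool = True) -> list[DrugGeneInteraction]:
        hits = self._by_gene.get(_norm_gene(gene), [])
        if curated_only:
            hits = [h for h in hits if h.curated]
        return list(hits)


class ExpressionTable:
    """Per-gene FPKM lookup; multiple rows per gene aggregate by maximum."""

    def __init__(self, fpkm: Mapping[str, float]):
        self._fpkm = {_norm_gene(g): float(v) for g, v in fpkm.items()}
        for g, v in self._fpkm.items():
            if v < 0:
                raise LoadError(f"negative FPKM {v} for gene {g}")

    @classmethod
    def from_tsv(cls, path: str | Path, dialect: str = "plain") -> "ExpressionTable":
        if dialect == "plain":
            df = _read_tsv(path, ["gene", "fpkm"])
            gene_col, fpkm_col = "gene", "fpkm"
        elif dialect == "tracking":
            df = _read_tsv(path, ["gene_short_name", "FPKM"])
            gene_col, fpkm_col = "gene_short_name", "FPKM"
        else:
            raise ConfigurationError(f"unknown expression dialect {dialect!r}")
        agg: dict[str, float] = {}
        for _, row in df.iterrows():
            gene = _norm_gene(row[gene_col])
            value = float(row[fpkm_col])
            if value < 0:
                raise LoadError(f"{path}: negative FPKM {value} for gene {gene}")
            agg[gene] = max(agg.get(gene, 0.0), value)
        return cls(agg)

    def fpkm(self, gene: str) -> Optional[float]:
        return self._fpkm.get(_norm_gene(gene))

    def __len__(self) -> int:
        return len(self._fpkm)


def compute_fpkm(
    counts: Mapping[str, int], lengths: Mapping[str, int], total_mapped: int
) -> list[ExpressionRecord]:
    """FPKM = count / ((length/1e3) * (total_mapped/1e6)).

    Desk-scale convenience for building expression tables from read counts
    on fixture data.
    """
    if total_mapped <= 0:
        raise ConfigurationError("total_mapped must be > 0")
    out = []
    for gene in counts:
        length = lengths[gene]
        if length <= 0:
            raise ConfigurationError(f"gene {gene} has non-positive length {length}")
        out.append(
            ExpressionRecord(
                gene_symbol=gene,
                fpkm=counts[gene] / ((length / 1e3) * (total_mapped / 1e6)),
            )
        )
    return out
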