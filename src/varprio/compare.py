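"""Cross-sample shared-mutation analysis.

Builds, for each of the four profile categories (RD, RDD, and their
highly-expressed subsets), the matrix of genes mutated in *both* of two
declared sample groups (e.g. cell lines vs tumors). Matching can be done at
gene level, exact-variant level (normalized allele identity), or by shared
known-somatic (COSMIC) id. A gene carries a multi-hit flag per group when
more than one group member is mutated in it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .prioritize import AnnotatedVariant

log = logging.getLogger(__name__)

CATEGORIES = ("rd", "rdd", "rd_expressed", "rdd_expressed")
LEVELS = ("gene", "exact_variant", "cosmic_id")


def qualifies(av: AnnotatedVariant, category: str) -> bool:
    if category == "rd":
        return True
    if category == "rdd":
        return av.druggable
    if category == "rd_expressed":
        return av.highly_expressed
    if category == "rdd_expressed":
        return av.druggable and av.highly_expressed
    raise ConfigurationError(f"unknown category {category!r}; choose from {CATEGORIES}")


@dataclass
class SharedMutationMatrix:
    category: str
    level: str
    genes: list[str]
    samples: list[str]
    groups: dict[str, list[str]]
    presence: dict[str, dict[str, bool]]  # gene -> sample -> qualifying variant present
    multi_hit: dict[str, dict[str, bool]] = field(default_factory=dict)  # gene -> group

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.genes:
            row: dict = {"gene": gene}
            for s in self.samples:
                row[s] = int(self.presence[gene].get(s, False))
            for g in self.groups:
                row[f"multi_hit_{g}"] = int(self.multi_hit.get(gene, {}).get(g, False))
            rows.append(row)
        cols = ["gene"] + self.samples + [f"multi_hit_{g}" for g in self.groups]
        return pd.DataFrame(rows, columns=cols)


def _items(av: AnnotatedVariant, level: str):
    """The matching token(s) of one variant at the requested level."""
    if level == "gene":
        return [av.gene] if av.gene else []
    if level == "exact_variant":
        return [av.variant.key]
    if level == "cosmic_id":
        return [av.cosmic_id] if av.cosmic_id is not None else []
    raise ConfigurationError(f"unknown matching level {level!r}; choose from {LEVELS}")


def shared_mutations(
    profiles: Mapping[str, Sequence[AnnotatedVariant]],
    groups: Optional[Mapping[str, Sequence[str]]] = None,
    level: str = "gene",
    category: str = "rd",
) -> SharedMutationMatrix:
    """Build the shared-mutation matrix for one category at one matching level.

    ``profiles`` maps sample id -> that sample's RD variant list (cascade
    output). An item (gene / variant / COSMIC id) is shared when at least one
    sample of *each* group carries a category-qualifying variant with it.
    With ``groups=None`` (all-samples mode) an item is shared when at least
    two distinct samples carry it.
    """
    samples = sorted(profiles)
    if groups is None:
        group_map: dict[str, list[str]] = {"all": samples}
    else:
        group_map = {g: list(members) for g, members in groups.items()}
        for g, members in group_map.items():
            if not members:
                raise ConfigurationError(f"group {g!r} is empty")
            unknown = [s for s in members if s not in profiles]
            if unknown:
                raise ConfigurationError(f"group {g!r} references unknown samples {unknown}")

    if level == "cosmic_id":
        _warn_cosmic_conflicts(profiles)

    # per sample: matching items and the genes that carry them
    sample_items: dict[str, set] = {}
    item_genes: dict[object, set[str]] = {}
    for s in samples:
        items = set()
        for av in profiles[s]:
            if not qualifies(av, category):
                continue
            for item in _items(av, level):
                items.add(item)
                if av.gene:
                    item_genes.setdefault(item, set()).add(av.gene)
        sample_items[s] = items

    def carriers(item) -> set[str]:
        return {s for s in samples if item in sample_items[s]}

    all_items = set().union(*sample_items.values()) if sample_items else set()
    if groups is None:
        shared_items = {it for it in all_items if len(carriers(it)) >= 2}
    else:
        shared_items = {
            it
            for it in all_items
            if all(any(s in carriers(it) for s in members) for members in group_map.values())
        }

    shared_genes = sorted(set().union(*(item_genes[it] for it in shared_items)) if shared_items else set())

    # presence: sample has a qualifying variant in the gene carrying a shared item
    presence: dict[str, dict[str, bool]] = {g: {} for g in shared_genes}
    multi_hit: dict[str, dict[str, bool]] = {g: {} for g in shared_genes}
    for gene in shared_genes:
        for s in samples:
            has = any(
                qualifies(av, category)
                and av.gene == gene
                and any(it in shared_items for it in _items(av, level))
                for av in profiles[s]
            )
            presence[gene][s] = has
        for gname, members in group_map.items():
            multi_hit[gene][gname] = sum(presence[gene][s] for s in members) >= 2

    return SharedMutationMatrix(
        category=category,
        level=level,
        genes=shared_genes,
        samples=samples,
        groups=group_map,
        presence=presence,
        multi_hit=multi_hit,
    )


def _warn_cosmic_conflicts(profiles: Mapping[str, Sequence[AnnotatedVariant]]) -> None:
    by_id: dict[str, set] = {}
    for avs in profiles.values():
        for av in avs:
            if av.cosmic_id is not None:
                by_id.setdefault(av.cosmic_id, set()).add(av.variant.key)
    for cid, keys in sorted(by_id.items()):
        if len(keys) > 1:
            log.warning("cosmic id %s maps to multiple variant keys: %s", cid, sorted(keys))


def build_all_matrices(
    profiles: Mapping[str, Sequence[AnnotatedVariant]],
    groups: Optional[Mapping[str, Sequence[str]]] = None,
    level: str = "gene",
) -> dict[str, SharedMutationMatrix]:
    return {
        cat: shared_mutations(profiles, groups, level=level, category=cat) for cat in CATEGORIES
    }


def overlap_report(
    matrices: Mapping[str, SharedMutationMatrix], outdir: Optional[str | Path] = None
) -> dict:
    """Summarize the four category matrices and verify their nesting.

    Nesting (druggable subsets inside RD, expressed subsets inside
    unexpressed) is asserted and recorded in the returned metadata; a
    violation raises, as it indicates inconsistent inputs.
    """
    sample_lists = {tuple(m.samples) for m in matrices.values()}
    if len(sample_lists) > 1:
        raise ValidationError(f"inconsistent sample lists across matrices: {sample_lists}")
    genes = {cat: set(m.genes) for cat, m in matrices.items()}
    nesting_checks = {
        "rdd_subset_of_rd": genes.get("rdd", set()) <= genes.get("rd", set()),
        "rd_expressed_subset_of_rd": genes.get("rd_expressed", set()) <= genes.get("rd", set()),
        "rdd_expressed_subset_of_rdd": genes.get("rdd_expressed", set()) <= genes.get("rdd", set()),
        "rdd_expressed_subset_of_rd_expressed": genes.get("rdd_expressed", set())
        <= genes.get("rd_expressed", set()),
    }
    if not all(nesting_checks.values()):
        raise ValidationError(f"category nesting violated: {nesting_checks}")
    meta = {
        "samples": sorted(sample_lists.pop()) if sample_lists else [],
        "categories": {cat: sorted(g) for cat, g in genes.items()},
        "nesting": nesting_checks,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cat, m in matrices.items():
            m.to_frame().to_csv(outdir / f"shared_mutations_{cat}.tsv", sep="\t", index=False)
    return meta
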