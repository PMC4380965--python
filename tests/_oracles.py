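"""Independent brute-force oracles used to validate the implementation.

These deliberately take different computational routes than the package:
the consequence oracle edits the genome as a position-tagged base list and
re-extracts the coding sequence, the normalization oracle enumerates every
equivalent representation of an allele pair, and the shared-mutation oracle
does plain set algebra over per-sample token sets.
"""

from __future__ import annotations

from Bio.Seq import Seq

# ---------------------------------------------------------------------------
# Consequence classification oracle


def _translate(seq: str) -> str:
    n = len(seq) - len(seq) % 3
    if n == 0:
        return ""
    return str(Seq(seq[:n]).translate())


def _premature(prot_ref: str, prot_alt: str) -> bool:
    ref_stop = prot_ref.find("*")
    alt_stop = prot_alt.find("*")
    if alt_stop == -1:
        return False
    if alt_stop == len(prot_alt) - 1 and (ref_stop == -1 or ref_stop == len(prot_ref) - 1):
        return False
    return ref_stop == -1 or alt_stop < ref_stop or alt_stop < len(prot_alt) - 1


def oracle_classify(v, model, chrom_seq: str) -> str:
    """Classify one normalized variant against one model by genome editing."""
    ref_len, alt_len = len(v.ref), len(v.alt)
    if ref_len == alt_len:
        bases = list(range(v.pos, v.pos + ref_len))
    elif alt_len > ref_len:
        bases = [v.pos, v.pos + 1]
    else:
        bases = list(range(v.pos + 1, v.pos + ref_len))

    def in_exon(p):
        return any(s <= p <= e for s, e in model.exons)

    def in_cds(p):
        return any(s <= p <= e for s, e in model.cds)

    tx_start, tx_end = model.exons[0][0], model.exons[-1][1]
    inside = [p for p in bases if tx_start <= p <= tx_end]
    if not inside:
        return "intergenic"
    exonic = [p for p in inside if in_exon(p)]
    intronic = [p for p in inside if not in_exon(p)]
    if exonic and (intronic or len(inside) < len(bases)):
        return "splicing"
    if not exonic:
        bounds = [b for s, e in model.exons for b in (s, e)]
        dist = min(abs(p - b) for p in intronic for b in bounds)
        return "splicing" if dist <= 2 else "intronic"
    cds_bases = [p for p in bases if in_cds(p)]
    if not cds_bases:
        return "utr"
    if len(cds_bases) < len(bases):
        return "splicing"

    # coding: apply the edit to a position-tagged base list and re-extract
    tagged = [(p, chrom_seq[p - 1]) for p in range(1, len(chrom_seq) + 1)]
    if ref_len == alt_len:
        edited = list(tagged)
        for i, p in enumerate(range(v.pos, v.pos + ref_len)):
            edited[p - 1] = (p, v.alt[i])
    elif alt_len > ref_len:  # anchored insertion after pos
        edited = (
            tagged[: v.pos - 1]
            + [(v.pos, v.alt[0])]
            + [("ins", b) for b in v.alt[1:]]
            + tagged[v.pos :]
        )
    else:  # anchored deletion of pos+1 .. pos+ref_len-1
        edited = tagged[: v.pos] + tagged[v.pos + ref_len - 1 :]

    def member(entry):
        p, _ = entry
        if p == "ins":
            return True  # gated: insertion point is strictly inside the CDS
        return in_cds(p)

    ref_cds = "".join(b for p, b in tagged if p != "ins" and in_cds(p))
    alt_cds = "".join(b for entry, b in ((e, e[1]) for e in edited) if member(entry))
    if model.strand == "-":
        ref_cds = str(Seq(ref_cds).reverse_complement())
        alt_cds = str(Seq(alt_cds).reverse_complement())
    prot_ref, prot_alt = _translate(ref_cds), _translate(alt_cds)

    delta = alt_len - ref_len
    if delta % 3 != 0:
        return "frameshift_insertion" if delta > 0 else "frameshift_deletion"
    if _premature(prot_ref, prot_alt):
        return "stopgain"
    if delta == 0:
        if prot_ref == prot_alt:
            return "synonymous_snv"
        for a, b in zip(prot_ref, prot_alt):
            if a != b:
                return "stoploss" if a == "*" else "nonsynonymous_snv"
        return "synonymous_snv"
    return "nonframeshift_insertion" if delta > 0 else "nonframeshift_deletion"


# ---------------------------------------------------------------------------
# Normalization oracle


def enumerate_equivalent(chrom_seq: str, pos: int, ref: str, alt: str):
    """All (pos', ref', alt') representations producing the same edited sequence."""
    edited = chrom_seq[: pos - 1] + alt + chrom_seq[pos - 1 + len(ref) :]
    max_len = len(ref) + len(alt) + 2
    out = []
    for p in range(1, len(chrom_seq) + 1):
        for rlen in range(0, min(max_len, len(chrom_seq) - p + 2)):
            r = chrom_seq[p - 1 : p - 1 + rlen]
            tail = len(chrom_seq) - (p - 1 + rlen)
            a = edited[p - 1 : len(edited) - tail] if tail <= len(edited) - (p - 1) else None
            if a is None or len(a) > max_len:
                continue
            if chrom_seq[: p - 1] + a + chrom_seq[p - 1 + rlen :] != edited:
                continue
            if not r or not a or r == a:
                continue
            out.append((p, r, a))
    return out


def leftmost_minimal(chrom_seq: str, pos: int, ref: str, alt: str):
    """The minimal-length, then leftmost, equivalent representation."""
    candidates = enumerate_equivalent(chrom_seq, pos, ref, alt)
    assert candidates, "variant has no valid representation"
    best_len = min(len(r) + len(a) for _, r, a in candidates)
    minimal = [c for c in candidates if len(c[1]) + len(c[2]) == best_len]
    return min(minimal, key=lambda c: c[0])


# ---------------------------------------------------------------------------
# Shared-mutation set-algebra oracle


def oracle_shared_genes(profiles, groups, level, category) -> set[str]:
    """Genes shared between groups, via plain set intersection."""

    def qualifying(av):
        if category == "rdd":
            return len(av.drugs) > 0
        if category == "rd_expressed":
            return av.highly_expressed
        if category == "rdd_expressed":
            return len(av.drugs) > 0 and av.highly_expressed
        return True

    def tokens(av):
        if level == "gene":
            return {av.gene} if av.gene else set()
        if level == "exact_variant":
            return {av.variant.key}
        return {av.cosmic_id} if av.cosmic_id else set()

    per_sample = {
        s: set().union(*(tokens(av) for av in avs if qualifying(av)), set())
        for s, avs in profiles.items()
    }
    group_unions = [
        set().union(*(per_sample[s] for s in members), set()) for members in groups.values()
    ]
    shared_tokens = set.intersection(*group_unions) if group_unions else set()
    genes = set()
    for s, avs in profiles.items():
        for av in avs:
            if qualifying(av) and (tokens(av) & shared_tokens) and av.gene:
                genes.add(av.gene)
    return genes
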