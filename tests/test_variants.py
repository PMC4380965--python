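"""Variant records, normalization, and VCF/tabular I/O."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from varprio.errors import ConfigurationError, ValidationError
from varprio.reference import DictReference
from varprio.variants import (
    Variant,
    normalize_variant,
    read_variant_table,
    read_varscan_table,
    read_vcf,
    trim_variant,
    write_variants,
)

from _oracles import leftmost_minimal


def test_vaf_computed_from_depths():
    v = Variant("S", "chr1", 10, "A", "G", total_depth=100, alt_depth=30)
    assert v.vaf == pytest.approx(0.30)


def test_depth_and_allele_validation():
    with pytest.raises(ValidationError):
        Variant("S", "chr1", 10, "A", "A")
    with pytest.raises(ValidationError):
        Variant("S", "chr1", 10, "N", "G")
    with pytest.raises(ValidationError):
        Variant("S", "chr1", 10, "A", "G", total_depth=10, alt_depth=20)
    with pytest.raises(ValidationError):
        Variant("S", "chr1", 0, "A", "G")


def test_prefix_trim():
    v = trim_variant(Variant("S", "chr1", 100, "AT", "AG"))
    assert (v.pos, v.ref, v.alt) == (101, "T", "G")


def test_ref_mismatch_raises():
    ref = DictReference({"chr1": "ACGTACGT"})
    with pytest.raises(ValidationError):
        normalize_variant(Variant("S", "chr1", 2, "A", "T"), ref)


def test_left_alignment_of_deletion_in_repeat_run():
    # deleting one T from the TTT run must report the leftmost position
    ref = DictReference({"chr1": "GGACTTTGCA"})
    v = Variant("S", "chr1", 6, "TT", "T")  # rightmost representation
    n = normalize_variant(v, ref)
    assert (n.pos, n.ref, n.alt) == (4, "CT", "C")
    assert normalize_variant(n, ref) == n  # idempotent


@settings(max_examples=200, deadline=None, derandomize=True)
@given(data=st.data())
def test_normalization_matches_bruteforce_leftmost_minimal(data):
    seq = data.draw(
        st.text(alphabet="ACGT", min_size=10, max_size=50), label="reference"
    )
    pos = data.draw(st.integers(3, len(seq) - 5), label="pos")
    kind = data.draw(st.sampled_from(["snv", "ins", "del"]), label="kind")
    ref_base = seq[pos - 1]
    if kind == "snv":
        alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref_base]))
        v = Variant("S", "c", pos, ref_base, alt)
    elif kind == "ins":
        ins = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=3))
        v = Variant("S", "c", pos, ref_base, ref_base + ins)
    else:
        length = data.draw(st.integers(1, min(3, len(seq) - pos)))
        v = Variant("S", "c", pos, seq[pos - 1 : pos + length], ref_base)
    reference = DictReference({"c": seq})
    n = normalize_variant(v, reference)
    assert normalize_variant(n, reference) == n
    exp_pos, exp_ref, exp_alt = leftmost_minimal(seq, v.pos, v.ref, v.alt)
    assert (n.pos, n.ref, n.alt) == (exp_pos, exp_ref, exp_alt)


VARSCAN = """chrom\tposition\tref\tvar\treads1\treads2
chr1\t5\tA\tG\t90\t10
chr1\t12\tA\t+AG\t60\t40
chr1\t20\tT\t-CA\t70\t30
"""


def test_varscan_reader(tmp_path):
    p = tmp_path / "calls.tsv"
    p.write_text(VARSCAN)
    vs = read_varscan_table(p, "S1")
    assert vs[0].vaf == pytest.approx(0.10)
    assert (vs[1].ref, vs[1].alt, vs[1].pos) == ("A", "AAG", 12)  # +AG insertion
    assert (vs[2].ref, vs[2].alt) == ("TCA", "T")  # -CA deletion
    assert all(v.sample_id == "S1" for v in vs)


def test_varscan_missing_column(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("chrom\tposition\tref\treads1\treads2\n")
    with pytest.raises(ConfigurationError, match="var"):
        read_varscan_table(p, "S1")


def test_varscan_header_only(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("chrom\tposition\tref\tvar\treads1\treads2\n")
    assert read_varscan_table(p, "S1") == []


VCF_TEXT = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="allele depths">
##contig=<ID=chr1,length=1000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chr1\t10\t.\tA\tG,T\t.\tPASS\tDP=100\tDP:AD\t100:60,30,10
chr1\t50\t.\tC\t<DEL>\t.\tPASS\tDP=50\tDP\t50
chr1\t70\t.\tAT\tAG\t.\tPASS\t.\tDP:AD\t80:50,30
"""


def test_vcf_reader_multiallelic_split_and_depths(tmp_path):
    p = tmp_path / "calls.vcf"
    p.write_text(VCF_TEXT)
    vs = read_vcf(p, "S1")
    # multi-allelic split: one record per ALT, symbolic <DEL> skipped
    assert [(v.pos, v.ref, v.alt) for v in vs] == [
        (10, "A", "G"),
        (10, "A", "T"),
        (71, "T", "G"),  # shared prefix trimmed on read
    ]
    assert vs[0].alt_depth == 30 and vs[0].total_depth == 100
    assert vs[0].vaf == pytest.approx(0.30)
    assert vs[1].alt_depth == 10 and vs[1].vaf == pytest.approx(0.10)
    assert vs[2].vaf == pytest.approx(30 / 80)


def _random_normalized_variants(n, seed, sample="S1"):
    rng = random.Random(seed)
    seq = "".join(rng.choice("ACGT") for _ in range(500))
    ref = DictReference({"chr1": seq})
    out, seen = [], set()
    while len(out) < n:
        pos = rng.randint(5, 490)
        kind = rng.choice(["snv", "ins", "del", "nodepth"])
        base = seq[pos - 1]
        if kind in ("snv", "nodepth"):
            alt = rng.choice([b for b in "ACGT" if b != base])
            depths = {} if kind == "nodepth" else {"total_depth": 100, "alt_depth": 42}
            v = Variant(sample, "chr1", pos, base, alt, **depths)
        elif kind == "ins":
            v = Variant(sample, "chr1", pos, base, base + rng.choice("ACGT"),
                        total_depth=60, alt_depth=20)
        else:
            v = Variant(sample, "chr1", pos, seq[pos - 1 : pos + 2], base,
                        total_depth=90, alt_depth=30)
        v = normalize_variant(v, ref)
        if v.key in seen:
            continue
        seen.add(v.key)
        out.append(v)
    return out


@pytest.mark.parametrize("fmt", ["tsv", "vcf"])
def test_round_trip(tmp_path, fmt):
    vs = sorted(
        _random_normalized_variants(10, seed=3),
        key=lambda v: (v.chrom, v.pos, v.ref, v.alt),
    )
    path = tmp_path / f"out.{fmt}"
    write_variants(vs, path, format=fmt)
    back = read_variant_table(path) if fmt == "tsv" else read_vcf(path, "S1")
    assert back == vs


@pytest.mark.parametrize("fmt", ["tsv", "vcf"])
def test_round_trip_empty_and_missing_depths(tmp_path, fmt):
    path = tmp_path / f"empty.{fmt}"
    write_variants([], path, format=fmt)
    back = read_variant_table(path) if fmt == "tsv" else read_vcf(path, "S1")
    assert back == []
    v = Variant("S1", "chr1", 10, "A", "G")  # no depths at all
    path2 = tmp_path / f"nodepth.{fmt}"
    write_variants([v], path2, format=fmt)
    back = read_variant_table(path2) if fmt == "tsv" else read_vcf(path2, "S1")
    assert back == [v]
    assert back[0].vaf is None and back[0].total_depth is None
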