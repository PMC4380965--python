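import random

import pytest

from varprio.reference import DictReference
from varprio.simulate import build_genome
from varprio.transcripts import TranscriptModel
from varprio.variants import Variant, normalize_variant

# Small handcrafted gene: 10 bp pad, 5' UTR at 11-13, single-interval CDS
# ATG GAA TGG TAA at 14-25, 3' UTR at 26-30, pad to 40.
TOY_SEQ = "ACGTACGTAC" + "GGC" + "ATGGAATGGTAA" + "CCTGA" + "ACGTACGTAC"


@pytest.fixture(scope="session")
def toy_reference():
    return DictReference({"chr1": TOY_SEQ})


@pytest.fixture(scope="session")
def toy_transcript(toy_reference):
    return TranscriptModel(
        transcript_id="TX_TOY",
        gene_symbol="TOY",
        chrom="chr1",
        strand="+",
        exons=((11, 30),),
        cds=((14, 25),),
        reference=toy_reference,
    )


@pytest.fixture(scope="session")
def toy_transcript_minus():
    """Mirror of the toy gene on the minus strand of a reversed chromosome."""
    from varprio.transcripts import revcomp

    seq = revcomp(TOY_SEQ)
    ref = DictReference({"chr1": seq})
    L = len(TOY_SEQ)
    return TranscriptModel(
        transcript_id="TX_TOYM",
        gene_symbol="TOYM",
        chrom="chr1",
        strand="-",
        exons=((L + 1 - 30, L + 1 - 11),),
        cds=((L + 1 - 25, L + 1 - 14),),
        reference=ref,
    )


@pytest.fixture(scope="session")
def random_genome():
    """A deterministic multi-gene genome shared by classifier tests."""
    rng = random.Random(20240917)
    reference, models = build_genome(rng, 12)
    chrom_seq = reference.fetch("chr1", 1, reference.length("chr1"))
    return reference, models, chrom_seq


def make_random_variant(rng: random.Random, reference, chrom_seq: str, lo: int, hi: int):
    """Random normalized SNV/insertion/deletion within [lo, hi]."""
    while True:
        kind = rng.choice(["snv", "snv", "ins", "del"])
        pos = rng.randint(lo, hi)
        ref_base = chrom_seq[pos - 1]
        if kind == "snv":
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            v = Variant("S", "chr1", pos, ref_base, alt)
        elif kind == "ins":
            ins = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 3)))
            v = Variant("S", "chr1", pos, ref_base, ref_base + ins)
        else:
            length = rng.randint(1, 3)
            if pos + length > len(chrom_seq):
                continue
            v = Variant(
                "S", "chr1", pos, chrom_seq[pos - 1 : pos + length], ref_base
            )
        return normalize_variant(v, reference)
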