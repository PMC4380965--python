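"""The prioritization cascade: filters, boundaries, ts/tv, and summaries."""

import random

import pytest

from varprio.consequence import ConsequenceCall
from varprio.knowledge import DrugGeneInteraction
from varprio.pipeline import run_bundle_sample
from varprio.prioritize import (
    AnnotatedVariant,
    CascadeResult,
    PrioritizationConfig,
    apply_expression_filter,
    filter_by_vaf,
    is_rare,
    rare_deleterious,
    summarize,
    tstv_ratio,
)
from varprio.knowledge import ExpressionTable
from varprio.simulate import ProfileCounts, SampleDesign, StudyDesign, generate_study
from varprio.variants import Variant


def _v(pos, ref, alt, vaf=None, depths=None):
    kw = {}
    if depths:
        kw = {"total_depth": depths[0], "alt_depth": depths[1]}
    return Variant("S", "chr1", pos, ref, alt, vaf=vaf, **kw)


def _av(klass="nonsynonymous_snv", gene="G1", **kw):
    return AnnotatedVariant(
        variant=kw.pop("variant", _v(10, "A", "G", vaf=0.5)),
        consequence=ConsequenceCall(gene, "TX1", klass),
        **kw,
    )


class TestVafFilter:
    def test_presets(self):
        assert PrioritizationConfig.from_preset("cell_line_exome").vaf_min == 0.10
        assert PrioritizationConfig.from_preset("tumor_transcriptome").vaf_min == 0.30

    def test_boundary_inclusive_and_missing_removed(self):
        cfg = PrioritizationConfig.from_preset("cell_line_exome")
        vs = [
            _v(1, "A", "G", depths=(100, 10)),  # exactly 0.10: kept
            _v(2, "A", "G", depths=(100, 5)),   # 0.05: removed
            _v(3, "A", "G"),                    # missing VAF: removed
        ]
        kept = filter_by_vaf(vs, cfg)
        assert [v.pos for v in kept] == [1]

    def test_tumor_preset_boundary(self):
        cfg = PrioritizationConfig.from_preset("tumor_transcriptome")
        assert filter_by_vaf([_v(1, "A", "G", depths=(100, 30))], cfg)


class TestRarity:
    cfg = PrioritizationConfig()

    def test_above_threshold_in_one_db_removed(self):
        assert not is_rare(_av(maf_1000g=0.001), self.cfg)
        assert not is_rare(_av(maf_esp=0.001), self.cfg)

    def test_missing_is_rare(self):
        assert is_rare(_av(), self.cfg)

    def test_boundary_strictly_greater(self):
        assert is_rare(_av(maf_1000g=0.0001), self.cfg)  # exactly at threshold: kept
        assert not is_rare(_av(maf_1000g=0.000100001), self.cfg)

    def test_both_mode(self):
        cfg = PrioritizationConfig(maf_combine="both")
        assert is_rare(_av(maf_1000g=0.001), cfg)  # only one db above
        assert not is_rare(_av(maf_1000g=0.001, maf_esp=0.001), cfg)


def test_rare_deleterious_conjunction():
    cfg = PrioritizationConfig()
    avs = [
        _av("synonymous_snv"),                       # rare, not deleterious
        _av("stopgain"),                             # kept
        _av("nonsynonymous_snv", maf_1000g=0.001),   # deleterious, common
        _av("frameshift_deletion"),                  # kept
        _av("splicing"),                             # not in the default set
    ]
    kept = rare_deleterious(avs, cfg)
    assert [a.consequence.klass for a in kept] == ["stopgain", "frameshift_deletion"]


def test_expression_gate_boundaries():
    cfg = PrioritizationConfig()
    table = ExpressionTable({"G10": 10.0, "G12": 12.0, "GEPS": 10.000001})
    avs = [_av(gene="G12"), _av(gene="G10"), _av(gene="GEPS"), _av(gene="GMISSING")]
    labeled, expressed = apply_expression_filter(avs, table, cfg)
    assert [a.gene for a in expressed] == ["G12", "GEPS"]  # strict > 10
    assert all(not a.highly_expressed for a in labeled if a.gene in ("G10", "GMISSING"))


class TestTsTv:
    def test_worked_example(self):
        vs = [_v(1, "A", "G"), _v(2, "G", "A"), _v(3, "C", "T"), _v(4, "A", "T")]
        assert tstv_ratio(vs) == pytest.approx(3.0)

    def test_indel_only_undefined(self):
        assert tstv_ratio([_v(1, "A", "AT"), _v(2, "ATT", "A")]) is None

    def test_random_against_enumeration(self):
        rng = random.Random(4)
        vs = []
        for i in range(200):
            ref = rng.choice("ACGT")
            alt = rng.choice([b for b in "ACGT" if b != ref])
            vs.append(_v(i + 1, ref, alt))
        ts_pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        ts = sum((v.ref, v.alt) in ts_pairs for v in vs)
        tv = len(vs) - ts
        assert tstv_ratio(vs) == pytest.approx(ts / tv)


def _drug(gene, name, source="S1", curated=True):
    return DrugGeneInteraction(gene, name, None, source, curated)


def test_distinct_drug_names_across_sources():
    av = _av(drugs=(_drug("G1", "dA", "S1"), _drug("G1", "dA", "S2"), _drug("G1", "dB", "S1")))
    result = CascadeResult(
        sample_id="S", config=PrioritizationConfig(), input_variants=[av.variant],
        vaf_passed=[av.variant], annotated=[av], rd=[av], rdd=[av],
        expression_available=False,
    )
    report = summarize(result)
    assert report.n_drugs == 2  # 3 interactions, 2 distinct names


def test_summarize_empty_input():
    result = CascadeResult(
        sample_id="S", config=PrioritizationConfig(), input_variants=[],
        vaf_passed=[], annotated=[], rd=[], rdd=[], expression_available=True,
    )
    report = summarize(result)
    assert report.n_rd == 0 and report.n_rdd == 0 and report.n_drugs == 0
    assert report.cosmic_ids == [] and report.druggable_genes == []
    assert report.tstv_ratio is None
    assert report.n_rd_expressed == 0


@pytest.fixture(scope="module")
def small_bundle():
    counts = ProfileCounts(
        n_rd=8, n_genes_rd=5, n_rd_cosmic=2, n_rdd=2, n_rdd_cosmic=1,
        n_druggable_genes=2, n_drugs=4, n_rd_expressed=3, n_genes_rd_expressed=2,
        n_rd_cosmic_expressed=1, n_rdd_expressed=1, n_rdd_cosmic_expressed=1,
        n_druggable_genes_expressed=1, n_drugs_expressed=3,
    )
    design = StudyDesign(samples=[SampleDesign("S1", counts, preset="cell_line_exome")])
    return generate_study(42, design)


def test_planted_truth_recovery_small(small_bundle):
    _, report = run_bundle_sample(small_bundle, "S1")
    expected = small_bundle.manifest["samples"]["S1"]["expected"]
    for key, value in report.count_fields().items():
        assert value == expected[key], key


def test_subset_chain_and_order_invariance(small_bundle):
    result, report = run_bundle_sample(small_bundle, "S1")
    input_keys = {v.key for v in result.input_variants}
    vaf_keys = {v.key for v in result.vaf_passed}
    rd_keys = {a.variant.key for a in result.rd}
    rdd_keys = {a.variant.key for a in result.rdd}
    rd_expr = {a.variant.key for a in result.rd_expressed}
    rdd_expr = {a.variant.key for a in result.rdd_expressed}
    assert rdd_keys <= rd_keys <= vaf_keys <= input_keys
    assert rd_expr <= rd_keys and rdd_expr <= rdd_keys and rdd_expr <= rd_expr

    # permuting the input yields an identical report
    rng = random.Random(1)
    shuffled = list(small_bundle.variants["S1"])
    rng.shuffle(shuffled)
    bundle_vars = small_bundle.variants
    try:
        bundle_vars["S1"] = shuffled
        _, report2 = run_bundle_sample(small_bundle, "S1")
    finally:
        bundle_vars["S1"] = sorted(shuffled, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    assert report2.to_dict() == report.to_dict()


@pytest.mark.parametrize(
    "override",
    [{"vaf_min": 0.5}, {"fpkm_min": 40.0}, {"maf_max": 0.0},
     {"deleterious_classes": frozenset({"stopgain"})}],
)
def test_monotonicity_under_stricter_thresholds(small_bundle, override):
    _, base = run_bundle_sample(small_bundle, "S1")
    _, strict = run_bundle_sample(small_bundle, "S1", **override)
    for key, value in strict.count_fields().items():
        if key == "n_variants":
            continue
        assert value <= base.count_fields()[key], key


def test_decoys_guard_each_filter(small_bundle):
    """Each planted decoy stratum is held back by exactly its filter."""
    result, base = run_bundle_sample(small_bundle, "S1")
    # low-VAF decoy: the VAF stage removed something
    assert len(result.vaf_passed) < len(result.input_variants)
    # common-variant decoys: disabling the rarity filter adds RD variants
    _, no_maf = run_bundle_sample(small_bundle, "S1", maf_max=1.0)
    assert no_maf.n_rd > base.n_rd
    # synonymous decoy: widening the deleterious set adds RD variants
    wide = frozenset(
        {"nonsynonymous_snv", "stopgain", "stoploss", "frameshift_insertion",
         "frameshift_deletion", "synonymous_snv"}
    )
    _, with_syn = run_bundle_sample(small_bundle, "S1", deleterious_classes=wide)
    assert with_syn.n_rd > base.n_rd
    # non-curated decoy: dropping the curation requirement adds druggable genes
    _, all_curation = run_bundle_sample(small_bundle, "S1", curated_only=False)
    assert len(all_curation.druggable_genes) > len(base.druggable_genes)
    # boundary-FPKM decoy: relaxing the gate below 10 adds expressed RD variants
    _, low_gate = run_bundle_sample(small_bundle, "S1", fpkm_min=9.0)
    assert low_gate.n_rd_expressed > base.n_rd_expressed
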