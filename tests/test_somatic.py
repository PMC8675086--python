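"""Somatic filtering, LOH/copy-loss calls, and second-hit classification."""
import numpy as np
import pytest

from rccland.config import FilterConfig, load_gene_loci
from rccland.pathogenicity import classify_potential_plp
from rccland.somatic import (
    call_copy_loss,
    call_loh,
    classify_second_hit,
    filter_somatic,
)
from rccland.types import CopySegment, GeneLocus, ValidationError

from conftest import make_gcall, make_scall, random_somatic_calls


def verdicts(calls, cfg=None):
    _, traces = filter_somatic(calls, cfg or FilterConfig())
    return [set(t.failed_rules) for t in traces]


@pytest.mark.parametrize(
    "overrides,expected",
    [
        ({}, set()),
        ({"tumor_reads_total": 5, "tumor_reads_alt": 2, "vaf": 0.4}, {"S1_tumor_reads"}),
        ({"tumor_reads_total": 6, "tumor_reads_alt": 3, "vaf": 0.5}, set()),
        ({"normal_reads_total": 9, "normal_reads_alt": 0}, {"S2_normal"}),
        ({"normal_reads_alt": 2}, {"S2_normal"}),  # "at most one read" boundary
        ({"normal_reads_alt": 1}, set()),
        ({"max_mapping_quality": 19}, {"S3_mapq"}),
        ({"tumor_reads_total": 1000, "tumor_reads_alt": 8, "vaf": 0.008}, {"S4_vaf"}),
        ({"in_dbsnp142": True}, {"S5_dbsnp"}),
        ({"in_dbsnp142": True, "in_cosmic": True}, set()),  # COSMIC rescue
    ],
)
def test_somatic_rule_boundaries(overrides, expected):
    (got,) = verdicts([make_scall(**overrides)])
    assert got == expected


def test_somatic_filter_matches_naive_oracle():
    cfg = FilterConfig()
    for seed in range(100):
        rng = np.random.default_rng(seed)
        calls = random_somatic_calls(rng, 50)
        got = verdicts(calls, cfg)
        for c, fails in zip(calls, got):
            expected = set()
            if c.tumor_reads_total <= 5:
                expected.add("S1_tumor_reads")
            if c.normal_reads_total < 10 or c.normal_reads_alt > 1:
                expected.add("S2_normal")
            if c.max_mapping_quality < 20:
                expected.add("S3_mapq")
            if c.vaf < 0.01:
                expected.add("S4_vaf")
            if c.in_dbsnp142 and not c.in_cosmic:
                expected.add("S5_dbsnp")
            assert fails == expected


FANCA = GeneLocus("FANCA", "chr16", 89_800_001, 89_880_000, "q")
VHL = GeneLocus("VHL", "chr3", 10_000_001, 10_020_000, "p")


def test_call_loh_copy_neutral():
    seg = CopySegment("P1", "chr16", 60_000_000, 90_200_000, 1.0, 0)
    assert call_loh([seg], FANCA) is True


@pytest.mark.parametrize(
    "seg,expected",
    [
        (CopySegment("P1", "chr16", 1, 100, 0.5, 0), False),  # no overlap
        (CopySegment("P1", "chr16", 60_000_000, 90_200_000, 1.0, 1), False),
        (CopySegment("P1", "chr16", 60_000_000, 90_200_000, 1.0, None), False),
    ],
)
def test_call_loh_negative_cases(seg, expected):
    assert call_loh([seg], FANCA) is expected


@pytest.mark.parametrize(
    "ratio,expected",
    [(0.55, True), (0.89999, True), (0.9, False), (1.0, False)],  # strict cut-off
)
def test_call_copy_loss_boundary(ratio, expected):
    seg = CopySegment("P1", "chr3", 1, 90_000_000, ratio, 1)
    assert call_copy_loss([seg], VHL) is expected


def test_copy_loss_monotone_in_threshold():
    rng = np.random.default_rng(3)
    segs = [CopySegment("P1", "chr3", 1, 90_000_000, float(r), 1)
            for r in rng.uniform(0.2, 1.5, size=50)]
    previous = -1
    for cut in (0.3, 0.6, 0.9, 1.2):
        cfg = FilterConfig(cnv_loss_ratio=cut)
        n = sum(call_copy_loss([s], VHL, cfg) for s in segs)
        assert n >= previous
        previous = n


def test_overlap_matches_per_base_scan():
    """Interval overlap equals a brute-force per-base membership scan."""
    rng = np.random.default_rng(4)
    locus = GeneLocus("TOY", "chr1", 5_000, 9_000, "p")
    for _ in range(200):
        a = int(rng.integers(1, 15_000))
        b = int(rng.integers(1, 15_000))
        start, end = min(a, b), max(a, b)
        seg = CopySegment("P1", "chr1", start, end, 0.5, 0)
        base_set = set(range(start, end + 1)) & set(range(locus.start, locus.end + 1))
        assert call_copy_loss([seg], locus) is bool(base_set)
        assert call_loh([seg], locus) is bool(base_set)


def _pgv(gene="TSC1", chrom="chr9", pos=135_710_000, patient="P1"):
    return classify_potential_plp(
        make_gcall(patient_id=patient, gene=gene, chrom=chrom, pos=pos,
                   consequence="nonsense")
    )


@pytest.fixture(scope="module")
def loci():
    return load_gene_loci()


def test_second_hit_somatic_truncating(loci):
    pgv = _pgv()
    somatic = [make_scall(gene="TSC1", pos=135_712_345, ref="GA", alt="G",
                          consequence="frameshift")]
    report = classify_second_hit(pgv, somatic, [], loci)
    assert report.hit_type == {"somatic_truncating"}
    assert report.has_second_hit


def test_second_hit_damaging_missense_needs_both_predictors(loci):
    pgv = _pgv()
    hit = make_scall(gene="TSC1", pos=135_712_345, consequence="missense",
                     sift="deleterious", polyphen2="damaging")
    miss = make_scall(gene="TSC1", pos=135_712_346, consequence="missense",
                      sift="deleterious", polyphen2="benign")
    assert classify_second_hit(pgv, [hit], [], loci).hit_type == {"somatic_damaging_missense"}
    assert not classify_second_hit(pgv, [miss], [], loci).has_second_hit


def test_second_hit_copy_loss_on_flcn(loci):
    pgv = _pgv(gene="FLCN", chrom="chr17", pos=17_105_000)
    seg = CopySegment("P1", "chr17", 1, 22_000_000, 0.6, 1)
    report = classify_second_hit(pgv, [], [seg], loci)
    assert report.hit_type == {"copy_loss"}


def test_second_hit_absent_without_events(loci):
    pgv = _pgv(gene="ATM", chrom="chr11", pos=108_100_000)
    report = classify_second_hit(pgv, [], [], loci)
    assert not report.has_second_hit and report.hit_type == frozenset()


def test_germline_site_itself_is_not_a_second_hit(loci):
    pgv = _pgv()
    same_site = make_scall(gene="TSC1", pos=pgv.call.pos, consequence="nonsense")
    assert not classify_second_hit(pgv, [same_site], [], loci).has_second_hit


def test_missing_locus_is_an_error(loci):
    pgv = _pgv()
    with pytest.raises(ValidationError):
        classify_second_hit(pgv, [], [], {})


def test_fixture_second_hit_rates(fixture_results):
    """Reference cohort: 8/10 SRP and 3/18 OCP carriers show second hits."""
    s = fixture_results.summary_
    assert s.second_hit_counts == {"SRP": 8, "OCP": 3, "overall": 11}
    assert s.n_carriers_with_tumor == 28
    assert s.second_hit_rates["SRP"] == 80.0
    assert s.second_hit_rates["OCP"] == 16.7
    assert s.second_hit_rates["overall"] == 39.3
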