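"""P/LP promotion rules and carrier tallies."""
import random

import pytest

from rccland.pathogenicity import (
    call_carriers,
    classify_all,
    classify_potential_plp,
    is_truncating,
)
from rccland.types import PatientRecord, ValidationError

from conftest import make_gcall


@pytest.mark.parametrize(
    "consequence,expected",
    [("nonsense", True), ("frameshift", True), ("splice", True),
     ("missense", False), ("inframe_indel", False), ("synonymous", False)],
)
def test_is_truncating(consequence, expected):
    assert is_truncating(make_gcall(consequence=consequence)) is expected


def test_truncating_promotion():
    pgv = classify_potential_plp(make_gcall(consequence="nonsense"))
    assert pgv is not None and "truncating_rule" in pgv.route


@pytest.mark.parametrize(
    "aa,promoted", [(3, False), (4, True)]  # "more than three amino acids"
)
def test_inframe_size_boundary(aa, promoted):
    pgv = classify_potential_plp(
        make_gcall(consequence="inframe_indel", inframe_aa_change=aa,
                   ref="CAAAAAAAAA", alt="C")
    )
    assert (pgv is not None) is promoted
    if promoted:
        assert pgv.route == {"inframe_rule"}


@pytest.mark.parametrize(
    "sift,pp2,cadd,promoted",
    [
        ("deleterious", "damaging", 25.0, True),
        ("deleterious", "benign", 30.0, False),   # all three predictors required
        ("tolerated", "damaging", 30.0, False),
        ("deleterious", "damaging", 19.0, False),
        ("deleterious", "damaging", None, False),  # missing CADD cannot vote
    ],
)
def test_predictor_rule_requires_concordance(sift, pp2, cadd, promoted):
    pgv = classify_potential_plp(
        make_gcall(consequence="missense", sift=sift, polyphen2=pp2, cadd_phred=cadd)
    )
    assert (pgv is not None) is promoted


def test_clinvar_route_overrides_benign_predictors():
    pgv = classify_potential_plp(
        make_gcall(consequence="missense", sift="tolerated", polyphen2="benign",
                   clinvar_class="pathogenic")
    )
    assert pgv is not None and pgv.route == {"clinvar_route"}


def test_clinvar_benign_vetoes_predictor_only_promotion():
    pgv = classify_potential_plp(
        make_gcall(consequence="missense", sift="deleterious", polyphen2="damaging",
                   cadd_phred=30.0, clinvar_class="benign")
    )
    assert pgv is None


def test_clinvar_benign_does_not_veto_truncating():
    pgv = classify_potential_plp(
        make_gcall(consequence="nonsense", clinvar_class="likely_benign")
    )
    assert pgv is not None and "truncating_rule" in pgv.route


@pytest.mark.parametrize("hgmd,promoted", [("DM", True), ("DP", True), ("DFP", True),
                                           ("FP", True), ("DM?", False)])
def test_hgmd_route(hgmd, promoted):
    pgv = classify_potential_plp(
        make_gcall(consequence="missense", hgmd_class=hgmd)
    )
    assert (pgv is not None) is promoted


def test_routes_accumulate():
    pgv = classify_potential_plp(
        make_gcall(consequence="nonsense", clinvar_class="pathogenic", hgmd_class="DM")
    )
    assert pgv.route == {"truncating_rule", "clinvar_route", "hgmd_route"}


def test_missing_consequence_is_an_error():
    with pytest.raises(ValidationError):
        classify_potential_plp(make_gcall(consequence=None))


def test_promotion_monotone_in_annotations():
    base = make_gcall(consequence="missense", sift="deleterious",
                      polyphen2="damaging", cadd_phred=30.0)
    before = classify_potential_plp(base)
    after = classify_potential_plp(
        make_gcall(consequence="missense", sift="deleterious",
                   polyphen2="damaging", cadd_phred=30.0, clinvar_class="pathogenic")
    )
    assert before is not None and after is not None
    assert before.route <= after.route


def test_classification_is_order_independent():
    calls = [
        make_gcall(patient_id=f"P{i}", pos=10_001_000 + i,
                   consequence=["nonsense", "missense", "splice"][i % 3],
                   sift="deleterious", polyphen2="damaging", cadd_phred=28.0)
        for i in range(30)
    ]
    a = classify_all(calls)
    shuffled = calls[:]
    random.Random(5).shuffle(shuffled)
    b = classify_all(shuffled)
    assert [(p.patient_id, p.call.key, p.route) for p in a] == [
        (p.patient_id, p.call.key, p.route) for p in b
    ]


def _patient(pid):
    return PatientRecord(pid, "male", 50, None, "unknown", True, None)


def test_call_carriers_counts_multi_pgv():
    pgvs = [
        classify_potential_plp(make_gcall(patient_id="P1", gene="VHL")),
        classify_potential_plp(make_gcall(patient_id="P1", gene="TP53",
                                          chrom="chr17", pos=7_561_000)),
        classify_potential_plp(make_gcall(patient_id="P2", gene="ATM",
                                          chrom="chr11", pos=108_100_000)),
    ]
    table = call_carriers(pgvs, [_patient("P1"), _patient("P2"), _patient("P3")])
    assert table.n_carriers == 2
    assert table.n_pgvs == 3
    assert table.multi_pgv_carriers == ["P1"]
    assert table.genes == {"VHL", "TP53", "ATM"}


def test_call_carriers_rejects_orphan_patient():
    pgv = classify_potential_plp(make_gcall(patient_id="GHOST"))
    with pytest.raises(ValidationError):
        call_carriers([pgv], [_patient("P1")])


def test_no_pgvs_means_no_carriers():
    assert call_carriers([], [_patient("P1")]).n_carriers == 0


def test_fixture_carrier_arithmetic(fixture_results):
    """Reference cohort: 32 carriers, 37 PGVs, 25 genes, 5 double-carriers."""
    t = fixture_results.carriers
    assert t.n_carriers == 32
    assert t.n_pgvs == 37
    assert len(t.genes) == 25
    assert len(t.multi_pgv_carriers) == 5
    # total PGVs = carriers + extra variants in double-carriers
    assert t.n_pgvs == t.n_carriers + len(t.multi_pgv_carriers)
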