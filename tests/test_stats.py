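"""Association tests, rounding convention, and cohort summaries."""
import math

import numpy as np
import pytest

from rccland.pathogenicity import CarrierTable, call_carriers, classify_potential_plp
from rccland.stats import association_test, pct, round_half_up, summarize
from rccland.stratify import assign_groups
from rccland.config import default_panels
from rccland.types import PatientRecord, ValidationError

from conftest import make_gcall


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


@pytest.mark.parametrize(
    "value,expected",
    [(9.94, 9.9), (9.95, 10.0), (35.135, 35.1), (17.1532, 17.2), (8.108, 8.1)],
)
def test_round_half_up(value, expected):
    assert round_half_up(value) == expected


def test_symmetric_table_p_one():
    res = association_test([[5, 5], [5, 5]])
    assert res.p_value == pytest.approx(1.0)
    assert not res.significant


def test_extreme_table_matches_closed_form():
    res = association_test([[10, 0], [0, 10]])
    assert res.test_used == "fisher_exact"
    assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-12)


def test_small_expected_cells_choose_fisher():
    res = association_test([[2, 3], [4, 30]])
    assert res.test_used == "fisher_exact"


def test_large_2x2_uses_yates_chi2():
    res = association_test([[12, 59], [20, 231]])
    assert res.test_used == "chi2_yates"
    assert res.significant  # p ~ 0.046 < 0.05


def test_fisher_agrees_with_enumeration_oracle():
    rng = np.random.default_rng(8)
    from scipy.stats import fisher_exact

    for _ in range(300):
        t = rng.integers(0, 12, size=(2, 2))
        if t.sum() == 0:
            continue
        _, p = fisher_exact(t, alternative="two-sided")
        assert p == pytest.approx(fisher_two_sided_oracle(t.tolist()), rel=1e-8, abs=1e-12)


@pytest.mark.parametrize("bad", [[[1, -1], [2, 3]], [[1.5, 2], [3, 4]]])
def test_association_rejects_invalid_counts(bad):
    with pytest.raises(ValidationError):
        association_test(np.array(bad))


def test_rxc_table_uses_plain_chi2():
    res = association_test([[20, 30, 10], [15, 25, 20]])
    assert res.test_used == "chi2"


def _cohort(n, carriers):
    patients = [
        PatientRecord(f"P{i}", "male", 50, None, "unknown", True, None)
        for i in range(n)
    ]
    pgvs = [
        classify_potential_plp(make_gcall(patient_id=f"P{i}")) for i in range(carriers)
    ]
    table = call_carriers(pgvs, patients)
    panels = default_panels()
    return patients, table, assign_groups(table, patients, panels)


def test_summarize_single_carrier_percentage():
    patients, table, groups = _cohort(10, 1)
    s = summarize(patients, table, groups)
    assert s.carrier_pct == 10.0
    assert s.group_sizes == {"SRP": 1, "OCP": 0, "NCP": 9}


def test_summarize_empty_cohort_is_error():
    with pytest.raises(ValidationError):
        summarize([], CarrierTable(), {})


def test_summarize_rejects_inconsistent_patient_sets():
    patients, table, groups = _cohort(10, 1)
    del groups["P0"]
    with pytest.raises(ValidationError):
        summarize(patients, table, groups)


def test_pct_requires_positive_denominator():
    with pytest.raises(ValidationError):
        pct(1, 0)


def test_fixture_percentages_reproduce_published_rounding(fixture_results):
    """Every printed percentage equals half-up rounding of its count ratio."""
    s = fixture_results.summary_
    assert s.carrier_pct == 9.9           # 32/322
    assert s.multi_pgv_pct == 1.6         # 5/322
    assert s.per_gene_pct["VHL"] == 2.2   # 7/322
    assert s.group_pct["SRP"] == 3.7
    assert s.group_pct["OCP"] == 6.2
    assert s.consequence_pct == {
        "frameshift": 35.1, "nonsense": 35.1, "missense": 21.6, "splice": 8.1,
    }
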