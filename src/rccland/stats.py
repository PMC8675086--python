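"""Cohort summary statistics and two-tailed association tests.

Percentages are rounded half-up to one decimal. Categorical associations use
Fisher's exact test (two-sided) when any expected cell count is below 5 on a
2x2 table, otherwise the Pearson chi-squared test with Yates continuity
correction (2x2) or without correction (r x c); significance is declared at
p < alpha (default 0.05), two-tailed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Optional

import numpy as np
from scipy import stats as sps

from .config import FilterConfig
from .pathogenicity import CarrierTable
from .types import PatientRecord, ValidationError

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the convention of the reported percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, denom: int, ndigits: int = 1) -> float:
    if denom <= 0:
        raise ValidationError("percentage with non-positive denominator")
    return round_half_up(100.0 * count / denom, ndigits)


@dataclass(frozen=True)
class AssociationResult:
    statistic: Optional[float]
    p_value: float
    test_used: str
    significant: bool

    def __iter__(self):
        return iter((self.statistic, self.p_value, self.test_used))


def association_test(table, cfg: FilterConfig = None) -> AssociationResult:
    """Two-tailed test of independence on a contingency table of counts.

    2x2 tables with any expected cell < 5 use Fisher's exact test (statistic =
    odds ratio); other 2x2 tables use chi-squared with Yates correction; r x c
    tables use uncorrected chi-squared (with a logged warning when expected
    counts are small, since no exact r x c test is applied).
    """
    cfg = cfg or FilterConfig()
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("association_test requires an r x c table, r,c >= 2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValidationError("association_test requires non-negative integer counts")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    if n == 0:
        raise ValidationError("empty table")
    zero_margin = (row == 0).any() or (col == 0).any()
    if t.shape == (2, 2):
        if zero_margin:
            odds, p = sps.fisher_exact(t, alternative="two-sided")
            return AssociationResult(float(odds) if np.isfinite(odds) else None,
                                     float(p), "fisher_exact", p < cfg.alpha)
        expected = np.outer(row, col) / n
        # exact test when the chi-squared approximation is unsafe: small
        # expected counts or an empty observed cell
        if (expected < 5).any() or (t == 0).any():
            odds, p = sps.fisher_exact(t, alternative="two-sided")
            return AssociationResult(float(odds) if np.isfinite(odds) else None,
                                     float(p), "fisher_exact", p < cfg.alpha)
        res = sps.chi2_contingency(t, correction=True)
        return AssociationResult(float(res.statistic), float(res.pvalue),
                                 "chi2_yates", res.pvalue < cfg.alpha)
    if zero_margin:
        raise ValidationError("zero row/column margin in r x c table")
    expected = np.outer(row, col) / n
    if (expected < 5).any():
        logger.warning("r x c table has expected counts < 5; chi-squared is approximate")
    res = sps.chi2_contingency(t, correction=False)
    return AssociationResult(float(res.statistic), float(res.pvalue),
                             "chi2", res.pvalue < cfg.alpha)


def _distribution(patients: List[PatientRecord], attr) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for p in patients:
        v = attr(p)
        out[v] = out.get(v, 0) + 1
    return out


@dataclass
class CohortSummary:
    """Aggregated cohort counts and percentages (denominators explicit)."""

    n_patients: int
    n_tumor_patients: int
    n_carriers: int
    carrier_pct: float
    n_pgvs: int
    n_genes: int
    n_multi_pgv: int
    multi_pgv_pct: float
    per_gene_carriers: Dict[str, int]
    per_gene_pct: Dict[str, float]
    consequence_counts: Dict[str, int]
    consequence_pct: Dict[str, float]
    group_sizes: Dict[str, int]
    group_pct: Dict[str, float]
    per_group_clinical: Dict[str, Dict[str, Dict[str, int]]]
    n_carriers_with_tumor: int
    second_hit_counts: Dict[str, int] = field(default_factory=dict)
    second_hit_rates: Dict[str, float] = field(default_factory=dict)


def summarize(
    patients: Iterable[PatientRecord],
    carriers: CarrierTable,
    assignments: Dict,
    second_hit_reports: Optional[Dict[str, list]] = None,
    cfg: FilterConfig = None,
) -> CohortSummary:
    """Compute every reported cohort-level tally from the component tables."""
    cfg = cfg or FilterConfig()
    patients = list(patients)
    if not patients:
        raise ValidationError("empty cohort")
    pids = {p.patient_id for p in patients}
    if set(assignments) != pids:
        raise ValidationError("assignments and patient table disagree on patient set")
    if not set(carriers.by_patient) <= pids:
        raise ValidationError("carrier table contains unknown patients")

    n = len(patients)
    n_tumor = sum(p.tumor_tissue for p in patients)
    all_pgvs = [pgv for v in carriers.by_patient.values() for pgv in v]

    per_gene: Dict[str, set] = {}
    for pgv in all_pgvs:
        per_gene.setdefault(pgv.gene, set()).add(pgv.patient_id)
    per_gene_carriers = {g: len(s) for g, s in sorted(per_gene.items())}

    consequence_counts: Dict[str, int] = {}
    for pgv in all_pgvs:
        csq = pgv.call.consequence
        consequence_counts[csq] = consequence_counts.get(csq, 0) + 1

    sizes = {"SRP": 0, "OCP": 0, "NCP": 0}
    members: Dict[str, List[PatientRecord]] = {"SRP": [], "OCP": [], "NCP": []}
    for p in patients:
        g = assignments[p.patient_id].group
        sizes[g] += 1
        members[g].append(p)
    if sum(sizes.values()) != n:
        raise ValidationError("group sizes do not sum to cohort size")

    per_group_clinical = {
        g: {
            "sex": _distribution(ps, lambda p: p.sex),
            "age_band": _distribution(
                ps, lambda p: "le_cutoff" if p.age_years <= cfg.age_cutoff else "gt_cutoff"
            ),
            "smoker": _distribution(
                ps, lambda p: {True: "yes", False: "no", None: "unknown"}[p.smoker]
            ),
            "stage": _distribution(ps, lambda p: p.stage),
        }
        for g, ps in members.items()
    }

    tumor_pids = {p.patient_id for p in patients if p.tumor_tissue}
    carriers_with_tumor = [pid for pid in carriers.carriers if pid in tumor_pids]

    summary = CohortSummary(
        n_patients=n,
        n_tumor_patients=n_tumor,
        n_carriers=carriers.n_carriers,
        carrier_pct=pct(carriers.n_carriers, n),
        n_pgvs=carriers.n_pgvs,
        n_genes=len(carriers.genes),
        n_multi_pgv=len(carriers.multi_pgv_carriers),
        multi_pgv_pct=pct(len(carriers.multi_pgv_carriers), n),
        per_gene_carriers=per_gene_carriers,
        per_gene_pct={g: pct(c, n) for g, c in per_gene_carriers.items()},
        consequence_counts=dict(sorted(consequence_counts.items())),
        consequence_pct={
            c: pct(k, carriers.n_pgvs) for c, k in sorted(consequence_counts.items())
        } if carriers.n_pgvs else {},
        group_sizes=sizes,
        group_pct={g: pct(c, n) for g, c in sizes.items()},
        per_group_clinical=per_group_clinical,
        n_carriers_with_tumor=len(carriers_with_tumor),
    )

    if second_hit_reports is not None:
        from .somatic import has_any_hit

        counts = {"SRP": 0, "OCP": 0, "overall": 0}
        denoms = {"SRP": 0, "OCP": 0, "overall": 0}
        for pid in carriers_with_tumor:
            g = assignments[pid].group
            denoms[g] += 1
            denoms["overall"] += 1
            if pid in second_hit_reports and has_any_hit(second_hit_reports[pid]):
                counts[g] += 1
                counts["overall"] += 1
        summary.second_hit_counts = {
            k: counts[k] for k in ("SRP", "OCP", "overall")
        }
        summary.second_hit_rates = {
            k: pct(counts[k], denoms[k]) if denoms[k] else float("nan")
            for k in ("SRP", "OCP", "overall")
        }
    return summary
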