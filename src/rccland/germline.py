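"""Germline variant filtering.

Five rules, applied in order and all recorded per call:

R1_reads       >=5 reads covering the site with >=3 alternate reads
R2_af          heterozygous allele fraction within [0.3, 0.7] (inclusive)
R3_popfreq     <1% in every population database where the variant is observed
               (absence from a database is not evidence of commonness)
R4_cohortfreq  carried by <5% of the cohort, counted over patients and
               computed on the set surviving R1-R3
R5_relevance   functional relevance: synonymous and non-exonic variants are
               excluded, except splice variants
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, List, Tuple

from .config import FilterConfig
from .types import GermlineVariantCall, ValidationError

RULES = ("R1_reads", "R2_af", "R3_popfreq", "R4_cohortfreq", "R5_relevance")


@dataclass(frozen=True)
class FilterTrace:
    """Per-call audit record: which rules failed (empty = pass)."""

    call: GermlineVariantCall
    failed_rules: tuple

    @property
    def verdict(self) -> str:
        return "pass" if not self.failed_rules else "fail"


def _fails_r1(c: GermlineVariantCall, cfg: FilterConfig) -> bool:
    return c.reads_total < cfg.germline_min_reads_total or (
        c.reads_alt < cfg.germline_min_reads_alt
    )


def _fails_r2(c: GermlineVariantCall, cfg: FilterConfig) -> bool:
    return not (cfg.germline_af_low <= c.allele_fraction <= cfg.germline_af_high)


def _fails_r3(c: GermlineVariantCall, cfg: FilterConfig) -> bool:
    return any(f >= cfg.popfreq_max for f in c.pop_freqs.values())


def _fails_r5(c: GermlineVariantCall) -> bool:
    return c.consequence in {"synonymous", "non_exonic"}


def filter_germline(
    calls: Iterable[GermlineVariantCall], cohort_size: int, cfg: FilterConfig = None
) -> Tuple[List[GermlineVariantCall], List[FilterTrace]]:
    """Apply the five-rule germline filter standard.

    Returns the passing calls and one :class:`FilterTrace` per input call.
    The cohort-frequency rule counts distinct carriers per (chrom, pos, ref,
    alt) among calls surviving R1-R3, against ``cohort_size`` patients.
    """
    cfg = cfg or FilterConfig()
    if cohort_size < 1:
        raise ValidationError("cohort_size must be >= 1")
    calls = list(calls)

    early_fail = []
    for c in calls:
        fails = []
        if _fails_r1(c, cfg):
            fails.append("R1_reads")
        if _fails_r2(c, cfg):
            fails.append("R2_af")
        if _fails_r3(c, cfg):
            fails.append("R3_popfreq")
        early_fail.append(fails)

    carriers = defaultdict(set)
    for c, fails in zip(calls, early_fail):
        if not fails:
            carriers[c.key].add(c.patient_id)

    passing, traces = [], []
    for c, fails in zip(calls, early_fail):
        fails = list(fails)
        if not fails and len(carriers[c.key]) / cohort_size >= cfg.cohort_freq_max:
            fails.append("R4_cohortfreq")
        if _fails_r5(c):
            fails.append("R5_relevance")
        traces.append(FilterTrace(call=c, failed_rules=tuple(fails)))
        if not fails:
            passing.append(c)
    return passing, traces
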