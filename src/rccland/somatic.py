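"""Somatic variant filtering and second-hit detection for PGV carriers.

Somatic filter rules (tumor/normal paired calls):

S1_tumor_reads   more than 5 reads covering the site in tumor
S2_normal        >=10x normal coverage with at most one alternate read
S3_mapq          maximum mapping quality of alternate reads >=20
S4_vaf           variant allele fraction >=1%
S5_dbsnp         dbSNP 142 membership removes the call unless COSMIC documents it

Second hits on the remaining allele of a germline-hit gene, per the two-hit
model: a passing somatic truncating variant, a somatic missense called
deleterious by SIFT and damaging by PolyPhen-2, LOH (overlapping segment with
minor allele copy number zero, including copy-neutral LOH), or copy loss
(tumor/normal ratio below 0.9 over the gene locus). The germline variant's
own site is excluded from somatic matching so the first hit is never counted
twice.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

from .config import FilterConfig
from .types import (
    CopySegment,
    GeneLocus,
    PgvCall,
    SecondHitReport,
    SomaticVariantCall,
    TRUNCATING_CONSEQUENCES,
    ValidationError,
)

logger = logging.getLogger(__name__)

SOMATIC_RULES = ("S1_tumor_reads", "S2_normal", "S3_mapq", "S4_vaf", "S5_dbsnp")


@dataclass(frozen=True)
class SomaticFilterTrace:
    call: SomaticVariantCall
    failed_rules: tuple

    @property
    def verdict(self) -> str:
        return "pass" if not self.failed_rules else "fail"


def filter_somatic(
    calls: Iterable[SomaticVariantCall], cfg: FilterConfig = None
) -> Tuple[List[SomaticVariantCall], List[SomaticFilterTrace]]:
    """Apply the somatic filter standard; returns passing calls and traces."""
    cfg = cfg or FilterConfig()
    passing, traces = [], []
    for c in calls:
        fails = []
        if c.tumor_reads_total < cfg.somatic_min_tumor_reads:
            fails.append("S1_tumor_reads")
        if (
            c.normal_reads_total < cfg.somatic_min_normal_depth
            or c.normal_reads_alt > cfg.somatic_max_normal_alt
        ):
            fails.append("S2_normal")
        if c.max_mapping_quality < cfg.somatic_min_mapq:
            fails.append("S3_mapq")
        if c.vaf < cfg.somatic_min_vaf:
            fails.append("S4_vaf")
        if c.in_dbsnp142 and not c.in_cosmic:
            fails.append("S5_dbsnp")
        traces.append(SomaticFilterTrace(call=c, failed_rules=tuple(fails)))
        if not fails:
            passing.append(c)
    return passing, traces


def call_loh(segments: Iterable[CopySegment], locus: GeneLocus) -> bool:
    """True iff a segment overlapping the locus has minor allele copy number 0.

    Segments without an allele-specific estimate cannot support an LOH call
    (logged once per locus); copy-neutral LOH qualifies.
    """
    hit = False
    for s in segments:
        if not s.overlaps(locus.chrom, locus.start, locus.end):
            continue
        if s.minor_allele_copies is None:
            logger.warning(
                "segment %s %s:%d-%d lacks minor allele copies; cannot call LOH at %s",
                s.patient_id, s.chrom, s.start, s.end, locus.gene,
            )
            continue
        if s.minor_allele_copies == 0:
            hit = True
    return hit


def call_copy_loss(
    segments: Iterable[CopySegment], locus: GeneLocus, cfg: FilterConfig = None
) -> bool:
    """True iff an overlapping segment has tumor/normal ratio below the cut-off."""
    cfg = cfg or FilterConfig()
    return any(
        s.copy_ratio < cfg.cnv_loss_ratio
        for s in segments
        if s.overlaps(locus.chrom, locus.start, locus.end)
    )


def classify_second_hit(
    pgv: PgvCall,
    somatic_passing: Iterable[SomaticVariantCall],
    segments: Iterable[CopySegment],
    loci: Dict[str, GeneLocus],
    cfg: FilterConfig = None,
) -> SecondHitReport:
    """Collect second-hit evidence for one PGV in one patient's tumor."""
    cfg = cfg or FilterConfig()
    gene = pgv.gene
    if gene not in loci:
        raise ValidationError(f"no locus available for PGV gene {gene}")
    locus = loci[gene]
    pid = pgv.patient_id
    germ_site = (pgv.call.chrom, pgv.call.pos)

    hits = set()
    evidence = []
    for s in somatic_passing:
        if s.patient_id != pid or s.gene != gene:
            continue
        if (s.chrom, s.pos) == germ_site:
            continue  # the first hit itself
        if s.consequence in TRUNCATING_CONSEQUENCES:
            hits.add("somatic_truncating")
            evidence.append(s)
        elif (
            s.consequence == "missense"
            and s.sift == "deleterious"
            and s.polyphen2 == "damaging"
        ):
            hits.add("somatic_damaging_missense")
            evidence.append(s)

    patient_segments = [s for s in segments if s.patient_id == pid]
    if call_loh(patient_segments, locus):
        hits.add("loh")
        evidence.extend(
            s for s in patient_segments
            if s.overlaps(locus.chrom, locus.start, locus.end)
            and s.minor_allele_copies == 0
        )
    if call_copy_loss(patient_segments, locus, cfg):
        hits.add("copy_loss")
        evidence.extend(
            s for s in patient_segments
            if s.overlaps(locus.chrom, locus.start, locus.end)
            and s.copy_ratio < cfg.cnv_loss_ratio
        )

    return SecondHitReport(
        patient_id=pid, gene=gene, hit_type=frozenset(hits), evidence=tuple(dict.fromkeys(evidence))
    )


def second_hits_for_cohort(
    carriers,
    patients,
    somatic_passing: Iterable[SomaticVariantCall],
    segments: Iterable[CopySegment],
    loci: Dict[str, GeneLocus],
    cfg: FilterConfig = None,
) -> Dict[str, List[SecondHitReport]]:
    """Run the second-hit classifier for every carrier with tumor data.

    Returns patient_id -> one report per PGV gene.
    """
    cfg = cfg or FilterConfig()
    tumor_patients = {p.patient_id for p in patients if p.tumor_tissue}
    somatic_passing = list(somatic_passing)
    segments = list(segments)
    reports: Dict[str, List[SecondHitReport]] = {}
    for pid in carriers.carriers:
        if pid not in tumor_patients:
            continue
        seen_genes = set()
        per_patient = []
        for pgv in carriers.by_patient[pid]:
            if pgv.gene in seen_genes:
                continue
            seen_genes.add(pgv.gene)
            per_patient.append(
                classify_second_hit(pgv, somatic_passing, segments, loci, cfg)
            )
        reports[pid] = per_patient
    return reports


def has_any_hit(reports: List[SecondHitReport]) -> bool:
    return any(r.has_second_hit for r in reports)
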