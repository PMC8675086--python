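"""Rule-based promotion of filtered germline variants to P/LP (PGV) status.

A variant is promoted when any of five routes fires:

truncating_rule  nonsense, frameshift, or canonical splice-site variant
inframe_rule     in-frame indel affecting more than three amino acids
predictor_rule   missense called deleterious by SIFT, damaging by PolyPhen-2
                 AND with CADD Phred above the configured cut-off (all three)
clinvar_route    classified pathogenic / likely pathogenic in ClinVar
hgmd_route       HGMD class DM, DP, DFP or FP

A ClinVar benign / likely-benign assertion vetoes a promotion that rests on
the predictor rule alone (modelling the manual ACMG review step); it never
overrides a truncating call or a positive database route.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

from .config import FilterConfig
from .types import (
    GermlineVariantCall,
    PgvCall,
    TRUNCATING_CONSEQUENCES,
    ValidationError,
)

HGMD_PROMOTING = {"DM", "DP", "DFP", "FP"}
CLINVAR_PLP = {"pathogenic", "likely_pathogenic"}
CLINVAR_BENIGN = {"benign", "likely_benign"}


def is_truncating(call: GermlineVariantCall) -> bool:
    """True for presumed loss-of-function consequences (nonsense/frameshift/splice)."""
    if call.consequence is None:
        raise ValidationError(f"{call.patient_id} {call.chrom}:{call.pos}: no consequence")
    return call.consequence in TRUNCATING_CONSEQUENCES


def classify_potential_plp(
    call: GermlineVariantCall, cfg: FilterConfig = None
) -> Optional[PgvCall]:
    """Classify one filtered call; returns a :class:`PgvCall` or ``None``."""
    cfg = cfg or FilterConfig()
    if call.consequence is None:
        raise ValidationError(f"{call.patient_id} {call.chrom}:{call.pos}: no consequence")
    routes = set()
    if is_truncating(call):
        routes.add("truncating_rule")
    if call.consequence == "inframe_indel" and call.inframe_aa_change >= cfg.inframe_min_aa:
        routes.add("inframe_rule")
    if call.consequence == "missense":
        votes = [
            call.sift == "deleterious",
            call.polyphen2 == "damaging",
            call.cadd_phred is not None and call.cadd_phred >= cfg.cadd_deleterious_min,
        ]
        concordant = all(votes) if cfg.predictor_rule_requires_all else sum(votes) >= 2
        if concordant:
            routes.add("predictor_rule")
    if call.clinvar_class in CLINVAR_PLP:
        routes.add("clinvar_route")
    if call.hgmd_class in HGMD_PROMOTING:
        routes.add("hgmd_route")
    # manual-review model: a benign ClinVar assertion defeats in-silico-only evidence
    if call.clinvar_class in CLINVAR_BENIGN and routes == {"predictor_rule"}:
        routes = set()
    if not routes:
        return None
    return PgvCall(call=call, route=frozenset(routes))


def classify_all(
    calls: Iterable[GermlineVariantCall], cfg: FilterConfig = None
) -> List[PgvCall]:
    """Classify a list of filtered calls, order-independent and deterministic."""
    cfg = cfg or FilterConfig()
    pgvs = [p for p in (classify_potential_plp(c, cfg) for c in calls) if p is not None]
    pgvs.sort(key=lambda p: (p.patient_id, p.call.key))
    return pgvs


@dataclass
class CarrierTable:
    """Carriers and their PGVs, with the cohort-level tallies derived from them."""

    by_patient: Dict[str, List[PgvCall]] = field(default_factory=dict)

    @property
    def carriers(self) -> List[str]:
        return sorted(self.by_patient)

    @property
    def n_carriers(self) -> int:
        return len(self.by_patient)

    @property
    def n_pgvs(self) -> int:
        return sum(len(v) for v in self.by_patient.values())

    @property
    def genes(self) -> set:
        return {p.gene for v in self.by_patient.values() for p in v}

    @property
    def multi_pgv_carriers(self) -> List[str]:
        return sorted(pid for pid, v in self.by_patient.items() if len(v) > 1)

    def genes_of(self, patient_id: str) -> set:
        return {p.gene for p in self.by_patient.get(patient_id, [])}


def call_carriers(pgvs: Iterable[PgvCall], patients) -> CarrierTable:
    """Group PGVs per patient; every PGV's patient must exist in the cohort."""
    known = {p.patient_id for p in patients}
    table = defaultdict(list)
    for pgv in pgvs:
        if pgv.patient_id not in known:
            raise ValidationError(f"PGV for unknown patient {pgv.patient_id}")
        table[pgv.patient_id].append(pgv)
    for v in table.values():
        v.sort(key=lambda p: p.call.key)
    return CarrierTable(by_patient=dict(table))
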