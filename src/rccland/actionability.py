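"""Clinical actionability tiering from a packaged evidence table.

The evidence table (gene, alteration class, basis, OncoKB-style level,
candidate therapy, oncogenic flag) is a versioned TSV standing in for live
OncoKB/NCCN lookups, so runs are reproducible and offline. A patient is
actionable when any passing somatic variant, any PGV, or dMMR status matches
an evidence row with a level; the exclusive patient-level breakdown uses the
precedence somatic > germline > dMMR. Only patients with tumor data are
evaluated.
"""
from __future__ import annotations

import csv
import importlib.resources as resources
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

from .pathogenicity import CarrierTable
from .types import (
    ActionabilityCall,
    ConfigError,
    PatientRecord,
    SomaticVariantCall,
    TRUNCATING_CONSEQUENCES,
)

LEVELS = {"1", "2", "3A", "3B", "4", "R1", "R2"}
ALTERATION_CLASSES = {"any", "truncating", "missense", "plp", "marker"}
_NONCODING = {"synonymous", "non_exonic"}


@dataclass(frozen=True)
class EvidenceRow:
    gene: str
    alteration_class: str
    basis: str
    level: str  # empty string = oncogenic but not actionable
    therapy: str
    oncogenic: bool


class EvidenceTable:
    """Lookup of (gene, alteration class, basis) -> level/therapy."""

    def __init__(self, rows: Iterable[EvidenceRow]):
        self.rows = list(rows)
        for r in self.rows:
            if r.alteration_class not in ALTERATION_CLASSES:
                raise ConfigError(f"unknown alteration class {r.alteration_class!r}")
            if r.basis not in {"somatic", "germline", "dmmr"}:
                raise ConfigError(f"unknown basis {r.basis!r}")
            if r.level and r.level not in LEVELS:
                raise ConfigError(f"unknown evidence level {r.level!r}")

    @classmethod
    def from_tsv(cls, path) -> "EvidenceTable":
        rows = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = ["gene", "alteration_class", "basis", "level", "therapy", "oncogenic"]
            if reader.fieldnames is None or [
                c for c in required if c not in reader.fieldnames
            ]:
                raise ConfigError(f"evidence table requires columns {required}")
            for row in reader:
                rows.append(
                    EvidenceRow(
                        gene=row["gene"].strip(),
                        alteration_class=row["alteration_class"].strip(),
                        basis=row["basis"].strip(),
                        level=row["level"].strip(),
                        therapy=row["therapy"].strip(),
                        oncogenic=row["oncogenic"].strip().lower() == "yes",
                    )
                )
        return cls(rows)

    @classmethod
    def packaged(cls) -> "EvidenceTable":
        """The synthetic evidence table shipped with the package."""
        with resources.as_file(
            resources.files("rccland.data").joinpath("evidence.tsv")
        ) as p:
            return cls.from_tsv(p)

    def somatic_rows(self, gene: str, consequence: Optional[str]) -> List[EvidenceRow]:
        if consequence in _NONCODING:
            return []
        out = []
        for r in self.rows:
            if r.basis != "somatic" or r.gene != gene or not r.level:
                continue
            if r.alteration_class == "any":
                out.append(r)
            elif r.alteration_class == "truncating" and consequence in TRUNCATING_CONSEQUENCES:
                out.append(r)
            elif r.alteration_class == "missense" and consequence == "missense":
                out.append(r)
        return out

    def germline_rows(self, gene: str) -> List[EvidenceRow]:
        return [
            r
            for r in self.rows
            if r.basis == "germline" and r.gene == gene and r.level
            and r.alteration_class in {"plp", "any"}
        ]

    def dmmr_rows(self) -> List[EvidenceRow]:
        return [r for r in self.rows if r.basis == "dmmr" and r.level]

    def oncogenic_genes(self) -> set:
        return {r.gene for r in self.rows if r.basis == "somatic" and r.oncogenic}


def tier_actionability(
    patient: PatientRecord,
    somatic_calls: Iterable[SomaticVariantCall],
    pgvs: Iterable,
    evidence: EvidenceTable,
) -> List[ActionabilityCall]:
    """All actionability calls for one patient with tumor data."""
    calls: List[ActionabilityCall] = []
    seen = set()
    for s in somatic_calls:
        for r in evidence.somatic_rows(s.gene, s.consequence):
            key = ("somatic", r.gene, r.level, r.therapy)
            if key not in seen:
                seen.add(key)
                calls.append(
                    ActionabilityCall(
                        patient_id=patient.patient_id,
                        basis="somatic",
                        gene_or_marker=r.gene,
                        level=r.level,
                        candidate_therapy=r.therapy,
                    )
                )
    for pgv in pgvs:
        for r in evidence.germline_rows(pgv.gene):
            key = ("germline", r.gene, r.level, r.therapy)
            if key not in seen:
                seen.add(key)
                calls.append(
                    ActionabilityCall(
                        patient_id=patient.patient_id,
                        basis="germline",
                        gene_or_marker=r.gene,
                        level=r.level,
                        candidate_therapy=r.therapy,
                    )
                )
    if patient.mmr_deficient is True:
        for r in evidence.dmmr_rows():
            calls.append(
                ActionabilityCall(
                    patient_id=patient.patient_id,
                    basis="dmmr",
                    gene_or_marker="dMMR",
                    level=r.level,
                    candidate_therapy=r.therapy,
                )
            )
    return calls


@dataclass
class ActionabilitySummary:
    """Patient-exclusive actionability tallies over the tumor-data denominator."""

    denominator: int
    calls: Dict[str, List[ActionabilityCall]]
    exclusive_counts: Dict[str, int]  # somatic / germline / dmmr, precedence-resolved
    n_actionable: int
    n_oncogenic_only: int


_PRECEDENCE = ("somatic", "germline", "dmmr")


def cohort_actionability(
    patients: Iterable[PatientRecord],
    somatic_passing_by_patient: Dict[str, List[SomaticVariantCall]],
    carriers: CarrierTable,
    evidence: EvidenceTable,
) -> ActionabilitySummary:
    """Tier every patient with tumor data; exclusive somatic>germline>dMMR counts."""
    tumor_patients = [p for p in patients if p.tumor_tissue]
    calls: Dict[str, List[ActionabilityCall]] = {}
    exclusive = {b: 0 for b in _PRECEDENCE}
    oncogenic_genes = evidence.oncogenic_genes()
    n_oncogenic_only = 0
    for p in tumor_patients:
        pcalls = tier_actionability(
            p,
            somatic_passing_by_patient.get(p.patient_id, []),
            carriers.by_patient.get(p.patient_id, []),
            evidence,
        )
        if pcalls:
            calls[p.patient_id] = pcalls
            bases = {c.basis for c in pcalls}
            for b in _PRECEDENCE:
                if b in bases:
                    exclusive[b] += 1
                    break
        else:
            somatic_genes = {
                s.gene
                for s in somatic_passing_by_patient.get(p.patient_id, [])
                if s.consequence not in _NONCODING
            }
            if somatic_genes & oncogenic_genes:
                n_oncogenic_only += 1
    return ActionabilitySummary(
        denominator=len(tumor_patients),
        calls=calls,
        exclusive_counts=exclusive,
        n_actionable=len(calls),
        n_oncogenic_only=n_oncogenic_only,
    )
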