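"""Cohort stratification by germline status.

Patients partition into SRP (any PGV in a syndromic-RCC gene; takes
precedence), OCP (any PGV, none syndromic), and NCP (no PGV). OCP carriers
subclassify as DDR vs non-DDR by whether any PGV gene is a DNA-damage-repair
gene. The age dichotomy (<=46 vs >46 years) follows genetic-testing
guideline practice for RCC.
"""
from __future__ import annotations

from typing import Dict, Iterable

import numpy as np

from .config import FilterConfig, GenePanels
from .pathogenicity import CarrierTable
from .types import GroupAssignment, PatientRecord, ValidationError


def assign_group(patient_id: str, pgv_genes: set, panels: GenePanels) -> GroupAssignment:
    """Assign one patient given the set of genes carrying their PGVs."""
    outside = pgv_genes - panels.panel
    if outside:
        raise ValidationError(
            f"{patient_id}: PGV gene(s) outside the assay panel: {sorted(outside)}"
        )
    if pgv_genes & panels.syndromic_rcc:
        return GroupAssignment(patient_id=patient_id, group="SRP")
    if pgv_genes:
        sub = "DDR" if pgv_genes & panels.ddr else "non_DDR"
        return GroupAssignment(patient_id=patient_id, group="OCP", ocp_subclass=sub)
    return GroupAssignment(patient_id=patient_id, group="NCP")


def assign_groups(
    carriers: CarrierTable, patients: Iterable[PatientRecord], panels: GenePanels
) -> Dict[str, GroupAssignment]:
    """Partition the whole cohort; every patient lands in exactly one group."""
    return {
        p.patient_id: assign_group(p.patient_id, carriers.genes_of(p.patient_id), panels)
        for p in patients
    }


def group_sizes(assignments: Dict[str, GroupAssignment]) -> Dict[str, int]:
    sizes = {"SRP": 0, "OCP": 0, "NCP": 0}
    for a in assignments.values():
        sizes[a.group] += 1
    return sizes


def age_contingency(
    assignments: Dict[str, GroupAssignment],
    patients: Iterable[PatientRecord],
    cfg: FilterConfig = None,
) -> np.ndarray:
    """2x2 table: rows = age (<=cutoff, >cutoff), columns = (carrier, non-carrier).

    Carrier means group SRP or OCP. Cells sum to the cohort size.
    """
    cfg = cfg or FilterConfig()
    table = np.zeros((2, 2), dtype=int)
    for p in patients:
        row = 0 if p.age_years <= cfg.age_cutoff else 1
        col = 0 if assignments[p.patient_id].group in {"SRP", "OCP"} else 1
        table[row, col] += 1
    return table
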