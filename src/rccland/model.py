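"""Model/Results facade over the interpretation pipeline.

:class:`RccCohortModel` bundles a cohort's inputs (clinical table, germline
and somatic calls, copy-number segments) with the configuration, panels,
locus table and evidence table; ``fit()`` runs filtering, P/LP
classification, stratification, second-hit detection, actionability tiering
and the association tests, returning an :class:`RccCohortResults` whose
``summary()`` prints the cohort report.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as rio
from .actionability import ActionabilitySummary, EvidenceTable, cohort_actionability
from .config import FilterConfig, GenePanels, default_panels, load_gene_loci
from .germline import filter_germline
from .pathogenicity import CarrierTable, call_carriers, classify_all
from .signatures import MutationCatalog, build_catalog, cosine_match, run_nmf
from .somatic import filter_somatic, second_hits_for_cohort
from .stats import AssociationResult, CohortSummary, association_test, summarize
from .stratify import age_contingency, assign_groups
from .types import ValidationError


class RccCohortModel:
    """A renal-cell-carcinoma cohort ready for germline/somatic interpretation."""

    def __init__(
        self,
        patients,
        germline_calls,
        somatic_calls=(),
        segments=(),
        config: Optional[FilterConfig] = None,
        panels: Optional[GenePanels] = None,
        loci: Optional[dict] = None,
        evidence: Optional[EvidenceTable] = None,
    ):
        self.patients = list(patients)
        if not self.patients:
            raise ValidationError("empty cohort")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate patient_id in cohort")
        self.germline_calls = list(germline_calls)
        self.somatic_calls = list(somatic_calls)
        self.segments = list(segments)
        self.config = config or FilterConfig()
        self.panels = panels or default_panels()
        self.loci = loci or load_gene_loci()
        self.evidence = evidence or EvidenceTable.packaged()

    @classmethod
    def from_files(
        cls,
        clinical_tsv,
        germline_vcf,
        somatic_vcf=None,
        seg_tsv=None,
        config_yaml=None,
        panels_yaml=None,
        evidence_tsv=None,
        annotation_dialect: str = "default",
        seg_zero_based: bool = False,
    ) -> "RccCohortModel":
        """Build a model from the standard file set."""
        return cls(
            patients=rio.read_clinical_tsv(clinical_tsv),
            germline_calls=rio.read_germline_vcf(germline_vcf, annotation_dialect),
            somatic_calls=(
                rio.read_somatic_vcf(somatic_vcf, annotation_dialect) if somatic_vcf else ()
            ),
            segments=rio.read_seg(seg_tsv, seg_zero_based) if seg_tsv else (),
            config=FilterConfig.from_yaml(config_yaml) if config_yaml else None,
            panels=GenePanels.from_yaml(panels_yaml) if panels_yaml else None,
            evidence=EvidenceTable.from_tsv(evidence_tsv) if evidence_tsv else None,
        )

    def fit(self, signatures: bool = False, k: Optional[int] = None, seed: int = 0,
            n_restarts: int = 10) -> "RccCohortResults":
        """Run the full interpretation pipeline.

        With ``signatures=True`` the per-group 96-context catalog is built and
        factorized (``k=None`` scans 1..5 and keeps the smallest k whose
        incremental reconstruction-error improvement falls below 5%).
        """
        cfg = self.config
        n = len(self.patients)

        g_pass, g_traces = filter_germline(self.germline_calls, n, cfg)
        pgvs = classify_all(g_pass, cfg)
        carriers = call_carriers(pgvs, self.patients)
        assignments = assign_groups(carriers, self.patients, self.panels)

        s_pass, s_traces = filter_somatic(self.somatic_calls, cfg)
        second_hits = second_hits_for_cohort(
            carriers, self.patients, s_pass, self.segments, self.loci, cfg
        )

        somatic_by_patient: Dict[str, list] = {}
        for c in s_pass:
            somatic_by_patient.setdefault(c.patient_id, []).append(c)
        actionability = cohort_actionability(
            self.patients, somatic_by_patient, carriers, self.evidence
        )

        summary = summarize(self.patients, carriers, assignments, second_hits, cfg)
        age_table = age_contingency(assignments, self.patients, cfg)
        age_test = association_test(age_table, cfg)

        catalog = exposures = sigset = None
        if signatures:
            tumor_groups = {
                p.patient_id: assignments[p.patient_id].group
                for p in self.patients
                if p.tumor_tissue
            }
            catalog = build_catalog(s_pass, groupby=tumor_groups)
            if k is None:
                k = _select_k(catalog, seed, n_restarts)
            sigset, exposures = run_nmf(catalog, k=k, seed=seed, n_restarts=n_restarts)

        return RccCohortResults(
            model=self,
            pgvs=pgvs,
            carriers=carriers,
            assignments=assignments,
            germline_traces=g_traces,
            somatic_traces=s_traces,
            somatic_passing=s_pass,
            second_hits=second_hits,
            actionability=actionability,
            summary_=summary,
            age_table=age_table,
            age_test=age_test,
            catalog=catalog,
            signature_set=sigset,
            exposures=exposures,
        )


def _select_k(catalog: MutationCatalog, seed: int, n_restarts: int) -> int:
    """Smallest k in 1..5 whose error improvement over k-1 drops below 5%."""
    kmax = min(5, int((catalog.counts.sum(axis=0) > 0).sum()))
    errors = []
    X = catalog.counts.astype(float)
    for k in range(1, kmax + 1):
        sig, exp = run_nmf(catalog, k=k, seed=seed, n_restarts=n_restarts)
        err = float(np.linalg.norm(X - sig.signatures @ exp.to_numpy()))
        errors.append(err)
        if k > 1 and errors[k - 2] > 0 and (errors[k - 2] - err) / errors[k - 2] < 0.05:
            return k - 1
    return kmax


@dataclass
class RccCohortResults:
    """Fitted cohort results: estimates, tables and report."""

    model: RccCohortModel
    pgvs: list
    carriers: CarrierTable
    assignments: dict
    germline_traces: list
    somatic_traces: list
    somatic_passing: list
    second_hits: Dict[str, list]
    actionability: ActionabilitySummary
    summary_: CohortSummary
    age_table: np.ndarray
    age_test: AssociationResult
    catalog: Optional[MutationCatalog] = None
    signature_set: Optional[object] = None
    exposures: Optional[pd.DataFrame] = None

    def pgv_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": p.patient_id,
                "gene": p.gene,
                "chrom": p.call.chrom,
                "pos": p.call.pos,
                "ref": p.call.ref,
                "alt": p.call.alt,
                "consequence": p.call.consequence,
                "routes": ",".join(sorted(p.route)),
                "group": self.assignments[p.patient_id].group,
            }
            for p in self.pgvs
        ]
        return pd.DataFrame(rows)

    def second_hit_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": r.patient_id,
                "gene": r.gene,
                "hit_types": ",".join(sorted(r.hit_type)),
                "has_second_hit": r.has_second_hit,
            }
            for reports in self.second_hits.values()
            for r in reports
        ]
        return pd.DataFrame(rows)

    def actionability_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": c.patient_id,
                "basis": c.basis,
                "gene_or_marker": c.gene_or_marker,
                "level": c.level,
                "candidate_therapy": c.candidate_therapy,
            }
            for calls in self.actionability.calls.values()
            for c in calls
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable cohort report."""
        s = self.summary_
        a = self.actionability
        lines = [
            "Cohort germline/somatic interpretation",
            "=" * 54,
            f"Patients: {s.n_patients} ({s.n_tumor_patients} with tumor tissue)",
            f"P/LP carriers: {s.n_carriers} ({s.carrier_pct}%), "
            f"{s.n_pgvs} PGVs in {s.n_genes} genes",
            f"Multi-PGV carriers: {s.n_multi_pgv} ({s.multi_pgv_pct}%)",
            "Consequences: "
            + ", ".join(
                f"{c} {k}/{s.n_pgvs} ({s.consequence_pct[c]}%)"
                for c, k in s.consequence_counts.items()
            ),
            "Groups: "
            + ", ".join(
                f"{g} {s.group_sizes[g]} ({s.group_pct[g]}%)" for g in ("SRP", "OCP", "NCP")
            ),
            f"Age <= {self.model.config.age_cutoff} contingency "
            f"(rows: young/old; cols: carrier/non-carrier):",
            f"  {self.age_table.tolist()}",
            f"  {self.age_test.test_used}: p = {self.age_test.p_value:.4g} "
            f"({'significant' if self.age_test.significant else 'not significant'} "
            f"at alpha = {self.model.config.alpha})",
        ]
        if s.second_hit_rates:
            c, r = s.second_hit_counts, s.second_hit_rates
            lines.append(
                f"Second hits: SRP {c['SRP']} ({r['SRP']}%), OCP {c['OCP']} ({r['OCP']}%), "
                f"overall {c['overall']}/{s.n_carriers_with_tumor} ({r['overall']}%)"
            )
        from .stats import pct

        if a.denominator:
            ex = a.exclusive_counts
            lines.append(
                f"Actionable: {a.n_actionable}/{a.denominator} "
                f"({pct(a.n_actionable, a.denominator)}%) — somatic {ex['somatic']}, "
                f"germline {ex['germline']}, dMMR {ex['dmmr']}"
            )
            lines.append(
                f"Oncogenic without actionable alteration: {a.n_oncogenic_only}/"
                f"{a.denominator} ({pct(a.n_oncogenic_only, a.denominator)}%)"
            )
        if self.signature_set is not None:
            lines.append(
                "Signatures extracted: "
                + ", ".join(self.signature_set.names)
                + f" over columns {list(self.catalog.columns)}"
            )
        return "\n".join(lines)

    def match_signatures(self, reference, cfg=None) -> List[tuple]:
        """Assign each extracted signature to a reference set by cosine similarity."""
        if self.signature_set is None:
            raise ValidationError("fit(signatures=True) before matching")
        cfg = cfg or self.model.config
        return [
            (name,) + cosine_match(self.signature_set.signatures[:, j], reference, cfg)
            for j, name in enumerate(self.signature_set.names)
        ]
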