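"""Core domain records flowing through the variant-interpretation pipeline.

All genomic coordinates are 1-based inclusive (VCF convention). Categorical
annotation fields use ``None`` to mean "missing"; missing is never silently
mapped onto a value that would pass a filter.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

SEXES = {"male", "female"}
STAGES = {"I", "II", "III", "IV", "unknown"}
CONSEQUENCES = {
    "nonsense",
    "frameshift",
    "missense",
    "splice",
    "inframe_indel",
    "synonymous",
    "non_exonic",
    "other",
}
#: consequences presumed to abolish protein function (canonical splice = +/-2)
TRUNCATING_CONSEQUENCES = {"nonsense", "frameshift", "splice"}
SIFT_VALUES = {"deleterious", "tolerated"}
POLYPHEN2_VALUES = {"damaging", "benign"}
CLINVAR_VALUES = {"pathogenic", "likely_pathogenic", "vus", "benign", "likely_benign"}
HGMD_VALUES = {"DM", "DM?", "DP", "DFP", "FP"}
POPULATION_DBS = ("ExAC", "1000G", "ESP6500")


class RcclandError(Exception):
    """Base class for package errors."""


class ParseError(RcclandError):
    """Malformed input file."""


class ConfigError(RcclandError):
    """Invalid configuration (unknown dialect, malformed evidence table, ...)."""


class ValidationError(RcclandError):
    """Input violates a stated invariant (duplicate IDs, overlapping segments, ...)."""


@dataclass(frozen=True)
class PatientRecord:
    """Clinical/demographic attributes of one patient.

    ``smoker`` and ``mmr_deficient`` are tri-state: True / False / None (unknown).
    """

    patient_id: str
    sex: str
    age_years: int
    smoker: Optional[bool]
    stage: str
    tumor_tissue: bool
    mmr_deficient: Optional[bool]

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"{self.patient_id}: unknown sex {self.sex!r}")
        if not (0 <= self.age_years <= 130):
            raise ValidationError(
                f"{self.patient_id}: age {self.age_years} outside [0, 130]"
            )
        if self.stage not in STAGES:
            raise ValidationError(f"{self.patient_id}: unknown stage {self.stage!r}")


@dataclass(frozen=True)
class GermlineVariantCall:
    """One germline variant observation in one patient (sample-site-alt)."""

    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Optional[str]
    reads_total: int
    reads_alt: int
    allele_fraction: float
    inframe_aa_change: int = 0
    pop_freqs: dict = field(default_factory=dict)
    sift: Optional[str] = None
    polyphen2: Optional[str] = None
    cadd_phred: Optional[float] = None
    clinvar_class: Optional[str] = None
    hgmd_class: Optional[str] = None
    dbsnp_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.reads_alt > self.reads_total:
            raise ValidationError(
                f"{self.patient_id} {self.chrom}:{self.pos} "
                f"reads_alt {self.reads_alt} > reads_total {self.reads_total}"
            )
        if self.reads_total > 0 and abs(
            self.allele_fraction - self.reads_alt / self.reads_total
        ) > 0.05:
            raise ValidationError(
                f"{self.patient_id} {self.chrom}:{self.pos} allele_fraction "
                f"{self.allele_fraction:.3f} inconsistent with "
                f"{self.reads_alt}/{self.reads_total}"
            )

    @property
    def key(self) -> tuple:
        """Variant identity irrespective of carrier: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SomaticVariantCall:
    """One somatic (tumor vs matched normal) variant observation."""

    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Optional[str]
    tumor_reads_total: int
    tumor_reads_alt: int
    normal_reads_total: int
    normal_reads_alt: int
    max_mapping_quality: int
    vaf: float
    sift: Optional[str] = None
    polyphen2: Optional[str] = None
    in_dbsnp142: bool = False
    in_cosmic: bool = False
    trinucleotide_context: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tumor_reads_alt > self.tumor_reads_total:
            raise ValidationError(
                f"{self.patient_id} {self.chrom}:{self.pos} tumor alt > total reads"
            )
        if self.normal_reads_alt > self.normal_reads_total:
            raise ValidationError(
                f"{self.patient_id} {self.chrom}:{self.pos} normal alt > total reads"
            )

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in "ACGT"
            and self.alt in "ACGT"
            and self.ref != self.alt
        )


@dataclass(frozen=True)
class CopySegment:
    """Allele-specific copy-number interval from a FACETS-style caller.

    ``copy_ratio`` is tumor/normal; ``minor_allele_copies`` = 0 marks LOH
    (including copy-neutral LOH); ``None`` means the caller reported no
    allele-specific estimate.
    """

    patient_id: str
    chrom: str
    start: int
    end: int
    copy_ratio: float
    minor_allele_copies: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.patient_id} {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.copy_ratio < 0:
            raise ValidationError(f"{self.patient_id}: negative copy ratio")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and self.end >= start


@dataclass(frozen=True)
class GeneLocus:
    """Genomic interval of a panel gene (used to intersect genes with segments)."""

    gene: str
    chrom: str
    start: int
    end: int
    arm: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.gene}: locus start > end")
        if self.arm not in {"p", "q"}:
            raise ValidationError(f"{self.gene}: arm must be 'p' or 'q'")


@dataclass(frozen=True)
class PgvCall:
    """A germline variant promoted to pathogenic / likely pathogenic.

    ``route`` records which classification rules fired (truncating, in-frame
    size, concordant predictors, ClinVar, HGMD); at least one is required.
    """

    call: GermlineVariantCall
    route: frozenset
    final_class: str = "pathogenic_or_likely_pathogenic"

    def __post_init__(self) -> None:
        if not self.route:
            raise ValidationError("PgvCall requires a non-empty route")

    @property
    def patient_id(self) -> str:
        return self.call.patient_id

    @property
    def gene(self) -> str:
        return self.call.gene


@dataclass(frozen=True)
class GroupAssignment:
    """Patient stratum by germline status: SRP / OCP / NCP (+ DDR subclass)."""

    patient_id: str
    group: str
    ocp_subclass: str = "none"

    def __post_init__(self) -> None:
        if self.group not in {"SRP", "OCP", "NCP"}:
            raise ValidationError(f"unknown group {self.group!r}")
        if (self.ocp_subclass != "none") != (self.group == "OCP"):
            raise ValidationError("ocp_subclass set iff group is OCP")


@dataclass(frozen=True)
class SecondHitReport:
    """Somatic second-hit evidence for one (carrier, PGV gene) pair."""

    patient_id: str
    gene: str
    hit_type: frozenset
    evidence: tuple = ()

    @property
    def has_second_hit(self) -> bool:
        return bool(self.hit_type)


@dataclass(frozen=True)
class ActionabilityCall:
    """One actionable alteration for one patient (OncoKB-style level)."""

    patient_id: str
    basis: str  # somatic | germline | dmmr
    gene_or_marker: str
    level: str
    candidate_therapy: str

    def __post_init__(self) -> None:
        if self.basis not in {"somatic", "germline", "dmmr"}:
            raise ValidationError(f"unknown actionability basis {self.basis!r}")
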