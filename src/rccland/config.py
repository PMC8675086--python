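"""Numeric thresholds, gene panels, and the packaged gene-locus table.

Every tunable cut-off used anywhere in the pipeline lives in
:class:`FilterConfig` so a run is fully described by one YAML file.
"""
from __future__ import annotations

import importlib.resources as resources
from dataclasses import asdict, dataclass, field, fields

import yaml

from .types import ConfigError, GeneLocus, ValidationError


@dataclass
class FilterConfig:
    """All numeric thresholds of the pipeline, with study defaults.

    Germline filter: >=5 reads with >=3 alternate reads; heterozygous allele
    fraction in [0.3, 0.7]; population frequency <1% in every database where
    observed; cohort carrier frequency <5%. Somatic filter: >5 tumor reads,
    >=10x normal with <=1 alternate read, max mapping quality >=20, VAF >=1%.
    Copy-loss calls use tumor/normal ratio <0.9; signature matching uses
    cosine >0.7; association tests use alpha=0.05 two-tailed; the age
    dichotomy is <=46 years.
    """

    germline_min_reads_total: int = 5
    germline_min_reads_alt: int = 3
    germline_af_low: float = 0.3
    germline_af_high: float = 0.7
    popfreq_max: float = 0.01
    cohort_freq_max: float = 0.05
    somatic_min_tumor_reads: int = 6  # strict ">5 reads"
    somatic_min_normal_depth: int = 10
    somatic_max_normal_alt: int = 1
    somatic_min_mapq: int = 20
    somatic_min_vaf: float = 0.01
    cnv_loss_ratio: float = 0.9
    cosine_threshold: float = 0.7
    alpha: float = 0.05
    age_cutoff: int = 46
    cadd_deleterious_min: float = 20.0
    inframe_min_aa: int = 4  # "more than three amino acids"
    predictor_rule_requires_all: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.germline_af_low <= self.germline_af_high <= 1):
            raise ConfigError("germline AF bounds must satisfy 0 <= low <= high <= 1")
        for name in ("popfreq_max", "cohort_freq_max", "somatic_min_vaf", "alpha"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not (0 <= self.cosine_threshold <= 1):
            raise ConfigError("cosine_threshold outside [0, 1]")
        if self.cnv_loss_ratio < 0:
            raise ConfigError("cnv_loss_ratio must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown FilterConfig keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


@dataclass
class GenePanels:
    """Gene sets driving patient stratification.

    ``syndromic_rcc`` are genes of recognized hereditary RCC syndromes;
    ``ddr`` and ``other_cancer`` split the remaining cancer-predisposition
    genes; ``panel`` is the full assay membership used for validation.
    """

    syndromic_rcc: frozenset
    ddr: frozenset
    other_cancer: frozenset
    panel: frozenset = field(default=frozenset())

    def __post_init__(self) -> None:
        self.syndromic_rcc = frozenset(self.syndromic_rcc)
        self.ddr = frozenset(self.ddr)
        self.other_cancer = frozenset(self.other_cancer)
        overlap = self.syndromic_rcc & self.other_cancer
        if overlap:
            raise ConfigError(
                f"syndromic and other-cancer panels overlap: {sorted(overlap)}"
            )
        self.panel = frozenset(self.panel) | self.syndromic_rcc | self.ddr | self.other_cancer

    def to_yaml(self, path) -> None:
        d = {
            "syndromic_rcc": sorted(self.syndromic_rcc),
            "ddr": sorted(self.ddr),
            "other_cancer": sorted(self.other_cancer),
            "panel": sorted(self.panel),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GenePanels":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        try:
            return cls(
                syndromic_rcc=d["syndromic_rcc"],
                ddr=d["ddr"],
                other_cancer=d["other_cancer"],
                panel=d.get("panel", []),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed panel YAML {path}: {exc}") from exc


def _data_path(name: str):
    return resources.files("rccland.data").joinpath(name)


def default_panels() -> GenePanels:
    """Panels shipped with the package (syndromic-RCC, DDR, other-cancer sets)."""
    with resources.as_file(_data_path("panels.yaml")) as p:
        return GenePanels.from_yaml(p)


def load_gene_loci(path=None) -> dict:
    """Read a gene-locus table (gene, chrom, arm, start, end; 1-based inclusive).

    Returns a mapping gene -> :class:`GeneLocus`. Defaults to the packaged
    synthetic locus table covering every panel gene the pipeline references.
    """
    if path is None:
        with resources.as_file(_data_path("gene_loci.tsv")) as p:
            return load_gene_loci(p)
    loci: dict = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene", "chrom", "arm", "start", "end"]
        if header != expected:
            raise ConfigError(f"gene locus table must have columns {expected}")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            gene, chrom, arm, start, end = line.rstrip("\n").split("\t")
            if gene in loci:
                raise ValidationError(f"duplicate locus for gene {gene} (line {ln})")
            loci[gene] = GeneLocus(
                gene=gene, chrom=chrom, arm=arm, start=int(start), end=int(end)
            )
    return loci
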