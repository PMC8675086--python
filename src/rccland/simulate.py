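"""Synthetic cohort generation.

Two generators emit complete input file sets (germline VCF, somatic VCF,
clinical TSV, SEG TSV) in the pipeline's own formats:

* :func:`generate_reference_cohort` — a fully deterministic 322-patient cohort
  reconstructing the published headline composition: 32 P/LP carriers with 37
  PGVs in 25 genes (5 double-carriers), the 13/13/8/3
  frameshift/nonsense/missense/splice mix, 71 patients aged <=46, 274 with
  tumor tissue (28 carriers), the 8/10 SRP and 3/18 OCP second-hit patients,
  and the 30/9/8 somatic/germline/dMMR actionability decomposition.
  Attributes the published tables do not pin (which carriers smoke, exact
  stages) are assigned by patient index and documented in the manifest.

* :func:`generate_random_cohort` — a parameterized stochastic cohort with a
  ground-truth table of every planted carrier, PGV, second hit and signature
  exposure, for recovery and calibration tests.
"""
from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .config import load_gene_loci
from .io import (
    write_clinical_tsv,
    write_germline_vcf,
    write_seg,
    write_somatic_vcf,
)
from .signatures import (
    CONTEXT_LABELS,
    MutationCatalog,
    SignatureSet,
    revcomp,
)
from .types import (
    ConfigError,
    CopySegment,
    GermlineVariantCall,
    PatientRecord,
    SomaticVariantCall,
)

# ---------------------------------------------------------------------------
# deterministic fixture
# ---------------------------------------------------------------------------

#: (patient index, [(gene, consequence), ...]) — 32 carriers, 37 PGVs, 25 genes
_CARRIER_SPEC = [
    (1, [("VHL", "nonsense"), ("PBRM1", "frameshift")]),
    (2, [("VHL", "frameshift"), ("BAP1", "nonsense")]),
    (3, [("VHL", "missense"), ("TP53", "missense")]),
    (4, [("VHL", "nonsense")]),
    (5, [("VHL", "frameshift")]),
    (6, [("VHL", "splice")]),
    (7, [("VHL", "nonsense")]),
    (8, [("FH", "frameshift")]),
    (9, [("FH", "nonsense")]),
    (10, [("TSC2", "frameshift"), ("TSC2", "nonsense")]),
    (11, [("FLCN", "frameshift")]),
    (12, [("TSC1", "nonsense")]),
    (13, [("ATM", "frameshift")]),
    (14, [("ATM", "nonsense")]),
    (15, [("BLM", "frameshift"), ("MRE11", "missense")]),
    (16, [("BLM", "nonsense")]),
    (17, [("BRCA1", "frameshift")]),
    (18, [("BRCA1", "nonsense")]),
    (19, [("NBN", "frameshift")]),
    (20, [("NBN", "nonsense")]),
    (21, [("ATR", "missense")]),
    (22, [("BRCA2", "frameshift")]),
    (23, [("CHEK2", "nonsense")]),
    (24, [("FANCA", "frameshift")]),
    (25, [("RECQL4", "missense")]),
    (26, [("SLX4", "frameshift")]),
    (27, [("DICER1", "nonsense")]),
    (28, [("NF2", "splice")]),
    (29, [("NOTCH3", "missense")]),
    (30, [("PPM1D", "missense")]),
    (31, [("PTCH1", "splice")]),
    (32, [("TSHR", "missense")]),
]

#: carriers aged <= 46 (7 syndromic-RCC, 5 other-cancer carriers)
_YOUNG_CARRIERS = {1, 2, 5, 6, 9, 10, 12, 14, 17, 21, 27, 30}
#: carriers without tumor tissue (1 VHL, 1 FH, 1 ATM, 1 NOTCH3)
_CARRIERS_NO_TUMOR = {4, 8, 13, 29}
#: non-carrier indices without tumor tissue
_NONCARRIERS_NO_TUMOR = set(range(33, 77))
#: non-carrier indices aged <= 46 (59 patients)
_YOUNG_NONCARRIERS = set(range(77, 136))
#: smokers (129 patients, Table-level tally; arbitrary identities)
_SMOKERS = set(range(50, 179))
#: dMMR patients (8 non-carriers with tumor data, no actionable somatic variant)
_DMMR = set(range(140, 148))
#: carriers whose tumor carries an actionable somatic variant (VHL carriers)
_CARRIERS_WITH_ACTIONABLE_SOMATIC = {1, 2, 3}
#: non-carriers with an actionable somatic variant (27 patients)
_NONCARRIERS_WITH_ACTIONABLE_SOMATIC = set(range(77, 104))
_ACTIONABLE_SOMATIC_GENES = ["PIK3CA", "KRAS", "BRAF", "MET", "MTOR"]
_BACKGROUND_GENES = ["SETD2", "GNAQ", "INPPL1", "ARID1A", "KMT2D", "KMT2B"]
_BACKGROUND_SNVS_PER_TUMOR = 6

#: planted copy-number / LOH second hits: patient -> (chrom, start, end, ratio, minor)
_SEGMENT_HITS = {
    1: ("chr3", 1, 90_000_000, 0.55, 0),
    2: ("chr3", 1, 90_000_000, 0.55, 0),
    3: ("chr3", 1, 90_000_000, 0.55, 0),
    5: ("chr3", 1, 90_000_000, 0.55, 0),
    6: ("chr3", 1, 90_000_000, 0.55, 0),
    7: ("chr3", 1, 90_000_000, 0.55, 0),
    11: ("chr17", 1, 22_000_000, 0.60, 0),
    22: ("chr13", 20_000_000, 115_000_000, 0.60, 0),
    24: ("chr16", 60_000_000, 90_200_000, 1.00, 0),  # copy-neutral LOH at FANCA
    28: ("chr22", 15_000_000, 51_000_000, 0.62, 0),
}
#: carrier with a somatic truncating second hit in the germline-hit gene
_SOMATIC_HIT_PATIENT = 12  # TSC1

N_FIXTURE_PATIENTS = 322


def _pid(i: int) -> str:
    return f"RCC{i:03d}"


def _fixture_patients() -> list:
    stages = ["I"] * 33 + ["II"] * 74 + ["III"] * 72 + ["IV"] * 61 + ["unknown"] * 82
    young = _YOUNG_CARRIERS | _YOUNG_NONCARRIERS
    no_tumor = _CARRIERS_NO_TUMOR | _NONCARRIERS_NO_TUMOR
    females = [i for i in range(1, N_FIXTURE_PATIENTS + 1) if i % 3 == 0][:105]
    female_set = set(females)
    patients = []
    for i in range(1, N_FIXTURE_PATIENTS + 1):
        tumor = i not in no_tumor
        age = 28 + (i % 19) if i in young else 47 + (i % 40)
        patients.append(
            PatientRecord(
                patient_id=_pid(i),
                sex="female" if i in female_set else "male",
                age_years=age,
                smoker=i in _SMOKERS,
                stage=stages[i - 1],
                tumor_tissue=tumor,
                mmr_deficient=(i in _DMMR) if tumor else None,
            )
        )
    return patients


def _germline_variant(vi, i, gene, csq, ordinal, loci) -> GermlineVariantCall:
    locus = loci[gene]
    pos = locus.start + 1000 * ordinal
    if csq == "frameshift":
        ref, alt = "CA", "C"
    elif csq == "splice":
        ref, alt = "G", "A"
    else:
        ref, alt = "C", "T"
    total = 100 + (vi * 7) % 60
    af = 0.45 + (vi % 5) * 0.01
    alt_reads = round(total * af)
    kwargs = {}
    if csq == "missense":
        kwargs.update(sift="deleterious", polyphen2="damaging", cadd_phred=25.0 + vi % 6)
    if vi % 3 == 0:
        kwargs["clinvar_class"] = "pathogenic"
    if vi % 4 == 0:
        kwargs["hgmd_class"] = "DM"
    if vi < 17:
        kwargs["dbsnp_id"] = f"rs9{100000 + vi}"
    return GermlineVariantCall(
        patient_id=_pid(i),
        gene=gene,
        chrom=locus.chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        consequence=csq,
        reads_total=total,
        reads_alt=alt_reads,
        allele_fraction=alt_reads / total,
        pop_freqs={"ExAC": 0.0001} if vi % 2 == 0 else {},
        **kwargs,
    )


def _fixture_germline(loci) -> list:
    calls = []
    gene_ordinal: Dict[str, int] = {}
    vi = 0
    for i, variants in _CARRIER_SPEC:
        for gene, csq in variants:
            gene_ordinal[gene] = gene_ordinal.get(gene, 0) + 1
            calls.append(_germline_variant(vi, i, gene, csq, gene_ordinal[gene], loci))
            vi += 1

    # decoys exercising each filter rule; none survives to classification
    brca2 = loci["BRCA2"]
    for i in range(100, 130):  # common variant: fails the population-frequency rule
        calls.append(
            GermlineVariantCall(
                patient_id=_pid(i), gene="BRCA2", chrom=brca2.chrom,
                pos=brca2.start + 50_000, ref="A", alt="G", consequence="missense",
                reads_total=100, reads_alt=48, allele_fraction=0.48,
                pop_freqs={"ExAC": 0.02, "1000G": 0.015},
                sift="tolerated", polyphen2="benign", dbsnp_id="rs9200001",
            )
        )
    atm = loci["ATM"]
    for i in range(150, 170):  # 20/322 = 6.2% of cohort: fails the cohort-frequency rule
        calls.append(
            GermlineVariantCall(
                patient_id=_pid(i), gene="ATM", chrom=atm.chrom,
                pos=atm.start + 60_000, ref="T", alt="C", consequence="missense",
                reads_total=90, reads_alt=44, allele_fraction=44 / 90,
                sift="tolerated", polyphen2="benign",
            )
        )
    tp53 = loci["TP53"]
    calls.append(  # synonymous: fails functional relevance
        GermlineVariantCall(
            patient_id=_pid(33), gene="TP53", chrom=tp53.chrom, pos=tp53.start + 9000,
            ref="G", alt="A", consequence="synonymous",
            reads_total=80, reads_alt=38, allele_fraction=38 / 80,
        )
    )
    calls.append(  # shallow site: fails the read-support rule
        GermlineVariantCall(
            patient_id=_pid(34), gene="ATM", chrom=atm.chrom, pos=atm.start + 70_000,
            ref="C", alt="G", consequence="missense",
            reads_total=4, reads_alt=2, allele_fraction=0.5,
        )
    )
    blm = loci["BLM"]
    calls.append(  # allele fraction 0.9: fails the heterozygosity band
        GermlineVariantCall(
            patient_id=_pid(35), gene="BLM", chrom=blm.chrom, pos=blm.start + 42_000,
            ref="A", alt="T", consequence="missense",
            reads_total=100, reads_alt=90, allele_fraction=0.9,
        )
    )
    return calls


def _context_for(idx: int) -> tuple:
    """Deterministic (ref, alt, reference-strand context) cycling the 96 classes.

    Odd indices present the call on the purine strand to exercise
    normalization.
    """
    label = CONTEXT_LABELS[idx % 96]
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    context = five + ref + three
    if idx % 2 == 1:
        ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
    return ref, alt, context


def _fixture_somatic(patients, loci) -> list:
    calls = []
    tumor_idx = [int(p.patient_id[3:]) for p in patients if p.tumor_tissue]

    # TSC1 carrier: somatic truncating second hit in the germline-hit gene
    tsc1 = loci["TSC1"]
    calls.append(
        SomaticVariantCall(
            patient_id=_pid(_SOMATIC_HIT_PATIENT), gene="TSC1", chrom=tsc1.chrom,
            pos=tsc1.start + 5000, ref="GA", alt="G", consequence="frameshift",
            tumor_reads_total=200, tumor_reads_alt=60,
            normal_reads_total=80, normal_reads_alt=0,
            max_mapping_quality=60, vaf=0.3, in_cosmic=True,
        )
    )

    # actionable somatic variants (3 VHL carriers + 27 non-carriers)
    actionable = sorted(_CARRIERS_WITH_ACTIONABLE_SOMATIC) + sorted(
        _NONCARRIERS_WITH_ACTIONABLE_SOMATIC
    )
    for j, i in enumerate(actionable):
        gene = _ACTIONABLE_SOMATIC_GENES[j % len(_ACTIONABLE_SOMATIC_GENES)]
        locus = loci[gene]
        calls.append(
            SomaticVariantCall(
                patient_id=_pid(i), gene=gene, chrom=locus.chrom,
                pos=locus.start + 100 + j, ref="G", alt="T", consequence="missense",
                tumor_reads_total=400, tumor_reads_alt=120,
                normal_reads_total=120, normal_reads_alt=0,
                max_mapping_quality=60, vaf=0.3,
                sift="deleterious", polyphen2="damaging",
                in_dbsnp142=True, in_cosmic=True,
                trinucleotide_context="AGT",
            )
        )

    # background SNVs for every tumor (drive the 96-context catalog)
    k = 0
    for i in tumor_idx:
        for j in range(_BACKGROUND_SNVS_PER_TUMOR):
            gene = _BACKGROUND_GENES[(i + j) % len(_BACKGROUND_GENES)]
            locus = loci[gene]
            ref, alt, context = _context_for(i * _BACKGROUND_SNVS_PER_TUMOR + j)
            calls.append(
                SomaticVariantCall(
                    patient_id=_pid(i), gene=gene, chrom=locus.chrom,
                    pos=locus.start + 3000 + k, ref=ref, alt=alt,
                    consequence="synonymous" if j % 3 == 2 else "missense",
                    tumor_reads_total=300 + (k % 100), tumor_reads_alt=60 + (k % 40),
                    normal_reads_total=100, normal_reads_alt=0,
                    max_mapping_quality=60,
                    vaf=(60 + (k % 40)) / (300 + (k % 100)),
                    trinucleotide_context=context,
                )
            )
            k += 1

    # decoys exercising each somatic filter rule (patient RCC105)
    gnaq = loci["GNAQ"]
    base = dict(
        patient_id=_pid(105), gene="GNAQ", chrom=gnaq.chrom, ref="C", alt="A",
        consequence="missense", normal_reads_total=60, normal_reads_alt=0,
        max_mapping_quality=60,
    )
    calls.append(SomaticVariantCall(**{**base, "pos": gnaq.start + 100_001,
                 "tumor_reads_total": 5, "tumor_reads_alt": 2, "vaf": 0.4}))
    calls.append(SomaticVariantCall(**{**base, "pos": gnaq.start + 100_002,
                 "tumor_reads_total": 200, "tumor_reads_alt": 40, "vaf": 0.2,
                 "normal_reads_alt": 2}))
    calls.append(SomaticVariantCall(**{**base, "pos": gnaq.start + 100_003,
                 "tumor_reads_total": 200, "tumor_reads_alt": 40, "vaf": 0.2,
                 "max_mapping_quality": 15}))
    calls.append(SomaticVariantCall(**{**base, "pos": gnaq.start + 100_004,
                 "tumor_reads_total": 1000, "tumor_reads_alt": 8, "vaf": 0.008}))
    calls.append(SomaticVariantCall(**{**base, "pos": gnaq.start + 100_005,
                 "tumor_reads_total": 200, "tumor_reads_alt": 40, "vaf": 0.2,
                 "in_dbsnp142": True}))
    return calls


def _fixture_segments(loci) -> list:
    segments = []
    for i, (chrom, start, end, ratio, minor) in sorted(_SEGMENT_HITS.items()):
        segments.append(
            CopySegment(
                patient_id=_pid(i), chrom=chrom, start=start, end=end,
                copy_ratio=ratio, minor_allele_copies=minor,
            )
        )
    # copy-neutral segments over the PGV loci of the remaining carriers with tumor
    neutral = {
        9: "FH", 10: "TSC2", 12: "TSC1", 14: "ATM", 15: "BLM", 16: "BLM",
        17: "BRCA1", 18: "BRCA1", 19: "NBN", 20: "NBN", 21: "ATR", 23: "CHEK2",
        25: "RECQL4", 26: "SLX4", 27: "DICER1", 30: "PPM1D", 31: "PTCH1", 32: "TSHR",
    }
    for i, gene in sorted(neutral.items()):
        locus = loci[gene]
        segments.append(
            CopySegment(
                patient_id=_pid(i), chrom=locus.chrom,
                start=max(1, locus.start - 1_000_000), end=locus.end + 1_000_000,
                copy_ratio=1.0, minor_allele_copies=1,
            )
        )
    return segments


def generate_reference_cohort(out_dir) -> Dict[str, Path]:
    """Write the deterministic fixture cohort; byte-identical across runs.

    Returns paths for germline_vcf, somatic_vcf, clinical_tsv, seg_tsv,
    evidence_tsv and manifest_tsv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    loci = load_gene_loci()
    patients = _fixture_patients()
    germline = _fixture_germline(loci)
    somatic = _fixture_somatic(patients, loci)
    segments = _fixture_segments(loci)

    paths = {
        "clinical_tsv": out / "clinical.tsv",
        "germline_vcf": out / "germline.vcf",
        "somatic_vcf": out / "somatic.vcf",
        "seg_tsv": out / "segments.tsv",
        "evidence_tsv": out / "evidence.tsv",
        "manifest_tsv": out / "manifest.tsv",
    }
    write_clinical_tsv(patients, paths["clinical_tsv"])
    write_germline_vcf(germline, paths["germline_vcf"],
                       sample_ids=[p.patient_id for p in patients])
    tumor_ids = [p.patient_id for p in patients if p.tumor_tissue]
    write_somatic_vcf(somatic, paths["somatic_vcf"], sample_ids=tumor_ids)
    write_seg(segments, paths["seg_tsv"])

    import importlib.resources as resources

    with resources.as_file(
        resources.files("rccland.data").joinpath("evidence.tsv")
    ) as src:
        shutil.copyfile(src, paths["evidence_tsv"])

    manifest = pd.DataFrame(
        [
            {
                "patient_id": _pid(i), "gene": g, "consequence": c,
                "young": i in _YOUNG_CARRIERS, "tumor_tissue": i not in _CARRIERS_NO_TUMOR,
                "planted_second_hit": (
                    "segment" if i in _SEGMENT_HITS
                    else "somatic" if i == _SOMATIC_HIT_PATIENT else ""
                ),
            }
            for i, variants in _CARRIER_SPEC
            for g, c in variants
        ]
    )
    manifest.to_csv(paths["manifest_tsv"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# stochastic generator
# ---------------------------------------------------------------------------

#: per-gene PGV weights matching the fixture's variant spectrum
DEFAULT_GENE_WEIGHTS = {
    "VHL": 7, "FH": 2, "TSC2": 2, "ATM": 2, "BLM": 2, "BRCA1": 2, "NBN": 2,
    "PBRM1": 1, "BAP1": 1, "TP53": 1, "FLCN": 1, "TSC1": 1, "MRE11": 1,
    "ATR": 1, "BRCA2": 1, "CHEK2": 1, "FANCA": 1, "RECQL4": 1, "SLX4": 1,
    "DICER1": 1, "NF2": 1, "NOTCH3": 1, "PPM1D": 1, "PTCH1": 1, "TSHR": 1,
}

_CONSEQUENCE_MIX = (("frameshift", 13), ("nonsense", 13), ("missense", 8), ("splice", 3))


@dataclass
class SimParams:
    """Parameters of the stochastic cohort generator (seed is mandatory).

    Defaults mirror the study conditions: 322 patients, ~10% carrier
    prevalence, heterozygous germline VAF centered at 0.5, 274/322 tumor
    availability, ~10 somatic panel mutations per tumor, and a 39% planted
    second-hit probability per carrier with tumor data.
    """

    seed: int
    n_patients: int = 322
    carrier_prevalence: float = 0.099
    multi_pgv_prob: float = 5 / 32
    gene_weights: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENE_WEIGHTS))
    vaf_mean: float = 0.5
    vaf_sd: float = 0.05
    germline_depth_mean: float = 120.0
    contamination_rate: float = 0.05
    somatic_rate: float = 10.0
    tumor_fraction: float = 274 / 322
    mmr_rate: float = 8 / 274
    second_hit_prob: float = 11 / 28
    annotation_noise: float = 0.0
    signature_mixture: Optional[tuple] = None  # (SignatureSet, exposure weights (k,))

    def __post_init__(self) -> None:
        for name in (
            "carrier_prevalence", "multi_pgv_prob", "contamination_rate",
            "tumor_fraction", "mmr_rate", "second_hit_prob", "annotation_noise",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")


def sample_catalog(
    signatures: SignatureSet, exposures: np.ndarray, n_mutations, rng
) -> MutationCatalog:
    """Draw a 96-context catalog from a planted signature mixture.

    ``exposures`` is (k, m): mutation-count weights per signature per column;
    ``n_mutations`` is the total per column (int or length-m sequence).
    """
    exposures = np.atleast_2d(np.asarray(exposures, dtype=float))
    k, m = exposures.shape
    if k != len(signatures.names):
        raise ConfigError("exposures rows must match number of signatures")
    n_mutations = np.broadcast_to(np.asarray(n_mutations, dtype=int), (m,))
    counts = np.zeros((96, m), dtype=int)
    for j in range(m):
        w = exposures[:, j]
        if w.sum() <= 0:
            continue
        p = signatures.signatures @ (w / w.sum())
        counts[:, j] = rng.multinomial(int(n_mutations[j]), p / p.sum())
    return MutationCatalog(counts=counts, columns=tuple(f"S{j+1}" for j in range(m)))


def _sample_context(rng, probs96=None) -> tuple:
    idx = int(rng.choice(96, p=probs96)) if probs96 is not None else int(rng.integers(96))
    label = CONTEXT_LABELS[idx]
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    context = five + ref + three
    if rng.random() < 0.5:  # present on the purine strand
        ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
    return ref, alt, context


def generate_random_cohort(params: SimParams, out_dir) -> dict:
    """Generate a stochastic cohort; returns file paths plus ground truth.

    The returned dict carries ``paths`` (clinical/germline/somatic/segments
    TSVs and VCFs, all parseable by the package readers) and ``truth``
    (DataFrames: planted carriers/PGVs, injected common variants, planted
    second hits).
    """
    rng = np.random.default_rng(params.seed)
    loci = load_gene_loci()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n = params.n_patients
    pids = [f"S{i:04d}" for i in range(1, n + 1)]
    tumor = rng.random(n) < params.tumor_fraction
    ages = np.clip(np.rint(rng.normal(56, 14, size=n)), 16, 87).astype(int)
    sexes = np.where(rng.random(n) < 0.674, "male", "female")
    smokers = rng.random(n) < 0.4
    stage_pool = ["I", "II", "III", "IV", "unknown"]
    stage_p = np.array([33, 74, 72, 61, 82], dtype=float) / 322.0
    stages = rng.choice(stage_pool, size=n, p=stage_p)
    mmr = (rng.random(n) < params.mmr_rate) & tumor

    patients = [
        PatientRecord(
            patient_id=pids[i], sex=str(sexes[i]), age_years=int(ages[i]),
            smoker=bool(smokers[i]), stage=str(stages[i]),
            tumor_tissue=bool(tumor[i]),
            mmr_deficient=bool(mmr[i]) if tumor[i] else None,
        )
        for i in range(n)
    ]

    genes = sorted(params.gene_weights)
    gene_p = np.array([params.gene_weights[g] for g in genes], dtype=float)
    gene_p /= gene_p.sum()
    csq_names = [c for c, _ in _CONSEQUENCE_MIX]
    csq_p = np.array([w for _, w in _CONSEQUENCE_MIX], dtype=float)
    csq_p /= csq_p.sum()

    used_positions: Dict[str, set] = {}

    def fresh_pos(gene) -> int:
        locus = loci[gene]
        used = used_positions.setdefault(gene, set())
        while True:
            pos = int(rng.integers(locus.start, locus.end + 1))
            if pos not in used:
                used.add(pos)
                return pos

    germline, truth_pgvs = [], []
    carrier_flags = rng.random(n) < params.carrier_prevalence
    for i in range(n):
        if not carrier_flags[i]:
            continue
        n_pgv = 2 if rng.random() < params.multi_pgv_prob else 1
        chosen = rng.choice(len(genes), size=n_pgv, replace=False, p=gene_p)
        for gi in chosen:
            gene = genes[int(gi)]
            csq = str(rng.choice(csq_names, p=csq_p))
            locus = loci[gene]
            pos = fresh_pos(gene)
            if csq == "frameshift":
                ref, alt = "CA", "C"
            else:
                ref, alt = "C", "T"
            depth = max(30, int(rng.poisson(params.germline_depth_mean)))
            af = float(np.clip(rng.normal(params.vaf_mean, params.vaf_sd), 0.31, 0.69))
            alt_reads = int(np.clip(round(af * depth), 3, depth))
            kwargs = {}
            if csq == "missense":
                noisy = rng.random() < params.annotation_noise
                kwargs.update(
                    sift="tolerated" if noisy else "deleterious",
                    polyphen2="damaging",
                    cadd_phred=float(rng.uniform(22, 35)),
                )
            germline.append(
                GermlineVariantCall(
                    patient_id=pids[i], gene=gene, chrom=locus.chrom, pos=pos,
                    ref=ref, alt=alt, consequence=csq,
                    reads_total=depth, reads_alt=alt_reads,
                    allele_fraction=alt_reads / depth,
                    **kwargs,
                )
            )
            truth_pgvs.append(
                {"patient_id": pids[i], "gene": gene, "chrom": locus.chrom,
                 "pos": pos, "ref": ref, "alt": alt, "consequence": csq,
                 "annotation_noise": csq == "missense" and kwargs.get("sift") == "tolerated"}
            )

    # common-variant contamination: caught by the population/cohort frequency rules
    truth_common = []
    n_common = round(params.contamination_rate * 20)
    for ci in range(n_common):
        gene = genes[int(rng.integers(len(genes)))]
        locus = loci[gene]
        pos = fresh_pos(gene)
        popfreq = float(rng.uniform(0.01, 0.1))
        carry_p = min(0.5, 2 * popfreq)
        carrier_idx = np.flatnonzero(rng.random(n) < carry_p)
        pop = {"ExAC": popfreq} if ci % 2 == 0 else {}  # odd ones rely on the cohort rule
        if not pop:
            carry_p = 0.08
            carrier_idx = np.flatnonzero(rng.random(n) < carry_p)
        for i in carrier_idx:
            depth = max(30, int(rng.poisson(params.germline_depth_mean)))
            alt_reads = int(np.clip(round(0.5 * depth), 3, depth))
            germline.append(
                GermlineVariantCall(
                    patient_id=pids[int(i)], gene=gene, chrom=locus.chrom, pos=pos,
                    ref="A", alt="G", consequence="missense",
                    reads_total=depth, reads_alt=alt_reads,
                    allele_fraction=alt_reads / depth,
                    pop_freqs=pop, sift="tolerated", polyphen2="benign",
                )
            )
        truth_common.append(
            {"gene": gene, "chrom": locus.chrom, "pos": pos,
             "n_carriers": len(carrier_idx), "pop_freq": popfreq if pop else None}
        )

    # somatic mutations
    probs96 = None
    if params.signature_mixture is not None:
        sigset, weights = params.signature_mixture
        w = np.asarray(weights, dtype=float)
        probs96 = sigset.signatures @ (w / w.sum())
        probs96 = probs96 / probs96.sum()

    pgv_genes_of: Dict[str, set] = {}
    for row in truth_pgvs:
        pgv_genes_of.setdefault(row["patient_id"], set()).add(row["gene"])

    somatic, segments, truth_hits = [], [], []
    for i in range(n):
        if not tumor[i]:
            continue
        pid = pids[i]
        forbidden = pgv_genes_of.get(pid, set())
        background = [g for g in _BACKGROUND_GENES if g not in forbidden]
        for _ in range(int(rng.poisson(params.somatic_rate))):
            gene = background[int(rng.integers(len(background)))]
            locus = loci[gene]
            pos = fresh_pos(gene)
            ref, alt, context = _sample_context(rng, probs96)
            depth = max(50, int(rng.poisson(500)))
            vaf = float(rng.uniform(0.05, 0.6))
            alt_reads = max(6, int(round(vaf * depth)))
            somatic.append(
                SomaticVariantCall(
                    patient_id=pid, gene=gene, chrom=locus.chrom, pos=pos,
                    ref=ref, alt=alt,
                    consequence="synonymous" if rng.random() < 0.4 else "missense",
                    tumor_reads_total=depth, tumor_reads_alt=alt_reads,
                    normal_reads_total=100, normal_reads_alt=0,
                    max_mapping_quality=60, vaf=alt_reads / depth,
                    trinucleotide_context=context,
                )
            )
        # planted second hit on the first PGV gene
        if forbidden and rng.random() < params.second_hit_prob:
            gene = sorted(forbidden)[0]
            locus = loci[gene]
            u = rng.random()
            if u < 0.5:
                hit = "copy_loss"
                segments.append(CopySegment(
                    patient_id=pid, chrom=locus.chrom,
                    start=max(1, locus.start - 1_000_000), end=locus.end + 1_000_000,
                    copy_ratio=float(rng.uniform(0.4, 0.8)), minor_allele_copies=0,
                ))
            elif u < 0.75:
                hit = "loh"
                segments.append(CopySegment(
                    patient_id=pid, chrom=locus.chrom,
                    start=max(1, locus.start - 1_000_000), end=locus.end + 1_000_000,
                    copy_ratio=1.0, minor_allele_copies=0,
                ))
            else:
                hit = "somatic_truncating"
                pos = fresh_pos(gene)
                somatic.append(SomaticVariantCall(
                    patient_id=pid, gene=gene, chrom=locus.chrom, pos=pos,
                    ref="C", alt="A", consequence="nonsense",
                    tumor_reads_total=300, tumor_reads_alt=90,
                    normal_reads_total=100, normal_reads_alt=0,
                    max_mapping_quality=60, vaf=0.3,
                ))
            truth_hits.append({"patient_id": pid, "gene": gene, "hit_type": hit})

    paths = {
        "clinical_tsv": out / "clinical.tsv",
        "germline_vcf": out / "germline.vcf",
        "somatic_vcf": out / "somatic.vcf",
        "seg_tsv": out / "segments.tsv",
    }
    write_clinical_tsv(patients, paths["clinical_tsv"])
    write_germline_vcf(germline, paths["germline_vcf"], sample_ids=pids)
    tumor_ids = [pids[i] for i in range(n) if tumor[i]]
    write_somatic_vcf(somatic, paths["somatic_vcf"], sample_ids=tumor_ids)
    write_seg(segments, paths["seg_tsv"])

    truth = {
        "carriers": pd.DataFrame(
            {"patient_id": pids, "is_carrier": carrier_flags, "tumor_tissue": tumor}
        ),
        "pgvs": pd.DataFrame(truth_pgvs),
        "common_variants": pd.DataFrame(truth_common),
        "second_hits": pd.DataFrame(truth_hits),
    }
    for name, df in truth.items():
        df.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)
    return {"paths": paths, "truth": truth}
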