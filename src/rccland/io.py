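"""Readers and writers for the pipeline's file formats.

Variants travel as VCF 4.2 with precomputed annotations in INFO keys (the
assay delivers SIFT/PolyPhen-2/CADD/ClinVar/HGMD calls with the variants, so
no annotation databases are queried at run time). Clinical attributes and
copy-number segments are tab-separated tables. All coordinates are 1-based
inclusive in memory; a SEG dialect flag converts 0-based half-open input.

Reading uses cyvcf2; the writers emit deterministic plain text so that a
generated cohort is byte-identical across runs.
"""
from __future__ import annotations

import csv
from collections import defaultdict
from typing import Iterable, Optional

from cyvcf2 import VCF

from .types import (
    CopySegment,
    GermlineVariantCall,
    ParseError,
    ConfigError,
    PatientRecord,
    SomaticVariantCall,
    ValidationError,
)

_CHROMS = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
_CHROM_ORDER = {c: i for i, c in enumerate(_CHROMS)}

#: canonical-field -> INFO-key mappings for germline annotation dialects
GERMLINE_DIALECTS = {
    "default": {
        "gene": "GENE",
        "consequence": "CSQ",
        "inframe_aa_change": "AAC",
        "ExAC": "AF_EXAC",
        "1000G": "AF_1KG",
        "ESP6500": "AF_ESP",
        "sift": "SIFT",
        "polyphen2": "PP2",
        "cadd_phred": "CADD",
        "clinvar_class": "CLNSIG",
        "hgmd_class": "HGMD",
        "dbsnp_id": "DBSNP",
    }
}

SOMATIC_DIALECTS = {
    "default": {
        "gene": "GENE",
        "consequence": "CSQ",
        "max_mapping_quality": "MQM",
        "sift": "SIFT",
        "polyphen2": "PP2",
        "in_dbsnp142": "DB142",
        "in_cosmic": "COSMIC",
        "trinucleotide_context": "TNC",
    }
}


def _chrom_sort_key(chrom: str):
    return (_CHROM_ORDER.get(chrom, len(_CHROM_ORDER)), chrom)


def _fmt_float(x: float) -> str:
    return f"{x:.6g}"


def _read_float(v) -> float:
    # htslib hands INFO floats back as float32; snap to the writer's 6-digit text
    return float(f"{float(v):.6g}")


def _int_or_missing(arr, si, j=0) -> Optional[int]:
    if arr is None:
        return None
    v = int(arr[si][j])
    return None if v < 0 else v


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = [
    "patient_id",
    "sex",
    "age_years",
    "smoker",
    "stage",
    "tumor_tissue",
    "mmr_deficient",
]


def _tristate(cell: str, where: str) -> Optional[bool]:
    cell = cell.strip().lower()
    if cell in {"", "unknown", "na", "nan"}:
        return None
    if cell in {"yes", "true", "1"}:
        return True
    if cell in {"no", "false", "0"}:
        return False
    raise ParseError(f"{where}: cannot interpret {cell!r} as yes/no/unknown")


def read_clinical_tsv(path) -> list:
    """Read the per-patient clinical table; blank categoricals become unknown."""
    patients = []
    seen = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or [
            c for c in CLINICAL_COLUMNS if c not in reader.fieldnames
        ]:
            raise ParseError(
                f"{path}: clinical table requires columns {CLINICAL_COLUMNS}"
            )
        for ln, row in enumerate(reader, start=2):
            pid = row["patient_id"].strip()
            if not pid:
                raise ParseError(f"{path} line {ln}: empty patient_id")
            if pid in seen:
                raise ValidationError(f"{path} line {ln}: duplicate patient_id {pid}")
            seen.add(pid)
            try:
                age = int(row["age_years"])
            except ValueError as exc:
                raise ParseError(
                    f"{path} line {ln}: non-numeric age {row['age_years']!r}"
                ) from exc
            stage = row["stage"].strip()
            tt = _tristate(row["tumor_tissue"], f"{path} line {ln} tumor_tissue")
            if tt is None:
                raise ParseError(f"{path} line {ln}: tumor_tissue must be yes/no")
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    sex=row["sex"].strip().lower(),
                    age_years=age,
                    smoker=_tristate(row["smoker"], f"{path} line {ln} smoker"),
                    stage=stage if stage else "unknown",
                    tumor_tissue=tt,
                    mmr_deficient=_tristate(
                        row["mmr_deficient"], f"{path} line {ln} mmr_deficient"
                    ),
                )
            )
    return patients


def write_clinical_tsv(patients: Iterable[PatientRecord], path) -> None:
    def b(v):
        return "unknown" if v is None else ("yes" if v else "no")

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CLINICAL_COLUMNS)
        for p in patients:
            w.writerow(
                [
                    p.patient_id,
                    p.sex,
                    p.age_years,
                    b(p.smoker),
                    p.stage,
                    "yes" if p.tumor_tissue else "no",
                    b(p.mmr_deficient),
                ]
            )


# ---------------------------------------------------------------------------
# SEG table
# ---------------------------------------------------------------------------

SEG_COLUMNS = ["patient_id", "chrom", "start", "end", "copy_ratio", "minor_allele_copies"]


def read_seg(path, zero_based_half_open: bool = False) -> list:
    """Read allele-specific copy-number segments.

    ``zero_based_half_open=True`` converts UCSC-style coordinates to the
    in-memory 1-based inclusive convention. Overlapping segments for the same
    patient and chromosome are rejected.
    """
    segments = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or [
            c for c in SEG_COLUMNS if c not in reader.fieldnames
        ]:
            raise ParseError(f"{path}: SEG table requires columns {SEG_COLUMNS}")
        for ln, row in enumerate(reader, start=2):
            try:
                start = int(row["start"])
                end = int(row["end"])
                ratio = float(row["copy_ratio"])
            except ValueError as exc:
                raise ParseError(f"{path} line {ln}: {exc}") from exc
            if zero_based_half_open:
                start += 1
            mac = row["minor_allele_copies"].strip()
            segments.append(
                CopySegment(
                    patient_id=row["patient_id"].strip(),
                    chrom=row["chrom"].strip(),
                    start=start,
                    end=end,
                    copy_ratio=ratio,
                    minor_allele_copies=int(mac) if mac not in {"", "NA", "."} else None,
                )
            )
    validate_segments(segments)
    return segments


def validate_segments(segments: Iterable[CopySegment]) -> None:
    """Reject overlapping segments within one patient/chromosome."""
    by_key = defaultdict(list)
    for s in segments:
        by_key[(s.patient_id, s.chrom)].append(s)
    offenders = []
    for (pid, chrom), segs in by_key.items():
        segs.sort(key=lambda s: (s.start, s.end))
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                offenders.append(
                    f"{pid} {chrom}:{a.start}-{a.end} overlaps {chrom}:{b.start}-{b.end}"
                )
    if offenders:
        raise ValidationError("overlapping segments: " + "; ".join(offenders))


def write_seg(segments: Iterable[CopySegment], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SEG_COLUMNS)
        for s in sorted(
            segments, key=lambda s: (s.patient_id, _chrom_sort_key(s.chrom), s.start)
        ):
            w.writerow(
                [
                    s.patient_id,
                    s.chrom,
                    s.start,
                    s.end,
                    _fmt_float(s.copy_ratio),
                    "" if s.minor_allele_copies is None else s.minor_allele_copies,
                ]
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _alt_depth(ad, si, ai, n_alt) -> Optional[int]:
    """Per-alt read depth from an AD array laid out as Number=R or Number=A."""
    if ad is None:
        return None
    ncol = ad.shape[1]
    j = ai + 1 if ncol == n_alt + 1 else ai
    v = int(ad[si][j])
    return None if v < 0 else v


def read_germline_vcf(path, annotation_dialect: str = "default") -> list:
    """Parse a multi-sample germline VCF into one call per sample-site-alt.

    Multi-allelic records are decomposed; annotations absent from INFO map to
    ``None`` (missing), never to filter-passing defaults.
    """
    if annotation_dialect not in GERMLINE_DIALECTS:
        raise ConfigError(f"unknown germline annotation dialect {annotation_dialect!r}")
    keys = GERMLINE_DIALECTS[annotation_dialect]
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad input
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = vcf.samples
    calls = []
    for rec_no, v in enumerate(vcf, start=1):
        info = v.INFO
        gene = info.get(keys["gene"])
        if gene is None:
            raise ParseError(f"{path} record {rec_no} ({v.CHROM}:{v.POS}): missing GENE")
        csq = info.get(keys["consequence"])
        aac = info.get(keys["inframe_aa_change"])
        pop = {}
        for db in ("ExAC", "1000G", "ESP6500"):
            val = info.get(keys[db])
            if val is not None:
                pop[db] = _read_float(val)
        cadd = info.get(keys["cadd_phred"])
        dp = v.format("DP")
        ad = v.format("AD")
        gts = v.genotypes
        n_alt = len(v.ALT)
        for ai, alt in enumerate(v.ALT):
            allele = ai + 1
            for si, sample in enumerate(samples):
                if allele not in gts[si][:-1]:
                    continue
                total = _int_or_missing(dp, si)
                altn = _alt_depth(ad, si, ai, n_alt)
                if total is None or altn is None:
                    raise ParseError(
                        f"{path} record {rec_no}: sample {sample} carries allele "
                        "but lacks DP/AD"
                    )
                calls.append(
                    GermlineVariantCall(
                        patient_id=sample,
                        gene=str(gene),
                        chrom=v.CHROM,
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        consequence=str(csq) if csq is not None else None,
                        inframe_aa_change=int(aac) if aac is not None else 0,
                        reads_total=total,
                        reads_alt=altn,
                        allele_fraction=altn / total if total else 0.0,
                        pop_freqs=pop,
                        sift=info.get(keys["sift"]),
                        polyphen2=info.get(keys["polyphen2"]),
                        cadd_phred=_read_float(cadd) if cadd is not None else None,
                        clinvar_class=info.get(keys["clinvar_class"]),
                        hgmd_class=info.get(keys["hgmd_class"]),
                        dbsnp_id=info.get(keys["dbsnp_id"]),
                    )
                )
    return calls


def read_somatic_vcf(path, annotation_dialect: str = "default") -> list:
    """Parse a multi-sample tumor/normal somatic VCF (one tumor per patient)."""
    if annotation_dialect not in SOMATIC_DIALECTS:
        raise ConfigError(f"unknown somatic annotation dialect {annotation_dialect!r}")
    keys = SOMATIC_DIALECTS[annotation_dialect]
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = vcf.samples
    calls = []
    for rec_no, v in enumerate(vcf, start=1):
        info = v.INFO
        gene = info.get(keys["gene"])
        if gene is None:
            raise ParseError(f"{path} record {rec_no} ({v.CHROM}:{v.POS}): missing GENE")
        csq = info.get(keys["consequence"])
        mqm = info.get(keys["max_mapping_quality"])
        tnc = info.get(keys["trinucleotide_context"])
        tdp = v.format("TDP")
        tad = v.format("TAD")
        ndp = v.format("NDP")
        nad = v.format("NAD")
        gts = v.genotypes
        n_alt = len(v.ALT)
        for ai, alt in enumerate(v.ALT):
            allele = ai + 1
            for si, sample in enumerate(samples):
                if allele not in gts[si][:-1]:
                    continue
                t_total = _int_or_missing(tdp, si)
                t_alt = _alt_depth(tad, si, ai, n_alt)
                n_total = _int_or_missing(ndp, si)
                n_alt_reads = _alt_depth(nad, si, ai, n_alt)
                if None in (t_total, t_alt, n_total, n_alt_reads):
                    raise ParseError(
                        f"{path} record {rec_no}: sample {sample} carries allele "
                        "but lacks TDP/TAD/NDP/NAD"
                    )
                calls.append(
                    SomaticVariantCall(
                        patient_id=sample,
                        gene=str(gene),
                        chrom=v.CHROM,
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        consequence=str(csq) if csq is not None else None,
                        tumor_reads_total=t_total,
                        tumor_reads_alt=t_alt,
                        normal_reads_total=n_total,
                        normal_reads_alt=n_alt_reads,
                        max_mapping_quality=int(mqm) if mqm is not None else 0,
                        vaf=t_alt / t_total if t_total else 0.0,
                        sift=info.get(keys["sift"]),
                        polyphen2=info.get(keys["polyphen2"]),
                        in_dbsnp142=bool(info.get(keys["in_dbsnp142"], False)),
                        in_cosmic=bool(info.get(keys["in_cosmic"], False)),
                        trinucleotide_context=str(tnc) if tnc is not None else None,
                    )
                )
    return calls


_GERMLINE_HEADER_BODY = """\
##INFO=<ID=GENE,Number=1,Type=String,Description="HGNC gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Coding consequence">
##INFO=<ID=AAC,Number=1,Type=Integer,Description="Amino acids affected by in-frame indel">
##INFO=<ID=AF_EXAC,Number=1,Type=Float,Description="ExAC allele frequency">
##INFO=<ID=AF_1KG,Number=1,Type=Float,Description="1000 Genomes allele frequency">
##INFO=<ID=AF_ESP,Number=1,Type=Float,Description="ESP6500 allele frequency">
##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT call">
##INFO=<ID=PP2,Number=1,Type=String,Description="PolyPhen-2 call">
##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD Phred score">
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar classification">
##INFO=<ID=HGMD,Number=1,Type=String,Description="HGMD class">
##INFO=<ID=DBSNP,Number=1,Type=String,Description="dbSNP identifier">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""

_SOMATIC_HEADER_BODY = """\
##INFO=<ID=GENE,Number=1,Type=String,Description="HGNC gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Coding consequence">
##INFO=<ID=MQM,Number=1,Type=Integer,Description="Maximum mapping quality of alt reads">
##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT call">
##INFO=<ID=PP2,Number=1,Type=String,Description="PolyPhen-2 call">
##INFO=<ID=DB142,Number=0,Type=Flag,Description="Present in dbSNP 142">
##INFO=<ID=COSMIC,Number=0,Type=Flag,Description="Documented in COSMIC">
##INFO=<ID=TNC,Number=1,Type=String,Description="Trinucleotide context of the reference strand">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=TDP,Number=1,Type=Integer,Description="Tumor depth">
##FORMAT=<ID=TAD,Number=1,Type=Integer,Description="Tumor alt depth">
##FORMAT=<ID=NDP,Number=1,Type=Integer,Description="Normal depth">
##FORMAT=<ID=NAD,Number=1,Type=Integer,Description="Normal alt depth">
"""


def _vcf_header(body: str, sample_ids) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length=250000000>" for c in _CHROMS]
    lines.append(body.rstrip("\n"))
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids)
    )
    return "\n".join(lines) + "\n"


def write_germline_vcf(calls, path, sample_ids) -> None:
    """Emit a deterministic multi-sample germline VCF (one column per patient)."""
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    by_key = defaultdict(list)
    for c in calls:
        if c.patient_id not in sample_index:
            raise ValidationError(f"call for unknown sample {c.patient_id}")
        by_key[c.key].append(c)
    with open(path, "w") as fh:
        fh.write(_vcf_header(_GERMLINE_HEADER_BODY, sample_ids))
        for key in sorted(by_key, key=lambda k: (_chrom_sort_key(k[0]), k[1], k[2], k[3])):
            group = by_key[key]
            rep = group[0]
            info = [f"GENE={rep.gene}"]
            if rep.consequence is not None:
                info.append(f"CSQ={rep.consequence}")
            if rep.inframe_aa_change:
                info.append(f"AAC={rep.inframe_aa_change}")
            for db, tag in (("ExAC", "AF_EXAC"), ("1000G", "AF_1KG"), ("ESP6500", "AF_ESP")):
                if db in rep.pop_freqs:
                    info.append(f"{tag}={_fmt_float(rep.pop_freqs[db])}")
            for attr, tag in (
                ("sift", "SIFT"),
                ("polyphen2", "PP2"),
                ("clinvar_class", "CLNSIG"),
                ("hgmd_class", "HGMD"),
            ):
                val = getattr(rep, attr)
                if val is not None:
                    info.append(f"{tag}={val}")
            if rep.cadd_phred is not None:
                info.append(f"CADD={_fmt_float(rep.cadd_phred)}")
            cols = ["./."] * len(sample_ids)
            for c in group:
                ref_reads = c.reads_total - c.reads_alt
                cols[sample_index[c.patient_id]] = (
                    f"0/1:{c.reads_total}:{ref_reads},{c.reads_alt}"
                )
            fh.write(
                "\t".join(
                    [
                        key[0],
                        str(key[1]),
                        rep.dbsnp_id or ".",
                        key[2],
                        key[3],
                        ".",
                        "PASS",
                        ";".join(info),
                        "GT:DP:AD",
                    ]
                    + cols
                )
                + "\n"
            )


def write_somatic_vcf(calls, path, sample_ids) -> None:
    """Emit a deterministic multi-sample somatic (tumor/normal) VCF."""
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    by_key = defaultdict(list)
    for c in calls:
        if c.patient_id not in sample_index:
            raise ValidationError(f"call for unknown sample {c.patient_id}")
        by_key[c.key].append(c)
    with open(path, "w") as fh:
        fh.write(_vcf_header(_SOMATIC_HEADER_BODY, sample_ids))
        for key in sorted(by_key, key=lambda k: (_chrom_sort_key(k[0]), k[1], k[2], k[3])):
            group = by_key[key]
            rep = group[0]
            info = [f"GENE={rep.gene}"]
            if rep.consequence is not None:
                info.append(f"CSQ={rep.consequence}")
            info.append(f"MQM={rep.max_mapping_quality}")
            if rep.sift is not None:
                info.append(f"SIFT={rep.sift}")
            if rep.polyphen2 is not None:
                info.append(f"PP2={rep.polyphen2}")
            if rep.in_dbsnp142:
                info.append("DB142")
            if rep.in_cosmic:
                info.append("COSMIC")
            if rep.trinucleotide_context is not None:
                info.append(f"TNC={rep.trinucleotide_context}")
            cols = ["./.:.:.:.:."] * len(sample_ids)
            for c in group:
                cols[sample_index[c.patient_id]] = (
                    f"0/1:{c.tumor_reads_total}:{c.tumor_reads_alt}:"
                    f"{c.normal_reads_total}:{c.normal_reads_alt}"
                )
            fh.write(
                "\t".join(
                    [
                        key[0],
                        str(key[1]),
                        ".",
                        key[2],
                        key[3],
                        ".",
                        "PASS",
                        ";".join(info),
                        "GT:TDP:TAD:NDP:NAD",
                    ]
                    + cols
                )
                + "\n"
            )
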