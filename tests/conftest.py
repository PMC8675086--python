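import numpy as np
import pytest

from rccland.config import FilterConfig
from rccland.model import RccCohortModel
from rccland.simulate import generate_reference_cohort
from rccland.types import GermlineVariantCall, SomaticVariantCall


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """The deterministic reference cohort, generated once per session."""
    out = tmp_path_factory.mktemp("fixture")
    return generate_reference_cohort(out)


@pytest.fixture(scope="session")
def fixture_results(fixture_paths):
    """Full pipeline results on the reference cohort."""
    model = RccCohortModel.from_files(
        clinical_tsv=fixture_paths["clinical_tsv"],
        germline_vcf=fixture_paths["germline_vcf"],
        somatic_vcf=fixture_paths["somatic_vcf"],
        seg_tsv=fixture_paths["seg_tsv"],
    )
    return model.fit()


@pytest.fixture
def cfg():
    return FilterConfig()


def make_gcall(**kwargs) -> GermlineVariantCall:
    """A filter-passing germline call; override any field."""
    base = dict(
        patient_id="P1",
        gene="VHL",
        chrom="chr3",
        pos=10_001_000,
        ref="C",
        alt="T",
        consequence="nonsense",
        reads_total=100,
        reads_alt=48,
        allele_fraction=0.48,
        pop_freqs={"ExAC": 0.0001},
    )
    base.update(kwargs)
    return GermlineVariantCall(**base)


def make_scall(**kwargs) -> SomaticVariantCall:
    """A filter-passing somatic call; override any field."""
    base = dict(
        patient_id="P1",
        gene="TSC1",
        chrom="chr9",
        pos=135_710_000,
        ref="C",
        alt="T",
        consequence="missense",
        tumor_reads_total=100,
        tumor_reads_alt=10,
        normal_reads_total=50,
        normal_reads_alt=0,
        max_mapping_quality=60,
        vaf=0.10,
    )
    base.update(kwargs)
    return SomaticVariantCall(**base)


def random_germline_calls(rng: np.random.Generator, n: int):
    """Random annotated germline calls spanning all filter boundaries."""
    consequences = [
        "nonsense", "frameshift", "missense", "splice",
        "inframe_indel", "synonymous", "non_exonic",
    ]
    calls = []
    for i in range(n):
        total = int(rng.integers(1, 200))
        alt = int(rng.integers(0, total + 1))
        pop = {}
        for db in ("ExAC", "1000G", "ESP6500"):
            if rng.random() < 0.5:
                pop[db] = float(rng.choice([0.0, 0.0001, 0.005, 0.01, 0.02, 0.2]))
        calls.append(
            GermlineVariantCall(
                patient_id=f"P{int(rng.integers(1, 60))}",
                gene="VHL",
                chrom="chr3",
                # few positions so the cohort-frequency rule is exercised
                pos=10_000_000 + int(rng.integers(1, 15)),
                ref="C",
                alt="T",
                consequence=str(rng.choice(consequences)),
                reads_total=total,
                reads_alt=alt,
                allele_fraction=alt / total,
                pop_freqs=pop,
            )
        )
    return calls


def random_somatic_calls(rng: np.random.Generator, n: int):
    calls = []
    for i in range(n):
        t_total = int(rng.integers(1, 60))
        t_alt = int(rng.integers(0, t_total + 1))
        n_total = int(rng.integers(0, 40))
        n_alt = int(rng.integers(0, min(n_total, 3) + 1))
        calls.append(
            SomaticVariantCall(
                patient_id=f"P{int(rng.integers(1, 30))}",
                gene="SETD2",
                chrom="chr3",
                pos=47_050_001 + i,
                ref="C",
                alt="A",
                consequence="missense",
                tumor_reads_total=t_total,
                tumor_reads_alt=t_alt,
                normal_reads_total=n_total,
                normal_reads_alt=n_alt,
                max_mapping_quality=int(rng.integers(0, 70)),
                vaf=t_alt / t_total if t_total else 0.0,
                in_dbsnp142=bool(rng.random() < 0.3),
                in_cosmic=bool(rng.random() < 0.3),
            )
        )
    return calls
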