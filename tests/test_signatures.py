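"""96-context catalogs, NMF extraction, and cosine matching."""
import numpy as np
import pytest

from rccland.config import FilterConfig
from rccland.signatures import (
    CONTEXT_LABELS,
    MutationCatalog,
    SignatureSet,
    build_catalog,
    cosine_match,
    cosine_similarity,
    normalize_snv,
    run_nmf,
)
from rccland.simulate import sample_catalog
from rccland.types import ValidationError

from conftest import make_scall


def test_catalog_has_96_canonical_labels():
    assert len(CONTEXT_LABELS) == 96
    assert len(set(CONTEXT_LABELS)) == 96
    assert CONTEXT_LABELS[0] == "A[C>A]A"


@pytest.mark.parametrize(
    "ref,alt,context,label",
    [
        ("C", "T", "ACA", "A[C>T]A"),
        ("G", "A", "TGT", "A[C>T]A"),  # purine strand normalized by revcomp
        ("T", "G", "ATC", "A[T>G]C"),
        ("A", "C", "GAT", "A[T>G]C"),
    ],
)
def test_normalize_snv(ref, alt, context, label):
    assert normalize_snv(ref, alt, context) == label


def test_normalize_rejects_inconsistent_context():
    with pytest.raises(ValidationError):
        normalize_snv("C", "T", "AGA")  # middle base is not the ref


def test_empty_call_list_gives_zero_catalog():
    catalog = build_catalog([])
    assert catalog.total == 0
    assert catalog.counts.shape == (96, 1)


def test_catalog_total_conserved_and_indels_skipped():
    calls = [
        make_scall(pos=1000 + i, ref="C", alt="T", trinucleotide_context="ACA")
        for i in range(10)
    ]
    calls.append(make_scall(pos=2000, ref="GA", alt="G",
                            consequence="frameshift"))  # indel: skipped
    calls.append(make_scall(pos=3000, ref="C", alt="T",
                            trinucleotide_context=None))  # no context: skipped
    catalog = build_catalog(calls)
    assert catalog.total == 10
    assert catalog.counts[CONTEXT_LABELS.index("A[C>T]A"), 0] == 10


def test_catalog_groups_by_patient_mapping():
    calls = [
        make_scall(patient_id="P1", pos=1000, trinucleotide_context="ACA", ref="C", alt="T"),
        make_scall(patient_id="P2", pos=2000, trinucleotide_context="ACA", ref="C", alt="T"),
        make_scall(patient_id="P2", pos=3000, trinucleotide_context="TCT", ref="C", alt="G"),
    ]
    catalog = build_catalog(calls, groupby={"P1": "SRP", "P2": "NCP"})
    assert catalog.columns == ("NCP", "SRP")
    assert catalog.counts.sum(axis=0).tolist() == [2, 1]


def _planted_signatures():
    """Two synthetic signatures with disjoint supports."""
    s1 = np.zeros(96)
    s2 = np.zeros(96)
    rng = np.random.default_rng(0)
    s1[:48] = rng.uniform(0.2, 1.0, 48)
    s2[48:] = rng.uniform(0.2, 1.0, 48)
    mat = np.column_stack([s1 / s1.sum(), s2 / s2.sum()])
    return SignatureSet(signatures=mat, names=("SBS-like-1", "SBS-like-2"))


def test_rank_one_catalog_recovered_exactly():
    truth = _planted_signatures()
    sig = truth.signatures[:, :1]
    exposures = np.array([[400.0, 900.0, 1600.0]])
    counts = np.rint(sig @ exposures).astype(int)
    catalog = MutationCatalog(counts=counts, columns=("a", "b", "c"))
    extracted, _ = run_nmf(catalog, k=1, seed=0, n_restarts=3)
    assert cosine_similarity(extracted.signatures[:, 0], sig[:, 0]) >= 0.999


def test_nmf_deterministic_given_seed():
    truth = _planted_signatures()
    rng = np.random.default_rng(1)
    catalog = sample_catalog(truth, np.array([[5, 1, 3], [1, 5, 3]], float), 2000, rng)
    a, ea = run_nmf(catalog, k=2, seed=42, n_restarts=4)
    b, eb = run_nmf(catalog, k=2, seed=42, n_restarts=4)
    assert np.array_equal(a.signatures, b.signatures)
    assert ea.equals(eb)


def test_two_planted_signatures_recovered():
    truth = _planted_signatures()
    rng = np.random.default_rng(2)
    catalog = sample_catalog(truth, np.array([[5, 1, 3], [1, 5, 3]], float), 3000, rng)
    extracted, exposures = run_nmf(catalog, k=2, seed=0, n_restarts=5)
    cfg = FilterConfig()
    matches = {cosine_match(extracted.signatures[:, j], truth, cfg)[0] for j in range(2)}
    assert matches == {"SBS-like-1", "SBS-like-2"}
    assert (exposures.to_numpy() >= 0).all()


def test_k_exceeding_nonzero_columns_rejected():
    catalog = build_catalog([])
    with pytest.raises(ValidationError):
        run_nmf(catalog, k=1)


def test_restarts_never_worsen_reconstruction():
    truth = _planted_signatures()
    rng = np.random.default_rng(3)
    catalog = sample_catalog(truth, np.array([[5, 1], [1, 5]], float), 1500, rng)
    X = catalog.counts.astype(float)

    def err(n_restarts):
        sig, exp = run_nmf(catalog, k=2, seed=7, n_restarts=n_restarts)
        return np.linalg.norm(X - sig.signatures @ exp.to_numpy())

    errors = [err(r) for r in (1, 3, 6)]
    assert errors[0] >= errors[1] >= errors[2] - 1e-9


def test_cosine_properties():
    a = np.zeros(96); a[0] = 1
    b = np.zeros(96); b[1] = 1
    ref = SignatureSet(signatures=np.column_stack([a, b]), names=("A", "B"))
    name, sim = cosine_match(a, ref)
    assert (name, sim) == ("A", 1.0)
    # orthogonal one-hot vectors fall below the acceptance threshold
    c = np.zeros(96); c[2] = 1
    name, sim = cosine_match(c, ref)
    assert name is None and sim == 0.0
    with pytest.raises(ValidationError):
        cosine_similarity(np.zeros(96), a)
    # bounded in [0, 1] for non-negative vectors
    rng = np.random.default_rng(5)
    for _ in range(50):
        u, v = rng.uniform(0, 1, 96), rng.uniform(0, 1, 96)
        assert 0.0 <= cosine_similarity(u, v) <= 1.0 + 1e-12
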