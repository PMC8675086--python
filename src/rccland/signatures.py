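"""Single-base-substitution mutational signatures.

Somatic SNVs are tallied into the standard 96-class catalog (6
pyrimidine-centered substitution types x 16 flanking contexts), factorized by
non-negative matrix factorization, and the extracted processes are assigned
to reference signatures by cosine similarity with an acceptance threshold
(default >0.7). Reference signatures (e.g. COSMIC SBS) are user-supplied; the
package ships none.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

from .config import FilterConfig
from .types import SomaticVariantCall, ValidationError

logger = logging.getLogger(__name__)

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
#: the 96 catalog labels, e.g. "A[C>A]A", ordered by substitution then context
CONTEXT_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
_LABEL_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_snv(ref: str, alt: str, context: str) -> str:
    """Map an SNV and its 3-mer context to the pyrimidine-strand catalog label.

    ``context`` is the reference-strand 3-mer around the site; its middle base
    must equal ``ref`` (or the call is inconsistent). Purine references are
    reverse-complemented onto the pyrimidine strand.
    """
    if len(context) != 3 or any(b not in BASES for b in context):
        raise ValidationError(f"bad trinucleotide context {context!r}")
    if context[1] != ref:
        raise ValidationError(
            f"context {context} inconsistent with ref allele {ref}"
        )
    if ref in "GA":
        ref, alt, context = (
            ref.translate(_COMPLEMENT),
            alt.translate(_COMPLEMENT),
            revcomp(context),
        )
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class MutationCatalog:
    """96-row count matrix, one column per sample or patient group."""

    counts: np.ndarray  # (96, m) non-negative ints
    columns: tuple
    labels: tuple = CONTEXT_LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96, len(self.columns)):
            raise ValidationError(
                f"catalog must be 96 x {len(self.columns)}, got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValidationError("catalog counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.columns))


@dataclass
class SignatureSet:
    """Non-negative 96-vectors, each summing to one."""

    signatures: np.ndarray  # (96, k)
    names: tuple

    def __post_init__(self) -> None:
        self.signatures = np.asarray(self.signatures, dtype=float)
        if self.signatures.shape != (96, len(self.names)):
            raise ValidationError("signature matrix must be 96 x len(names)")
        if (self.signatures < 0).any():
            raise ValidationError("signatures must be non-negative")
        sums = self.signatures.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("each signature must sum to 1")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureSet":
        df = df.reindex(list(CONTEXT_LABELS))
        if df.isna().any().any():
            raise ValidationError("reference signatures missing catalog rows")
        mat = df.to_numpy(dtype=float)
        return cls(signatures=mat / mat.sum(axis=0), names=tuple(df.columns))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.signatures, index=list(CONTEXT_LABELS), columns=list(self.names))


def build_catalog(
    calls: Iterable[SomaticVariantCall], groupby: Optional[Dict[str, str]] = None
) -> MutationCatalog:
    """Tally passing somatic SNVs into a 96-context catalog.

    ``groupby`` maps patient_id -> column label (e.g. the SRP/OCP/NCP group);
    without it all calls pool into a single "cohort" column. Indels and calls
    without a context are skipped and counted in the log; a context whose
    middle base contradicts the reference allele is an error.
    """
    calls = list(calls)
    if groupby is None:
        columns: Tuple[str, ...] = ("cohort",)
        col_of = lambda pid: 0  # noqa: E731
    else:
        columns = tuple(sorted(set(groupby.values())))
        index = {g: i for i, g in enumerate(columns)}
        col_of = lambda pid: index[groupby[pid]]  # noqa: E731
    counts = np.zeros((96, max(len(columns), 1)), dtype=int)
    skipped = 0
    for c in calls:
        if not c.is_snv or c.trinucleotide_context is None:
            skipped += 1
            continue
        if groupby is not None and c.patient_id not in groupby:
            skipped += 1
            continue
        label = normalize_snv(c.ref, c.alt, c.trinucleotide_context)
        counts[_LABEL_INDEX[label], col_of(c.patient_id)] += 1
    if skipped:
        logger.info("build_catalog: skipped %d non-SNV/contextless/ungrouped calls", skipped)
    return MutationCatalog(counts=counts, columns=columns)


def run_nmf(
    catalog: MutationCatalog, k: int, seed: int = 0, n_restarts: int = 10
) -> Tuple[SignatureSet, pd.DataFrame]:
    """Factorize a catalog into ``k`` signatures and their exposures.

    Best of ``n_restarts`` random initializations by Frobenius reconstruction
    error; deterministic given ``seed``. Signatures are column-normalized and
    the exposure matrix absorbs the scale, so signatures @ exposures
    approximates the catalog.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    X = catalog.counts.astype(float)
    nonzero_cols = int((X.sum(axis=0) > 0).sum())
    if k > nonzero_cols:
        raise ValidationError(
            f"k={k} exceeds the {nonzero_cols} non-zero catalog column(s)"
        )
    best = None
    for r in range(max(n_restarts, 1)):
        model = NMF(
            n_components=k,
            init="random",
            random_state=(seed + r) % (2**31),
            max_iter=2000,
            tol=1e-6,
        )
        W = model.fit_transform(X)
        if best is None or model.reconstruction_err_ < best[0]:
            best = (model.reconstruction_err_, W, model.components_)
    _, W, H = best
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    W = W / scale
    H = H * scale[:, None]
    names = tuple(f"Sig{i + 1}" for i in range(k))
    sigset = SignatureSet(signatures=W, names=names)
    exposures = pd.DataFrame(H, index=list(names), columns=list(catalog.columns))
    return sigset, exposures


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def cosine_match(
    signature: np.ndarray, reference: SignatureSet, cfg: FilterConfig = None
) -> Tuple[Optional[str], float]:
    """Best reference match by cosine similarity; None when below threshold."""
    cfg = cfg or FilterConfig()
    sims = [
        cosine_similarity(signature, reference.signatures[:, j])
        for j in range(len(reference.names))
    ]
    j = int(np.argmax(sims))
    best = sims[j]
    if best <= cfg.cosine_threshold:
        return None, best
    return reference.names[j], best
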