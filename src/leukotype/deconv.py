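"""Bulk deconvolution: blood-cell-type fractions by non-negative least
squares on a signature matrix, and the low-purity flag.

Leukemic blasts are B-cell precursors, so the collective B-lineage
fraction (pro-B1 through mature B) of a bulk sample estimates its leukemic
cell content; samples below the purity threshold (default 30%) are flagged
because normal-cell contamination degrades subtype classification.
Deconvolution runs in linear space (counts-per-million-like), where
mixtures are additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.optimize import nnls

from .containers import DeconvResult
from .synthetic import B_LINEAGE_BULK, CELL_TYPES

DEFAULT_PURITY_THRESHOLD = 0.30


@dataclass
class SignatureMatrix:
    """Gene x cell-type mean linear expression over 20 blood cell types."""

    values: pd.DataFrame  # genes x cell types
    marker_genes: pd.Index

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("signature expression must be non-negative")
        if self.values.columns.duplicated().any():
            raise ValueError("cell-type names must be unique")
        if list(self.values.columns) != CELL_TYPES:
            missing = set(CELL_TYPES) - set(self.values.columns)
            if missing:
                raise ValueError(f"signature missing cell types: {sorted(missing)}")
            self.values = self.values[CELL_TYPES]
        absent = self.marker_genes.difference(self.values.index)
        if len(absent):
            raise ValueError("marker genes must be rows of the signature")

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out["is_marker"] = out.index.isin(self.marker_genes).astype(int)
        out.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureMatrix":
        t = pd.read_csv(path, sep="\t", index_col=0)
        t.index = t.index.astype(str)
        markers = t.index[t.pop("is_marker").astype(bool)]
        return cls(t, markers)


def synthetic_signature_matrix(n_background: int = 200) -> SignatureMatrix:
    """Signature matrix matching the synthetic generator's cell models.

    Each cell type expresses its 12 signature genes 8-fold over a shared
    background; background genes are identical across types.
    """
    genes = [f"CT.{t}.{k}" for t in CELL_TYPES for k in range(12)]
    genes += [f"G{i:05d}" for i in range(n_background)]
    values = pd.DataFrame(10.0, index=pd.Index(genes, name="gene"), columns=CELL_TYPES)
    for t in CELL_TYPES:
        for k in range(12):
            values.loc[f"CT.{t}.{k}", t] *= 2.0 ** 3.0
    markers = pd.Index([g for g in genes if g.startswith("CT.")])
    return SignatureMatrix(values, markers)


def nnls_fractions(
    bulk: pd.Series,
    sig: SignatureMatrix,
    *,
    blast_types: list[str] | None = None,
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
    min_marker_overlap: float = 0.7,
) -> DeconvResult:
    """Non-negative least squares of one bulk sample on the signature.

    ``bulk`` is linear-scale expression indexed by gene.  Coefficients are
    renormalized to fractions; ``blast_fraction`` sums the B-lineage
    stages (pro-B1 to mature B by default).  Scale-invariant: multiplying
    the bulk vector by a positive constant leaves fractions unchanged.
    """
    shared = sig.marker_genes.intersection(bulk.index)
    if len(shared) / len(sig.marker_genes) < min_marker_overlap:
        raise ValueError(
            f"only {len(shared)}/{len(sig.marker_genes)} signature marker "
            f"genes present (need >= {min_marker_overlap:.0%})"
        )
    y = bulk.loc[shared].to_numpy(dtype=float)
    if not (y > 0).any():
        raise ValueError("bulk sample is all zero over the marker genes")
    A = sig.values.loc[shared].to_numpy(dtype=float)
    coef, _ = nnls(A, y)
    total = coef.sum()
    if total <= 0:
        raise ValueError("deconvolution produced an all-zero solution")
    fractions = pd.Series(coef / total, index=sig.values.columns)
    blast_types = blast_types or B_LINEAGE_BULK
    blast = float(fractions.loc[blast_types].sum())
    return DeconvResult(
        fractions=fractions,
        blast_fraction=blast,
        low_purity_flag=flag_low_purity(blast, purity_threshold),
    )


def flag_low_purity(
    blast_fraction: float, threshold: float = DEFAULT_PURITY_THRESHOLD
) -> bool:
    """True iff the B-lineage fraction falls below the purity threshold.

    Flagged samples are annotated, never suppressed: classification still
    runs, but the report warns that contamination may distort the call.
    """
    return blast_fraction < threshold
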