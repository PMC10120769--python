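"""Core domain containers shared across the pipeline.

Genes are keyed by unique string IDs (symbols or stable IDs); matrices are
pandas DataFrames with genes as rows and samples as columns so that label
alignment, subsetting and TSV round-trips all go through pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

VALID_CHROMS = [str(c) for c in range(1, 23)] + ["X", "Y"]
AUTOSOMES = [str(c) for c in range(1, 23)]


class ConfigurationError(ValueError):
    """Raised when an input configuration violates a documented contract."""


@dataclass
class CountMatrix:
    """Integer gene x sample read counts with per-gene annotation.

    Attributes
    ----------
    values : DataFrame
        Non-negative integer counts, genes as rows, samples as columns.
    gene_chrom : Series
        Chromosome label per gene ("1".."22", "X", "Y", or "other").
    coding : Series
        Boolean protein-coding flag per gene.
    gene_pos : Series or None
        Optional position of each gene along its chromosome (arbitrary
        monotone units); required only for iAMP21 segmental analysis.
    """

    values: pd.DataFrame
    gene_chrom: pd.Series
    coding: pd.Series
    gene_pos: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("gene IDs must be unique")
        for ann in (self.gene_chrom, self.coding):
            if not ann.index.equals(self.values.index):
                raise ValueError("gene annotation index must match count rows")
        bad = set(self.gene_chrom.unique()) - set(VALID_CHROMS) - {"other"}
        if bad:
            raise ValueError(f"invalid chromosome labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path: str | Path) -> None:
        """Write counts as TSV (genes as rows, header = sample IDs)."""
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    def write_annotation(self, path: str | Path) -> None:
        ann = pd.DataFrame(
            {"chrom": self.gene_chrom, "coding": self.coding.astype(int)}
        )
        if self.gene_pos is not None:
            ann["pos"] = self.gene_pos
        ann.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, annotation_path: str | Path | None = None
    ) -> "CountMatrix":
        values = pd.read_csv(counts_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        if annotation_path is not None:
            ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
            ann.index = ann.index.astype(str)
            ann = ann.reindex(values.index)
            chrom = ann["chrom"].astype(str)
            coding = ann["coding"].astype(bool)
            pos = ann["pos"].astype(float) if "pos" in ann else None
        else:
            chrom = pd.Series("other", index=values.index)
            coding = pd.Series(True, index=values.index)
            pos = None
        return cls(values.round().astype(np.int64), chrom, coding, pos)

    @classmethod
    def from_mtx(
        cls,
        mtx_path: str | Path,
        genes_path: str | Path,
        samples_path: str | Path,
        annotation_path: str | Path | None = None,
    ) -> "CountMatrix":
        """Read a genes x samples MatrixMarket file plus two index files."""
        mat = sparse.csr_matrix(spio.mmread(str(mtx_path)))
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
        samples = pd.read_csv(samples_path, sep="\t", header=None)[0].astype(str)
        values = pd.DataFrame(
            mat.toarray().astype(np.int64), index=genes, columns=samples
        )
        tmp = cls.from_tsv_frame(values)
        if annotation_path is not None:
            return cls.from_frames(values, annotation_path)
        return tmp

    @classmethod
    def from_tsv_frame(cls, values: pd.DataFrame) -> "CountMatrix":
        return cls(
            values,
            pd.Series("other", index=values.index),
            pd.Series(True, index=values.index),
        )

    @classmethod
    def from_frames(
        cls, values: pd.DataFrame, annotation_path: str | Path
    ) -> "CountMatrix":
        ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
        ann.index = ann.index.astype(str)
        ann = ann.reindex(values.index)
        pos = ann["pos"].astype(float) if "pos" in ann else None
        return cls(
            values, ann["chrom"].astype(str), ann["coding"].astype(bool), pos
        )


@dataclass
class GEPMatrix:
    """Variance-stabilized gene x sample expression.

    ``provenance`` records whether values came from the closed-form VST or
    the log2(normalized + 1) fallback.
    """

    values: pd.DataFrame
    provenance: str = "vst"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.values).all():
            raise ValueError("GEP values must be finite")
        if self.provenance not in ("vst", "log-fallback"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class FusionCall:
    """A normalized fusion-caller row (5' partner, 3' partner)."""

    gene5p: str
    gene3p: str
    caller: str  # "fusioncatcher-style" | "cicero-style" | "dual-caller"
    supporting_reads: int
    raw_row: int = -1

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene5p", self.gene5p.upper())
        object.__setattr__(self, "gene3p", self.gene3p.upper())
        if self.supporting_reads < 0:
            raise ValueError("supporting_reads must be >= 0")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5p, self.gene3p)

    @property
    def unordered(self) -> frozenset:
        return frozenset((self.gene5p, self.gene3p))

    def __str__(self) -> str:  # e.g. "BCR::ABL1"
        return f"{self.gene5p}::{self.gene3p}"


@dataclass(frozen=True)
class MutationCall:
    """A filtered short-variant call normalized to (gene, protein change)."""

    gene: str
    protein_change: str  # e.g. "P80R"
    chrom: str = "other"
    pos: int = 0
    ref: str = ""
    alt: str = ""
    population_af: float | None = None
    allele_depths: tuple[int, int] | None = None  # (ref depth, alt depth)
    annotated: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.upper())
        if self.population_af is not None and not 0 <= self.population_af <= 1:
            raise ValueError("population_af must be in [0, 1]")

    @property
    def vaf(self) -> float | None:
        if self.allele_depths is None:
            return None
        dref, dalt = self.allele_depths
        total = dref + dalt
        return dalt / total if total > 0 else None


@dataclass
class MatchedLesion:
    """A lesion matched against the sentinel catalog."""

    lesion: FusionCall | MutationCall
    implied_subtype: str | None
    kinase_class: bool = False  # Ph-like-class kinase evidence
    gep_consistency: str = "untested"  # consistent | inconsistent | untested

    @property
    def is_fusion(self) -> bool:
        return isinstance(self.lesion, FusionCall)


@dataclass
class LesionEvidence:
    """All lesion evidence for one sample after sentinel matching."""

    sentinel_fusions: list[MatchedLesion] = field(default_factory=list)
    sentinel_mutations: list[MatchedLesion] = field(default_factory=list)
    reportable_mutations: list[MutationCall] = field(default_factory=list)
    other_fusions: list[FusionCall] = field(default_factory=list)
    other_mutations: list[MutationCall] = field(default_factory=list)
    pax5_iamp: bool = False  # user-supplied intragenic amplification flag

    def fusions_implying(self, subtype: str) -> list[MatchedLesion]:
        return [
            m for m in self.sentinel_fusions if m.implied_subtype == subtype
        ]

    def has_fusion_pair(self, gene5p: str, gene3p: str) -> bool:
        pair = frozenset((gene5p.upper(), gene3p.upper()))
        return any(
            m.lesion.unordered == pair
            for m in self.sentinel_fusions
            if isinstance(m.lesion, FusionCall)
        )


@dataclass
class ModelPrediction:
    """One model's multi-round votes for one sample."""

    votes: list[str]
    modal_label: str
    confidence: float
    reported: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class GEPPrediction:
    """Unified GEP-level call for one sample from both ensemble models."""

    svm: ModelPrediction | None
    phenograph: ModelPrediction | None
    unified_label: str
    flag: str  # concordant | discordant | single-model | unclassified

    @property
    def reported(self) -> bool:
        return self.unified_label != "unclassified"


@dataclass
class ChromCNVProfile:
    """Chromosome-level copy state for one sample."""

    copies: dict[str, int]  # per chromosome, inferred integer copy
    ratios: dict[str, float]  # per chromosome log2 expression ratio
    baf_scores: dict[str, float]  # per chromosome |VAF-0.5| imbalance score
    unreliable: set[str]
    est_chrom_number: int
    karyotype_class: str  # Near haploid | Low hypodiploid | Low hyperdiploid
    #                       | Hyperdiploid | none | unreliable
    iamp21_flag: bool | None = None  # None = not assessable
    inferred_sex: str = "unknown"

    def __post_init__(self) -> None:
        total = sum(self.copies.values())
        if total != self.est_chrom_number:
            raise ValueError(
                "est_chrom_number must equal the sum of per-chromosome copies"
            )


@dataclass
class IntegratedCall:
    """The definitive subtype call with its full evidence trail."""

    sample_id: str
    final_subtype: str
    rule_id: str
    evidence_trail: list[tuple[str, str]]  # (evidence description, role)
    confidence_note: str  # lesion+GEP concordant | lesion-over-GEP
    #                       | GEP-only | insufficient
    provisional: bool = False

    def __post_init__(self) -> None:
        if self.final_subtype != "unclassified" and not self.evidence_trail:
            raise ValueError("a classified call must cite evidence")


@dataclass
class FeatureRanking:
    """Consensus feature genes ordered by mean Boruta importance."""

    table: pd.DataFrame  # index gene_id; columns importance, confirmed_in

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns[:2]) != ["importance", "confirmed_in"]:
            raise ValueError("ranking columns must be importance, confirmed_in")
        imp = t["importance"].to_numpy()
        if (np.diff(imp) > 1e-12).any():
            raise ValueError("ranking must be sorted by descending importance")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def top(self, k: int) -> pd.Index:
        return self.table.index[:k]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureRanking":
        t = pd.read_csv(path, sep="\t", index_col=0)
        t.index = t.index.astype(str)
        return cls(t)


@dataclass
class DeconvResult:
    """Cell-type fractions for one bulk sample plus the purity verdict."""

    fractions: pd.Series  # index = cell types, sums to 1
    blast_fraction: float
    low_purity_flag: bool

    def __post_init__(self) -> None:
        if (self.fractions < -1e-9).any():
            raise ValueError("fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-6:
            raise ValueError("fractions must sum to 1")
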