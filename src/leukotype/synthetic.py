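"""Synthetic B-ALL cohort generation.

Generates subtype-structured bulk and single-cell cohorts with internally
consistent genetic lesions so that every downstream stage (normalization,
feature selection, classification, lesion matching, CNV inference, rule
integration, deconvolution, single-cell annotation) can be exercised and
validated without patient data.

The expression model is a negative-binomial background: per-gene baseline
means are drawn log-normally, each sample gets a library-size factor, the
marker genes of the sample's subtype are mean-shifted by their log2 effect
(scaled by the subtype's distinctness class), genes on a chromosome with
copy number c have means multiplied by c/2, and lesion-coupled driver genes
(e.g. CRLF2 in CRLF2-rearranged samples) receive an additional boost.
Sentinel fusions and hotspot mutations are emitted alongside, with decoy
false-positive fusion rows and common SNPs, because real caller output is
dominated by noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import VALID_CHROMS, ConfigurationError, CountMatrix

# --------------------------------------------------------------------------
# vocabularies

CELL_TYPES = [
    "CLP", "pro-B1", "pro-B2", "pre-B1", "pre-B2", "immature B", "mature B",
    "plasma", "HSC", "LMPP", "GMP", "MEP", "DC", "myelocyte",
    "pro-myelocyte", "monocyte", "T", "NK", "erythroid", "megakaryocyte",
]
#: B-lineage window summed into the bulk blast fraction (pro-B1 .. mature B)
B_LINEAGE_BULK = ["pro-B1", "pro-B2", "pre-B1", "pre-B2", "immature B", "mature B"]
#: leukemic blast window at single-cell level (pro- to pre-B cells)
BLAST_CELL_TYPES = ["pro-B1", "pro-B2", "pre-B1", "pre-B2"]

#: the 19 expression-distinct classes emitted by the GEP models
GEP_CLASSES = [
    "ETV6::RUNX1", "KMT2A", "TCF3::PBX1", "DUX4", "MEF2D", "ZNF384",
    "BCL2/MYC", "HLF", "NUTM1", "CDX2/UBTF", "PAX5::ETV6", "PAX5 P80R",
    "PAX5alt", "IKZF1 N159Y", "Ph/Ph-like", "Hyperdiploid",
    "Low hypodiploid", "iAMP21", "ZEB2/CEBP",
]

DISTINCTNESS_SCALE = {
    "highly distinct": 1.0,
    "distinct": 0.8,
    "less distinct": 0.5,
    "non-distinct": 0.0,
}

#: driver genes pinned to their true chromosomes
NAMED_GENES = {
    "ETV6": "12", "RUNX1": "21", "KMT2A": "11", "AFF1": "4", "TCF3": "19",
    "PBX1": "1", "DUX4": "4", "IGH": "14", "MEF2D": "1", "BCL9": "1",
    "ZNF384": "12", "EP300": "22", "BCL2": "18", "MYC": "8", "BCL6": "3",
    "HLF": "17", "NUTM1": "15", "ACIN1": "14", "UBTF": "17", "ATXN7L3": "17",
    "CDX2": "13", "PAX5": "9", "NOL4L": "20", "IKZF1": "7", "ZEB2": "2",
    "BCR": "22", "ABL1": "9", "CRLF2": "X", "P2RY8": "X", "JAK2": "9",
    "EPOR": "19", "TP53": "17", "FLT3": "13", "IL7R": "5", "NRAS": "1",
    "KRAS": "12", "PTPN11": "12",
    "RPS4Y1": "Y", "DDX3Y": "Y", "EIF1AY": "Y", "KDM5D": "Y",
}
MITO_GENES = [f"MT-G{i}" for i in range(1, 14)]

#: fusion category -> lesion-coupled overexpressed gene and its log2 boost
LESION_EXPRESSION_BOOST = {
    "CRLF2": ("CRLF2", 4.0),
    "DUX4": ("DUX4", 5.0),
    "NUTM1": ("NUTM1", 4.0),
    "HLF": ("HLF", 4.0),
    "UBTF::ATXN7L3": ("CDX2", 4.0),
}


# --------------------------------------------------------------------------
# configuration types

@dataclass
class SubtypeSpec:
    """Generative description of one molecular subtype.

    ``gep_class`` is the expression class the subtype belongs to (phenocopy
    subtypes share the class of their canonical counterpart); ``None`` means
    the subtype has no recognizable expression signature.
    """

    name: str
    marker_genes: dict[str, float]  # gene -> log2 effect (> 0)
    gep_class: str | None
    sentinel_fusion: tuple[str, str] | None = None
    sentinel_mutation: tuple[str, str] | None = None  # (gene, protein change)
    chrom_profile: dict[str, int] = field(default_factory=dict)
    distinctness: str = "distinct"
    iamp21_segment: bool = False  # segmental chr21 amplification (copy 5)

    def __post_init__(self) -> None:
        if not self.chrom_profile:
            self.chrom_profile = default_chrom_profile()
        if set(self.chrom_profile) != set(VALID_CHROMS):
            raise ConfigurationError(
                f"{self.name}: chrom_profile needs 24 entries (1-22, X, Y)"
            )
        if any(not 1 <= c <= 6 for c in self.chrom_profile.values()):
            raise ConfigurationError(f"{self.name}: copy numbers must be 1..6")
        if any(e <= 0 for e in self.marker_genes.values()):
            raise ConfigurationError(f"{self.name}: marker effects must be > 0")
        if self.distinctness not in DISTINCTNESS_SCALE:
            raise ConfigurationError(
                f"{self.name}: unknown distinctness {self.distinctness!r}"
            )

    @property
    def effect_scale(self) -> float:
        return DISTINCTNESS_SCALE[self.distinctness]

    @property
    def chrom_number(self) -> int:
        return sum(self.chrom_profile.values())


def default_chrom_profile(**overrides: int) -> dict[str, int]:
    """A 46,XY diploid profile with optional per-chromosome overrides."""
    profile = {c: 2 for c in VALID_CHROMS}
    profile["X"] = 1
    profile["Y"] = 1
    for chrom, copy in overrides.items():
        profile[str(chrom)] = copy
    return profile


@dataclass
class CohortConfig:
    subtype_specs: list[SubtypeSpec]
    samples_per_subtype: int = 30
    n_genes: int = 2600
    nb_dispersion: float = 0.15  # asymptotic dispersion of the NB background
    nb_extra_poisson: float = 1.5  # 1/mean dispersion component (low-count excess)
    library_size_range: tuple[float, float] = (0.7, 1.5)
    base_mean_log_mu: float = np.log(30.0)
    base_mean_log_sigma: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_subtype < 1:
            raise ConfigurationError("samples_per_subtype must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        n_markers = len(
            {g for s in self.subtype_specs for g in s.marker_genes}
        )
        if self.n_genes < n_markers:
            raise ConfigurationError("n_genes smaller than marker universe")


@dataclass
class TruthRecord:
    """Ground truth for one generated sample."""

    sample_id: str
    subtype: str
    gep_class: str | None
    fusion: tuple[str, str] | None
    mutation: tuple[str, str] | None
    chrom_profile: dict[str, int]
    iamp21: bool = False


@dataclass
class BulkTruth:
    labels: pd.Series  # sample -> subtype name
    records: list[TruthRecord]
    chrom_profiles: pd.DataFrame  # sample x chromosome integer copies

    def record_for(self, sample_id: str) -> TruthRecord:
        return next(r for r in self.records if r.sample_id == sample_id)


# --------------------------------------------------------------------------
# default subtype catalog

def _markers(tag: str, extra: dict[str, float] | None = None) -> dict[str, float]:
    effects = [3.0, 2.5, 2.5, 2.0, 2.0, 1.8, 1.6, 1.5]
    m = {f"{tag}.M{i}": e for i, e in enumerate(effects)}
    if extra:
        m.update(extra)
    return m


def default_subtype_specs() -> list[SubtypeSpec]:
    """The shipped subtype catalog: all rule-table subtypes plus ZEB2/CEBP.

    Phenocopy subtypes reuse the marker set of their canonical class; the
    aneuploid subtypes are defined mainly by their chromosome profiles.
    """
    class_markers = {c: _markers(f"C{i:02d}") for i, c in enumerate(GEP_CLASSES)}
    S = SubtypeSpec
    cm = class_markers
    return [
        S("ETV6::RUNX1", cm["ETV6::RUNX1"], "ETV6::RUNX1",
          sentinel_fusion=("ETV6", "RUNX1"), distinctness="highly distinct"),
        S("ETV6::RUNX1-like", cm["ETV6::RUNX1"], "ETV6::RUNX1",
          distinctness="highly distinct"),
        S("KMT2A", cm["KMT2A"], "KMT2A",
          sentinel_fusion=("KMT2A", "AFF1"), distinctness="distinct"),
        S("KMT2A-like", cm["KMT2A"], "KMT2A", distinctness="distinct"),
        S("TCF3::PBX1", cm["TCF3::PBX1"], "TCF3::PBX1",
          sentinel_fusion=("TCF3", "PBX1"), distinctness="highly distinct"),
        S("DUX4", cm["DUX4"], "DUX4",
          sentinel_fusion=("IGH", "DUX4"), distinctness="highly distinct"),
        S("MEF2D", cm["MEF2D"], "MEF2D",
          sentinel_fusion=("MEF2D", "BCL9"), distinctness="highly distinct"),
        S("ZNF384", cm["ZNF384"], "ZNF384",
          sentinel_fusion=("EP300", "ZNF384"), distinctness="highly distinct"),
        S("ZNF384-like", cm["ZNF384"], "ZNF384",
          distinctness="highly distinct"),
        S("BCL2/MYC", cm["BCL2/MYC"], "BCL2/MYC",
          sentinel_fusion=("IGH", "MYC"), distinctness="distinct"),
        S("HLF", cm["HLF"], "HLF",
          sentinel_fusion=("TCF3", "HLF"), distinctness="distinct"),
        S("NUTM1", cm["NUTM1"], "NUTM1",
          sentinel_fusion=("ACIN1", "NUTM1"), distinctness="less distinct"),
        S("CDX2/UBTF", cm["CDX2/UBTF"], "CDX2/UBTF",
          sentinel_fusion=("UBTF", "ATXN7L3"), distinctness="highly distinct"),
        S("PAX5::ETV6", cm["PAX5::ETV6"], "PAX5::ETV6",
          sentinel_fusion=("PAX5", "ETV6"), distinctness="distinct"),
        S("PAX5 P80R", cm["PAX5 P80R"], "PAX5 P80R",
          sentinel_mutation=("PAX5", "P80R"), distinctness="highly distinct"),
        S("PAX5alt", cm["PAX5alt"], "PAX5alt",
          sentinel_fusion=("PAX5", "NOL4L"), distinctness="distinct"),
        S("IKZF1 N159Y", cm["IKZF1 N159Y"], "IKZF1 N159Y",
          sentinel_mutation=("IKZF1", "N159Y"), distinctness="highly distinct"),
        S("Ph", cm["Ph/Ph-like"], "Ph/Ph-like",
          sentinel_fusion=("BCR", "ABL1"), distinctness="distinct"),
        S("Ph-like", cm["Ph/Ph-like"], "Ph/Ph-like",
          sentinel_fusion=("IGH", "CRLF2"), distinctness="distinct"),
        S("CRLF2(non-Ph-like)", {}, None,
          sentinel_fusion=("P2RY8", "CRLF2"), distinctness="non-distinct"),
        S("ZEB2/CEBP", cm["ZEB2/CEBP"], "ZEB2/CEBP",
          sentinel_mutation=("ZEB2", "H1038R"), distinctness="distinct"),
        S("iAMP21", cm["iAMP21"], "iAMP21",
          distinctness="less distinct", iamp21_segment=True),
        S("Hyperdiploid", cm["Hyperdiploid"], "Hyperdiploid",
          chrom_profile=default_chrom_profile(
              **{"4": 3, "6": 3, "10": 3, "14": 3, "17": 3, "18": 3,
                 "21": 3, "X": 2}),
          distinctness="distinct"),
        S("Low hyperdiploid", cm["Hyperdiploid"], "Hyperdiploid",
          chrom_profile=default_chrom_profile(**{"10": 3, "21": 3}),
          distinctness="distinct"),
        S("Low hypodiploid", cm["Low hypodiploid"], "Low hypodiploid",
          sentinel_mutation=("TP53", "R248Q"),
          chrom_profile=default_chrom_profile(
              **{"2": 1, "3": 1, "4": 1, "7": 1, "9": 1, "12": 1, "13": 1,
                 "15": 1, "16": 1, "17": 1, "20": 1}),
          distinctness="distinct"),
        S("Near haploid", cm["Hyperdiploid"], "Hyperdiploid",
          chrom_profile={
              **{str(c): 1 for c in range(1, 23)}, "14": 2, "18": 2,
              "21": 2, "X": 1, "Y": 1},
          distinctness="non-distinct"),
    ]


def make_distinct_specs(
    n_classes: int = 8, effect: float = 2.0, n_markers: int = 10
) -> list[SubtypeSpec]:
    """Small highly distinct subtype set for classifier stress tests."""
    classes = GEP_CLASSES[:n_classes]
    return [
        SubtypeSpec(
            c,
            {f"C{i:02d}.M{k}": effect for k in range(n_markers)},
            c,
            distinctness="highly distinct",
        )
        for i, c in enumerate(classes)
    ]


# --------------------------------------------------------------------------
# gene universe

def build_gene_universe(
    config: CohortConfig, include_celltype_genes: bool = False
) -> tuple[pd.Index, pd.Series, pd.Series, pd.Series]:
    """Assemble gene IDs with chromosome, coding flag, and position.

    Named driver genes sit on their true chromosomes; marker and filler
    genes are distributed round-robin over all 24 chromosomes with monotone
    within-chromosome positions.
    """
    special: list[str] = list(NAMED_GENES)
    marker_ids = sorted(
        {g for s in config.subtype_specs for g in s.marker_genes}
        - set(NAMED_GENES)
    )
    celltype_ids = (
        [f"CT.{t}.{k}" for t in CELL_TYPES for k in range(12)]
        if include_celltype_genes
        else []
    )
    named = special + marker_ids + celltype_ids + MITO_GENES
    n_filler = config.n_genes - len(named)
    if n_filler < 0:
        raise ConfigurationError("n_genes too small for the named gene set")
    filler = [f"G{i:05d}" for i in range(n_filler)]
    ids = pd.Index(named + filler, name="gene_id")

    chrom = {}
    pos_counter = {c: 0 for c in VALID_CHROMS + ["other"]}
    pos = {}
    rotation = [c for c in VALID_CHROMS if c != "Y"] * 3 + ["Y"]
    for i, g in enumerate(ids):
        if g in NAMED_GENES:
            c = NAMED_GENES[g]
        elif g in MITO_GENES:
            c = "other"
        else:
            c = rotation[i % len(rotation)]
        chrom[g] = c
        pos[g] = float(pos_counter[c])
        pos_counter[c] += 1
    chrom_s = pd.Series(chrom, name="chrom").reindex(ids)
    pos_s = pd.Series(pos, name="pos").reindex(ids)
    coding = pd.Series(True, index=ids, name="coding")
    # a slice of filler genes is flagged non-coding so coding-only filters bite
    noncoding = [g for g in filler[:: 10]]
    coding.loc[noncoding] = False
    return ids, chrom_s, coding, pos_s


# --------------------------------------------------------------------------
# bulk generation

def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, disp: float | np.ndarray
) -> np.ndarray:
    r = 1.0 / np.asarray(disp, dtype=float)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_bulk_cohort(
    config: CohortConfig,
) -> tuple[CountMatrix, BulkTruth]:
    """Generate a bulk cohort with subtype-consistent lesions.

    Returns the count matrix and a :class:`BulkTruth` holding labels,
    per-sample lesion truth, and per-sample chromosome copy profiles.
    Deterministic under ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    ids, chrom, coding, pos = build_gene_universe(config)
    for spec in config.subtype_specs:
        missing = set(spec.marker_genes) - set(ids)
        if missing:
            raise ConfigurationError(
                f"{spec.name}: marker genes not in universe: {sorted(missing)}"
            )

    base = np.exp(
        rng.normal(config.base_mean_log_mu, config.base_mean_log_sigma, len(ids))
    )
    # subtype signature genes and named driver genes are reliably expressed
    # in real cohorts; floor their baseline at the typical gene mean so the
    # configured log2 effects are recoverable from group means
    floor = np.exp(config.base_mean_log_mu)
    anchored = {g for s in config.subtype_specs for g in s.marker_genes}
    anchored |= set(NAMED_GENES)
    for g in anchored:
        loc = ids.get_loc(g)
        base[loc] = max(base[loc], floor)
    base_s = pd.Series(base, index=ids)
    chrom_arr = chrom.to_numpy()
    pos_arr = pos.to_numpy()

    cols, labels, records, profiles = [], {}, [], {}
    lo, hi = config.library_size_range
    counter = 0
    for spec in config.subtype_specs:
        scale = np.ones(len(ids))
        for c, copy in spec.chrom_profile.items():
            scale[chrom_arr == c] *= copy / 2.0
        for g, eff in spec.marker_genes.items():
            scale[ids.get_loc(g)] *= 2.0 ** (eff * spec.effect_scale)
        if spec.iamp21_segment:
            on21 = np.where(chrom_arr == "21")[0]
            p21 = pos_arr[on21]
            lo21, hi21 = np.quantile(p21, [0.3, 0.7])
            seg = on21[(p21 >= lo21) & (p21 <= hi21)]
            scale[seg] *= 5.0 / 2.0  # focal 5-copy amplification
        if spec.sentinel_fusion is not None:
            cat = _boost_category(spec.sentinel_fusion)
            if cat is not None:
                gene, boost = LESION_EXPRESSION_BOOST[cat]
                scale[ids.get_loc(gene)] *= 2.0 ** boost

        for _ in range(config.samples_per_subtype):
            sid = f"S{counter:04d}"
            counter += 1
            lib = rng.uniform(lo, hi)
            mean = np.maximum(base * scale * lib, 1e-8)
            # dispersion decreases with expression, mirroring the usual
            # parametric mean-dispersion trend of bulk RNA-seq
            disp = config.nb_dispersion + config.nb_extra_poisson / np.maximum(mean, 0.5)
            cols.append(_nb_draw(rng, mean, disp))
            labels[sid] = spec.name
            records.append(
                TruthRecord(
                    sid, spec.name, spec.gep_class, spec.sentinel_fusion,
                    spec.sentinel_mutation, dict(spec.chrom_profile),
                    spec.iamp21_segment,
                )
            )
            profiles[sid] = dict(spec.chrom_profile)

    values = pd.DataFrame(
        np.column_stack(cols).astype(np.int64),
        index=ids,
        columns=list(labels),
    )
    counts = CountMatrix(values, chrom, coding, pos)
    truth = BulkTruth(
        pd.Series(labels, name="subtype"),
        records,
        pd.DataFrame(profiles).T.reindex(columns=VALID_CHROMS),
    )
    # keep base means around for signature construction
    counts.base_means = base_s  # type: ignore[attr-defined]
    return counts, truth


def _boost_category(fusion: tuple[str, str]) -> str | None:
    pair = {fusion[0].upper(), fusion[1].upper()}
    if pair == {"UBTF", "ATXN7L3"}:
        return "UBTF::ATXN7L3"
    for gene in ("CRLF2", "DUX4", "NUTM1", "HLF"):
        if gene in pair:
            return gene
    return None


# --------------------------------------------------------------------------
# single-cell generation

def generate_sc_matrix(
    spec: SubtypeSpec,
    n_blasts: int,
    contaminant_mix: dict[str, float],
    rng_seed: int = 0,
    *,
    n_cells_total: int | None = None,
    n_genes: int = 1600,
    mean_umis: float = 8000.0,  # typical droplet-based depth per cell
    dispersion: float = 0.4,
) -> tuple[sparse.csr_matrix, pd.Index, pd.Index, pd.Series]:
    """Generate a sparse cell x gene count matrix with truth labels.

    Blast cells carry the subtype's marker shifts on top of a randomly
    assigned B-precursor stage signature (pro-B1 .. pre-B2); contaminant
    cells carry their cell-type signature.  ``contaminant_mix`` fractions
    refer to the non-blast compartment and must sum to 1.

    Returns (matrix, barcodes, gene_ids, truth labels) where truth labels
    are "blast" or the contaminant cell type.
    """
    if abs(sum(contaminant_mix.values()) - 1.0) > 1e-6:
        raise ConfigurationError("contaminant fractions must sum to 1")
    if n_blasts < 0:
        raise ConfigurationError("n_blasts must be >= 0")
    total = n_cells_total or (n_blasts * 2 if n_blasts else 1000)
    n_contam = total - n_blasts
    if n_blasts == 0 and n_contam == 0:
        raise ConfigurationError("requested an empty cell population")

    rng = np.random.default_rng(rng_seed)
    # the cell transcriptome shares one gene universe with bulk cohorts:
    # include the whole marker vocabulary so bulk-trained references can
    # be cross-applied to cells
    universe_specs = default_subtype_specs() + make_distinct_specs(8) + [spec]
    cfg = CohortConfig(
        universe_specs,
        n_genes=n_genes,
        rng_seed=rng_seed,
        samples_per_subtype=1,
    )
    ids, chrom, coding, pos = build_gene_universe(
        cfg, include_celltype_genes=True
    )
    base = np.exp(rng.normal(np.log(2.0), 1.0, len(ids)))
    base[[ids.get_loc(g) for g in MITO_GENES]] *= 5.0  # mito background

    def celltype_scale(ct: str) -> np.ndarray:
        s = np.ones(len(ids))
        for k in range(12):
            s[ids.get_loc(f"CT.{ct}.{k}")] *= 2.0 ** 3.0
        return s

    rows: list[np.ndarray] = []
    labels: list[str] = []
    blast_stage_scales = {ct: celltype_scale(ct) for ct in BLAST_CELL_TYPES}
    marker_scale = np.ones(len(ids))
    for g, eff in spec.marker_genes.items():
        marker_scale[ids.get_loc(g)] *= 2.0 ** (eff * spec.effect_scale)

    for _ in range(n_blasts):
        stage = BLAST_CELL_TYPES[rng.integers(len(BLAST_CELL_TYPES))]
        scale = blast_stage_scales[stage] * marker_scale
        rows.append(_sc_cell(rng, base * scale, mean_umis, dispersion))
        labels.append("blast")
    contam_types = list(contaminant_mix)
    probs = np.array([contaminant_mix[t] for t in contam_types])
    contam_scales = {t: celltype_scale(t) for t in contam_types}
    for _ in range(n_contam):
        ct = contam_types[rng.choice(len(contam_types), p=probs)]
        rows.append(_sc_cell(rng, base * contam_scales[ct], mean_umis, dispersion))
        labels.append(ct)

    mat = sparse.csr_matrix(np.vstack(rows))
    barcodes = pd.Index([f"CELL{i:05d}" for i in range(len(labels))])
    return mat, barcodes, ids, pd.Series(labels, index=barcodes, name="truth")


def _sc_cell(
    rng: np.random.Generator, rel_mean: np.ndarray, mean_umis: float, disp: float
) -> np.ndarray:
    lib = rng.lognormal(np.log(mean_umis), 0.3)
    mean = rel_mean / rel_mean.sum() * lib
    return _nb_draw(rng, np.maximum(mean, 1e-10), disp)


def write_sc_matrix(
    mat: sparse.spmatrix,
    barcodes: pd.Index,
    gene_ids: pd.Index,
    out_dir: str | Path,
) -> None:
    """Write MatrixMarket triplet + barcodes/features index files."""
    from scipy import io as spio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(out / "matrix.mtx"), sparse.coo_matrix(mat))
    pd.Series(barcodes).to_csv(
        out / "barcodes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(gene_ids).to_csv(
        out / "features.tsv", sep="\t", index=False, header=False
    )


# --------------------------------------------------------------------------
# lesion file emission (VCF + fusion TSVs)

_FC_HEADER = (
    "Gene_1_symbol(5end_fusion_partner)\t"
    "Gene_2_symbol(3end_fusion_partner)\t"
    "Spanning_pairs\tSpanning_unique_reads"
)
_CICERO_HEADER = "gene_a\tgene_b\treadsA\treadsB\trating"

_DECOY_PAIRS = [
    ("AC01234.1", "RPL13"), ("GAPDH", "ACTB"), ("HLA-A", "HLA-B"),
    ("RPS19", "MALAT1"), ("EEF1A1", "FTL"), ("IGH", "RPL10"),
]
_DECOY_SNP_GENES = ["G00010", "G00020", "G00030", "G00040"]


def generate_vcf_and_fusion_files(
    record: TruthRecord,
    out_dir: str | Path,
    rng_seed: int = 0,
    *,
    baf_snps_per_chrom: int = 15,
    gene_chrom: pd.Series | None = None,
) -> dict[str, Path]:
    """Write a per-sample VCF and both fusion-table dialects.

    The VCF carries the truth sentinel mutation (gene + protein-change
    annotation, allele depths) plus decoy common SNPs annotated with
    population allele frequency >= 1%; heterozygous-range common SNPs are
    emitted on every chromosome with allele fractions consistent with the
    truth copy profile, so allele-imbalance scoring can be exercised.  The
    fusion tables carry the truth fusion plus decoy false-positive rows.
    """
    rng = np.random.default_rng(rng_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = record.sample_id

    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">',
        '##INFO=<ID=POPAF,Number=1,Type=Float,Description="Population allele frequency">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    lines += [f"##contig=<ID={c}>" for c in VALID_CHROMS]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sid
    )

    def vcf_row(chrom, pos, info, ad):
        ref, alt = "A", "G"
        return (
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t99\tPASS\t{info}\t"
            f"GT:AD\t0/1:{ad[0]},{ad[1]}"
        )

    if record.mutation is not None:
        gene, pchange = record.mutation
        chrom = NAMED_GENES.get(gene, "1")
        depth = int(rng.integers(40, 90))
        alt = int(rng.binomial(depth, 0.45))
        lines.append(
            vcf_row(
                chrom, int(rng.integers(1_000_000, 5_000_000)),
                f"GENE={gene};PCHANGE={pchange};POPAF=0.0001",
                (depth - alt, alt),
            )
        )
    # decoy rare variants in uninteresting genes (survive the AF filter)
    for g in _DECOY_SNP_GENES[:2]:
        depth = int(rng.integers(30, 60))
        alt = int(rng.binomial(depth, 0.5))
        lines.append(
            vcf_row(
                "2", int(rng.integers(1_000_000, 9_000_000)),
                f"GENE={g};PCHANGE=A100T;POPAF=0.0005",
                (depth - alt, alt),
            )
        )
    # common SNPs: population AF >= 1%, allele fractions follow copy state
    for chrom in VALID_CHROMS:
        copies = record.chrom_profile.get(chrom, 2)
        for k in range(baf_snps_per_chrom):
            depth = int(rng.integers(40, 120))
            if copies == 2:
                p = 0.5
            elif copies == 1:
                p = 0.97  # LOH: effectively homozygous
            else:
                p = rng.choice([1.0 / copies, (copies - 1.0) / copies])
            alt = int(rng.binomial(depth, p))
            af = round(float(rng.uniform(0.01, 0.5)), 4)
            lines.append(
                vcf_row(
                    chrom, 10_000_000 + k * 1000,
                    f"GENE=G{k:05d};PCHANGE=.;POPAF={af}",
                    (depth - alt, alt),
                )
            )
    vcf_path = out / f"{sid}.vcf"
    vcf_path.write_text("\n".join(lines) + "\n")

    fc_rows, ci_rows = [], []
    if record.fusion is not None:
        g5, g3 = record.fusion
        reads = int(rng.integers(8, 60))
        fc_rows.append(f"{g5}\t{g3}\t{reads}\t{reads // 2 + 1}")
        ci_rows.append(f"{g5}\t{g3}\t{reads}\t{reads - 2}\tHQ")
    for g5, g3 in _DECOY_PAIRS[: int(rng.integers(3, len(_DECOY_PAIRS)))]:
        fc_rows.append(f"{g5}\t{g3}\t{int(rng.integers(1, 4))}\t1")
        ci_rows.append(f"{g3}\t{g5}\t{int(rng.integers(1, 4))}\t1\tLQ")
    fc_path = out / f"{sid}.fusioncatcher.tsv"
    fc_path.write_text(_FC_HEADER + "\n" + "\n".join(fc_rows) + ("\n" if fc_rows else ""))
    ci_path = out / f"{sid}.cicero.tsv"
    ci_path.write_text(_CICERO_HEADER + "\n" + "\n".join(ci_rows) + ("\n" if ci_rows else ""))
    return {"vcf": vcf_path, "fusioncatcher": fc_path, "cicero": ci_path}
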