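"""Fusion-table and VCF parsing, sentinel matching, and expression
validation of genetic lesions.

Fusion callers report dozens to hundreds of candidate fusions per sample,
most of them false positives; this module replaces manual curation with a
catalog filter plus a minimum-read-support threshold.  The sentinel catalog
ships as an editable, versioned YAML file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .containers import FusionCall, LesionEvidence, MatchedLesion, MutationCall

log = logging.getLogger(__name__)

#: integration-table subtype -> GEP class used by the expression models
SUBTYPE_GEP_CLASS = {
    "ETV6::RUNX1": "ETV6::RUNX1",
    "ETV6::RUNX1-like": "ETV6::RUNX1",
    "KMT2A": "KMT2A",
    "KMT2A-like": "KMT2A",
    "TCF3::PBX1": "TCF3::PBX1",
    "DUX4": "DUX4",
    "MEF2D": "MEF2D",
    "ZNF384": "ZNF384",
    "ZNF384-like": "ZNF384",
    "BCL2/MYC": "BCL2/MYC",
    "HLF": "HLF",
    "NUTM1": "NUTM1",
    "CDX2/UBTF": "CDX2/UBTF",
    "PAX5::ETV6": "PAX5::ETV6",
    "PAX5 P80R": "PAX5 P80R",
    "PAX5alt": "PAX5alt",
    "IKZF1 N159Y": "IKZF1 N159Y",
    "Ph": "Ph/Ph-like",
    "Ph-like": "Ph/Ph-like",
    "CRLF2-r": "Ph/Ph-like",
    "Hyperdiploid": "Hyperdiploid",
    "Low hyperdiploid": "Hyperdiploid",
    "Near haploid": "Hyperdiploid",
    "Low hypodiploid": "Low hypodiploid",
    "iAMP21": "iAMP21",
    "ZEB2/CEBP": "ZEB2/CEBP",
}


@dataclass
class SentinelCatalog:
    version: int
    defining_fusion_pairs: dict[frozenset, str]
    defining_fusion_genes: dict[str, str]
    crlf2_genes: set[str]
    kinase_fusion_genes: set[str]
    sentinel_mutations: dict[tuple[str, str], str]
    pax5alt_mutation_genes: set[str]
    pax5alt_fusion_genes: set[str]
    reportable_hotspot_genes: set[str]
    expression_coupled: dict[str, str]


def load_catalog(path: str | Path | None = None) -> SentinelCatalog:
    """Load the sentinel catalog (the shipped one by default)."""
    if path is None:
        text = (
            resources.files("leukotype") / "data" / "sentinel_catalog.yaml"
        ).read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    pairs = {
        frozenset(k.split("::")): v
        for k, v in raw["defining_fusion_pairs"].items()
    }
    muts = {
        (m["gene"].upper(), m["protein_change"].upper()): m["subtype"]
        for m in raw["sentinel_mutations"]
    }
    return SentinelCatalog(
        version=raw["version"],
        defining_fusion_pairs=pairs,
        defining_fusion_genes={
            k.upper(): v for k, v in raw["defining_fusion_genes"].items()
        },
        crlf2_genes={g.upper() for g in raw["crlf2_genes"]},
        kinase_fusion_genes={g.upper() for g in raw["kinase_fusion_genes"]},
        sentinel_mutations=muts,
        pax5alt_mutation_genes={g.upper() for g in raw["pax5alt_mutation_genes"]},
        pax5alt_fusion_genes={g.upper() for g in raw["pax5alt_fusion_genes"]},
        reportable_hotspot_genes={
            g.upper() for g in raw["reportable_hotspot_genes"]
        },
        expression_coupled=raw["expression_coupled"],
    )


# --------------------------------------------------------------------------
# fusion parsing

_FC_COLS = {
    "5p": "Gene_1_symbol(5end_fusion_partner)",
    "3p": "Gene_2_symbol(3end_fusion_partner)",
    "reads": "Spanning_unique_reads",
}
_CICERO_COLS = {"5p": "gene_a", "3p": "gene_b", "reads": "readsA"}


def _detect_dialect(columns: list[str]) -> str:
    if _FC_COLS["5p"] in columns:
        return "fusioncatcher-style"
    if _CICERO_COLS["5p"] in columns:
        return "cicero-style"
    raise ValueError(
        "unknown fusion table header; expected columns "
        f"{_FC_COLS['5p']!r}/{_FC_COLS['3p']!r} (FusionCatcher-style) or "
        f"{_CICERO_COLS['5p']!r}/{_CICERO_COLS['3p']!r} (CICERO-style)"
    )


def parse_fusion_tables(
    paths: list[str | Path],
    dialect: str = "auto",
    *,
    min_reads: int = 0,
) -> list[FusionCall]:
    """Parse fusion tables, auto-detecting dialect from the header.

    Duplicate gene pairs (either orientation, across callers) are merged
    keeping the maximum read support; pairs seen by both callers are
    re-flagged ``dual-caller``.  Rows below ``min_reads`` are filtered
    (logged).
    """
    calls: list[FusionCall] = []
    for path in paths:
        table = pd.read_csv(path, sep="\t")
        d = dialect if dialect != "auto" else _detect_dialect(list(table.columns))
        cols = _FC_COLS if d == "fusioncatcher-style" else _CICERO_COLS
        for i, row in table.iterrows():
            reads = int(row.get(cols["reads"], 0) or 0)
            call = FusionCall(
                str(row[cols["5p"]]), str(row[cols["3p"]]), d, reads, raw_row=i
            )
            if reads < min_reads:
                log.info("filtered %s (%d < %d reads)", call, reads, min_reads)
                continue
            calls.append(call)

    merged: dict[frozenset, FusionCall] = {}
    for call in calls:
        key = call.unordered
        if key not in merged:
            merged[key] = call
            continue
        prev = merged[key]
        caller = (
            prev.caller
            if prev.caller == call.caller
            else "dual-caller"
        )
        best = prev if prev.supporting_reads >= call.supporting_reads else call
        log.info("merged duplicate fusion %s (callers: %s)", call, caller)
        merged[key] = FusionCall(
            best.gene5p, best.gene3p, caller, best.supporting_reads, best.raw_row
        )
    return list(merged.values())


# --------------------------------------------------------------------------
# VCF parsing

def _variant_to_call(v, sample_idx: int = 0) -> MutationCall:
    gene = str(v.INFO.get("GENE") or "")
    pchange = str(v.INFO.get("PCHANGE") or "")
    popaf = v.INFO.get("POPAF")
    annotated = bool(gene)
    ad = None
    try:
        depths = v.format("AD")
        if depths is not None:
            ad = (int(depths[sample_idx][0]), int(depths[sample_idx][1]))
    except Exception:  # pragma: no cover - malformed FORMAT
        ad = None
    return MutationCall(
        gene=gene or "UNKNOWN",
        protein_change=pchange.replace("p.", "").upper(),
        chrom=str(v.CHROM),
        pos=int(v.POS),
        ref=str(v.REF),
        alt=str(v.ALT[0]) if v.ALT else "",
        # cyvcf2 hands back float32: round to the printed precision so the
        # inclusive >= 1% boundary behaves as written in the VCF
        population_af=float(f"{float(popaf):.6g}") if popaf is not None else None,
        allele_depths=ad,
        annotated=annotated,
    )


def parse_vcf_variants(
    path: str | Path, af_threshold: float = 0.01
) -> list[MutationCall]:
    """Parse a VCF and drop common SNPs (population AF >= threshold).

    Variants without gene/protein-change annotation are kept but flagged
    unannotatable; variants without a population AF annotation are kept.
    """
    from cyvcf2 import VCF

    kept: list[MutationCall] = []
    removed = 0
    for v in VCF(str(path)):
        call = _variant_to_call(v)
        if call.population_af is not None and call.population_af >= af_threshold:
            removed += 1
            continue
        kept.append(call)
    if removed:
        log.info("removed %d common SNPs (population AF >= %g)", removed, af_threshold)
    return kept


def parse_vcf_for_baf(path: str | Path) -> list[MutationCall]:
    """Parse all VCF records with allele depths, including common SNPs.

    Common heterozygous SNPs are exactly the informative sites for
    allele-imbalance scoring, so this path applies no frequency filter.
    """
    from cyvcf2 import VCF

    return [
        c
        for c in (_variant_to_call(v) for v in VCF(str(path)))
        if c.allele_depths is not None
    ]


# --------------------------------------------------------------------------
# sentinel matching

def match_sentinels(
    fusions: list[FusionCall],
    mutations: list[MutationCall],
    catalog: SentinelCatalog | None = None,
) -> LesionEvidence:
    """Match lesions against the sentinel catalog.

    Exact-pair fusions are matched first, then single-gene rearrangement
    classes, then CRLF2/kinase-class evidence and PAX5 fusions.  Unmatched
    lesions are retained as "other"; the operation is idempotent and
    independent of input order.
    """
    cat = catalog or load_catalog()
    ev = LesionEvidence()
    for f in sorted(fusions, key=lambda x: (x.gene5p, x.gene3p)):
        if f.unordered in cat.defining_fusion_pairs:
            ev.sentinel_fusions.append(
                MatchedLesion(f, cat.defining_fusion_pairs[f.unordered])
            )
            continue
        gene_hit = next(
            (g for g in (f.gene5p, f.gene3p) if g in cat.defining_fusion_genes),
            None,
        )
        if gene_hit is not None:
            ev.sentinel_fusions.append(
                MatchedLesion(f, cat.defining_fusion_genes[gene_hit])
            )
            continue
        if f.unordered & cat.crlf2_genes:
            ev.sentinel_fusions.append(MatchedLesion(f, "CRLF2-r", kinase_class=True))
            continue
        if f.unordered & cat.kinase_fusion_genes:
            ev.sentinel_fusions.append(MatchedLesion(f, None, kinase_class=True))
            continue
        if f.unordered & cat.pax5alt_fusion_genes:
            ev.sentinel_fusions.append(MatchedLesion(f, "PAX5alt"))
            continue
        ev.other_fusions.append(f)

    for m in sorted(mutations, key=lambda x: (x.gene, x.protein_change)):
        key = (m.gene, m.protein_change.upper())
        if key in cat.sentinel_mutations:
            ev.sentinel_mutations.append(
                MatchedLesion(m, cat.sentinel_mutations[key])
            )
        elif (
            m.gene in cat.pax5alt_mutation_genes
            and m.protein_change not in ("", ".")
        ):
            ev.sentinel_mutations.append(MatchedLesion(m, "PAX5alt"))
        elif m.gene in cat.reportable_hotspot_genes:
            ev.reportable_mutations.append(m)
        else:
            ev.other_mutations.append(m)
    return ev


# --------------------------------------------------------------------------
# expression validation

def gep_validate_lesions(
    evidence: LesionEvidence,
    sample_gep: pd.Series,
    reference_values: pd.DataFrame,
    reference_labels: pd.Series,
    catalog: SentinelCatalog | None = None,
    *,
    percentile: float = 95.0,
) -> LesionEvidence:
    """Fill per-lesion GEP-consistency verdicts.

    For expression-coupled lesions the verdict is ``consistent`` iff the
    sample's expression of the coupled gene exceeds the given percentile of
    the subtype-negative reference samples (reference samples not belonging
    to the lesion's GEP class).  All other lesions stay ``untested``.
    """
    cat = catalog or load_catalog()
    for matched in evidence.sentinel_fusions:
        subtype = matched.implied_subtype
        gene = cat.expression_coupled.get(subtype or "")
        if gene is None:
            continue
        if gene not in sample_gep.index or gene not in reference_values.index:
            log.warning("gene %s absent from expression matrix; untested", gene)
            continue
        gep_class = SUBTYPE_GEP_CLASS.get(subtype, subtype)
        negative = reference_labels[reference_labels != gep_class].index
        cutoff = float(
            reference_values.loc[gene, negative].quantile(percentile / 100.0)
        )
        matched.gep_consistency = (
            "consistent" if float(sample_gep.loc[gene]) > cutoff else "inconsistent"
        )
    return evidence


def evidence_to_frame(evidence: LesionEvidence) -> pd.DataFrame:
    """Export all matched evidence as a flat table."""
    rows = []
    for m in evidence.sentinel_fusions:
        rows.append(
            {
                "kind": "fusion",
                "lesion": str(m.lesion),
                "implied_subtype": m.implied_subtype,
                "kinase_class": m.kinase_class,
                "gep_consistency": m.gep_consistency,
            }
        )
    for m in evidence.sentinel_mutations:
        rows.append(
            {
                "kind": "mutation",
                "lesion": f"{m.lesion.gene} {m.lesion.protein_change}",
                "implied_subtype": m.implied_subtype,
                "kinase_class": False,
                "gep_consistency": m.gep_consistency,
            }
        )
    for mut in evidence.reportable_mutations:
        rows.append(
            {
                "kind": "hotspot-context",
                "lesion": f"{mut.gene} {mut.protein_change}",
                "implied_subtype": None,
                "kinase_class": False,
                "gep_consistency": "untested",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["kind", "lesion", "implied_subtype", "kinase_class", "gep_consistency"],
    )
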