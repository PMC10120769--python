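"""The integration rule engine: definitive subtype from lesions, GEP
prediction and karyotype.

Genetic lesions determine the primary subtypes; GEP guides the secondary
decisions.  Within lesions, fusions outrank karyotype (a BCR::ABL1 fusion
beats a hyperdiploid chromosome count), and BCR::ABL1 outranks everything:
no combination of other evidence may turn a BCR::ABL1-positive sample into
a non-Ph call.  The rule order is encoded as data so the subtype
vocabulary can track future taxonomies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .containers import ChromCNVProfile, GEPPrediction, IntegratedCall, LesionEvidence
from .lesions import SUBTYPE_GEP_CLASS

#: canonical subtypes fired directly by a defining fusion
FUSION_DEFINED = {
    "Ph", "ETV6::RUNX1", "KMT2A", "TCF3::PBX1", "MEF2D", "ZNF384", "DUX4",
    "HLF", "NUTM1", "BCL2/MYC", "CDX2/UBTF", "PAX5::ETV6",
}
MUTATION_DEFINED = {"PAX5 P80R", "IKZF1 N159Y", "ZEB2/CEBP"}
ANEUPLOID_SUBTYPES = {
    "Near haploid", "Low hypodiploid", "Low hyperdiploid", "Hyperdiploid",
}
PHENOCOPY = {
    "ETV6::RUNX1": "ETV6::RUNX1-like",
    "KMT2A": "KMT2A-like",
    "ZNF384": "ZNF384-like",
}

FINAL_SUBTYPES = (
    sorted(FUSION_DEFINED | MUTATION_DEFINED | ANEUPLOID_SUBTYPES)
    + sorted(PHENOCOPY.values())
    + ["Ph-like", "CRLF2(non-Ph-like)", "PAX5alt", "iAMP21", "Ph/Ph-like",
       "unclassified"]
)


@dataclass
class _Ctx:
    sample_id: str
    gep: GEPPrediction
    lesions: LesionEvidence
    cnv: ChromCNVProfile | None
    karyotype_class: str  # clinical override if given, else CNV-derived
    karyotype_is_clinical: bool
    trail: list


def _supported_fusions(ctx: _Ctx, subtype: str | None = None):
    """Sentinel fusions not invalidated by expression (inconsistent lesions
    are down-weighted: they never fire a rule, only appear in the trail)."""
    out = []
    for m in ctx.lesions.sentinel_fusions:
        if subtype is not None and m.implied_subtype != subtype:
            continue
        if m.gep_consistency == "inconsistent":
            ctx.trail.append(
                (f"{m.lesion} ({m.implied_subtype}; expression-inconsistent)",
                 "down-weighted")
            )
            continue
        out.append(m)
    return out


def _gep_label(ctx: _Ctx) -> str:
    return ctx.gep.unified_label


def _gep_matches(ctx: _Ctx, subtype: str) -> bool:
    return _gep_label(ctx) == SUBTYPE_GEP_CLASS.get(subtype, subtype)


def _lesion_note(ctx: _Ctx, subtype: str) -> str:
    """Confidence note for a lesion-driven call: concordant if the GEP
    class agrees, lesion-over-GEP only on an actual conflict, lesion-only
    when no GEP call was reported at all."""
    if _gep_matches(ctx, subtype):
        return "lesion+GEP concordant"
    if not ctx.gep.reported:
        return "lesion-only"
    return "lesion-over-GEP"


# ---- rules, in precedence order ------------------------------------------

def _rule_bcr_abl1(ctx: _Ctx):
    for m in ctx.lesions.sentinel_fusions:
        if m.lesion.unordered == frozenset({"BCR", "ABL1"}):
            ctx.trail.append((str(m.lesion), "defining fusion"))
            return "Ph", _lesion_note(ctx, "Ph")
    return None


def _rule_defining_fusion(ctx: _Ctx):
    hits = [
        m
        for m in _supported_fusions(ctx)
        if m.implied_subtype in FUSION_DEFINED
    ]
    if not hits:
        return None
    concordant = [m for m in hits if _gep_matches(ctx, m.implied_subtype)]
    chosen = concordant[0] if concordant else hits[0]
    for m in hits:
        ctx.trail.append((str(m.lesion), "defining fusion"))
    if len({m.implied_subtype for m in hits}) > 1:
        ctx.trail.append(
            ("multiple defining fusions; highest-precedence evidence used",
             "conflict"),
        )
    return chosen.implied_subtype, _lesion_note(ctx, chosen.implied_subtype)


def _rule_sentinel_mutation(ctx: _Ctx):
    for m in ctx.lesions.sentinel_mutations:
        sub = m.implied_subtype
        if sub not in MUTATION_DEFINED:
            continue
        # ZEB2/CEBP is provisional and requires a concordant GEP
        if sub == "ZEB2/CEBP" and not _gep_matches(ctx, sub):
            ctx.trail.append(
                (f"{m.lesion.gene} {m.lesion.protein_change}",
                 "sentinel mutation (GEP-discordant; not fired)")
            )
            continue
        ctx.trail.append(
            (f"{m.lesion.gene} {m.lesion.protein_change}", "sentinel mutation")
        )
        return sub, _lesion_note(ctx, sub)
    return None


def _rule_ph_like(ctx: _Ctx):
    if _gep_label(ctx) != "Ph/Ph-like":
        return None
    kinase = [
        m for m in _supported_fusions(ctx)
        if m.kinase_class and m.lesion.unordered != frozenset({"BCR", "ABL1"})
    ]
    if not kinase:
        return None
    for m in kinase:
        ctx.trail.append((str(m.lesion), "kinase-activating lesion"))
    ctx.trail.append(("Ph/Ph-like GEP without BCR::ABL1", "GEP"))
    return "Ph-like", "lesion+GEP concordant"


def _rule_crlf2_non_ph_like(ctx: _Ctx):
    if _gep_label(ctx) == "Ph/Ph-like":
        return None
    hits = _supported_fusions(ctx, "CRLF2-r")
    if not hits:
        return None
    for m in hits:
        ctx.trail.append((str(m.lesion), "CRLF2 rearrangement"))
    ctx.trail.append(("GEP not Ph/Ph-like", "GEP"))
    note = "lesion-over-GEP" if ctx.gep.reported else "lesion-only"
    return "CRLF2(non-Ph-like)", note


def _rule_karyotype(ctx: _Ctx):
    if ctx.karyotype_class not in ANEUPLOID_SUBTYPES:
        return None
    # The aneuploid rows of the rule table pair chromosome-number ranges
    # with the Hyperdiploid / Low hypodiploid GEP classes (near haploid
    # famously mimics hyperdiploid expression).  An RNA-derived count is
    # noisy enough that it must not override a confidently reported,
    # unrelated GEP class; a clinical karyotype always wins.
    gep_compatible = (not ctx.gep.reported) or _gep_label(ctx) in (
        "Hyperdiploid",
        "Low hypodiploid",
    )
    if not (ctx.karyotype_is_clinical or gep_compatible):
        ctx.trail.append(
            (
                f"karyotype class {ctx.karyotype_class} (RNA-derived CNV; "
                f"not used against discordant GEP)",
                "context",
            )
        )
        return None
    source = (
        "clinical karyotype" if ctx.karyotype_is_clinical else "RNA-derived CNV"
    )
    ctx.trail.append(
        (f"karyotype class {ctx.karyotype_class} ({source})", "aneuploidy")
    )
    return ctx.karyotype_class, _lesion_note(ctx, ctx.karyotype_class)


def _rule_pax5alt(ctx: _Ctx):
    if _gep_label(ctx) != "PAX5alt":
        return None
    support = [
        str(m.lesion)
        for m in _supported_fusions(ctx, "PAX5alt")
    ] + [
        f"{m.lesion.gene} {m.lesion.protein_change}"
        for m in ctx.lesions.sentinel_mutations
        if m.implied_subtype == "PAX5alt"
    ]
    if ctx.lesions.pax5_iamp:
        support.append("PAX5 intragenic amplification (user-supplied)")
    if not support:
        return None
    for s in support:
        ctx.trail.append((s, "PAX5 alteration"))
    return "PAX5alt", "lesion+GEP concordant"


def _rule_iamp21(ctx: _Ctx):
    if (
        ctx.cnv is not None
        and ctx.cnv.iamp21_flag
        and _gep_label(ctx) == "iAMP21"
    ):
        ctx.trail.append(("segmental chr21 amplification", "CNV"))
        ctx.trail.append(("iAMP21 GEP", "GEP"))
        return "iAMP21", "lesion+GEP concordant"
    return None


def _rule_phenocopy(ctx: _Ctx):
    label = _gep_label(ctx)
    if label not in PHENOCOPY or not ctx.gep.reported:
        return None
    if any(
        m.implied_subtype == label for m in ctx.lesions.sentinel_fusions
    ):
        return None  # defining lesion present; earlier rules handle it
    ctx.trail.append((f"{label} GEP without the defining fusion", "GEP"))
    return PHENOCOPY[label], "GEP-only"


def _rule_gep_only(ctx: _Ctx):
    if not ctx.gep.reported:
        return None
    label = _gep_label(ctx)
    ctx.trail.append(
        (f"GEP prediction {label} ({ctx.gep.flag})", "GEP")
    )
    return label, "GEP-only"


RULES: list[tuple[str, Callable]] = [
    ("R1-bcr-abl1", _rule_bcr_abl1),
    ("R2-defining-fusion", _rule_defining_fusion),
    ("R3-sentinel-mutation", _rule_sentinel_mutation),
    ("R4-ph-like", _rule_ph_like),
    ("R5-crlf2-non-ph-like", _rule_crlf2_non_ph_like),
    ("R6-karyotype", _rule_karyotype),
    ("R7-pax5alt", _rule_pax5alt),
    ("R8-iamp21", _rule_iamp21),
    ("R9-phenocopy", _rule_phenocopy),
    ("R10-gep-only", _rule_gep_only),
]


def classify_integrative(
    gep_call: GEPPrediction,
    lesions: LesionEvidence | None = None,
    cnv: ChromCNVProfile | None = None,
    karyotype_override: str | None = None,
    sample_id: str = "sample",
) -> IntegratedCall:
    """Evaluate the rule table in precedence order (pure function).

    ``karyotype_override`` is a clinical karyotype class that, when given,
    replaces the CNV-derived one.
    """
    k_class = karyotype_override or (
        cnv.karyotype_class if cnv is not None else "none"
    )
    ctx = _Ctx(
        sample_id=sample_id,
        gep=gep_call,
        lesions=lesions or LesionEvidence(),
        cnv=cnv,
        karyotype_class=k_class,
        karyotype_is_clinical=karyotype_override is not None,
        trail=[],
    )
    for rule_id, rule in RULES:
        result = rule(ctx)
        if result is not None:
            subtype, note = result
            return IntegratedCall(
                sample_id=sample_id,
                final_subtype=subtype,
                rule_id=rule_id,
                evidence_trail=list(dict.fromkeys(ctx.trail)),
                confidence_note=note,
                provisional=(subtype == "ZEB2/CEBP"),
            )
    return IntegratedCall(
        sample_id=sample_id,
        final_subtype="unclassified",
        rule_id="R11-unclassified",
        evidence_trail=[],
        confidence_note="insufficient",
    )


def explain_call(
    call: IntegratedCall,
    gep: GEPPrediction | None = None,
    cnv: ChromCNVProfile | None = None,
) -> str:
    """Deterministic human-readable report of a call and its evidence."""
    lines = [
        f"Sample: {call.sample_id}",
        f"Final subtype: {call.final_subtype}"
        + (" (provisional)" if call.provisional else ""),
        f"Rule fired: {call.rule_id}",
        f"Confidence note: {call.confidence_note}",
        "",
        "Evidence:",
    ]
    if call.evidence_trail:
        lines += [f"  - {item} [{role}]" for item, role in call.evidence_trail]
    else:
        lines += [
            "  - none: no reported GEP call, no sentinel lesion, "
            "no informative karyotype"
        ]
    if gep is not None:
        lines.append("")
        lines.append("GEP models:")
        for name, pred in (("SVM", gep.svm), ("PhenoGraph", gep.phenograph)):
            if pred is None:
                lines.append(f"  {name}: not run")
            else:
                state = "reported" if pred.reported else "unclassified"
                lines.append(
                    f"  {name}: {pred.modal_label} "
                    f"(confidence {pred.confidence:.3f}, {state})"
                )
    if cnv is not None:
        lines.append("")
        lines.append(
            f"CNV: {cnv.est_chrom_number} chromosomes "
            f"({cnv.karyotype_class}); iAMP21="
            + ("n/a" if cnv.iamp21_flag is None else str(cnv.iamp21_flag))
            + f"; inferred sex {cnv.inferred_sex}"
        )
    return "\n".join(lines)
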