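"""Shared fixtures: small synthetic cohorts and fitted reference models.

Everything is generated at test time from fixed seeds; no data files ship
with the test suite.
"""

from __future__ import annotations

import pytest

from leukotype import classifier, featsel, normalize, synthetic
from leukotype.containers import GEPMatrix


@pytest.fixture(scope="session")
def distinct8_cohort():
    """8 highly distinct classes x 30 samples: the separable reference."""
    specs = synthetic.make_distinct_specs(8)
    cfg = synthetic.CohortConfig(
        specs, samples_per_subtype=30, n_genes=1500, rng_seed=42
    )
    counts, truth = synthetic.generate_bulk_cohort(cfg)
    return counts, truth


@pytest.fixture(scope="session")
def distinct8_gep(distinct8_cohort):
    counts, truth = distinct8_cohort
    return normalize.vst_transform(counts), truth


@pytest.fixture(scope="session")
def fitted_model(distinct8_cohort, distinct8_gep):
    """Both GEP models fitted on the separable reference (top 300 genes)."""
    counts, truth = distinct8_cohort
    gep, _ = distinct8_gep
    ranking = featsel.quick_importance_ranking(
        gep, truth.labels, counts.coding, alpha=None
    )
    top = classifier.FeatureRanking(ranking.table.iloc[:300])
    ref = GEPMatrix(gep.values.loc[top.gene_ids], gep.provenance)
    return classifier.fit_svm_model(ref, truth.labels, top, seed=7)


@pytest.fixture(scope="session")
def full_catalog_cohort():
    """All default subtype specs x 5 samples, for lesion/CNV/rule tests."""
    specs = synthetic.default_subtype_specs()
    cfg = synthetic.CohortConfig(
        specs, samples_per_subtype=5, n_genes=2600, rng_seed=3
    )
    counts, truth = synthetic.generate_bulk_cohort(cfg)
    gep = normalize.vst_transform(counts)
    return counts, truth, gep


# --------------------------------------------------------------------------
# rule-table scenario builders, shared by the rule-engine and acceptance
# suites

def make_gep_prediction(label: str | None, rounds: int = 11):
    """A unified GEP call: both models unanimously report ``label``, or an
    unclassified call when label is None."""
    from leukotype.classifier import _summarize_votes, unify_gep_call

    if label is None:
        spread = [f"c{i}" for i in range(rounds)]
        p = _summarize_votes(spread)
        return unify_gep_call(p, p)
    p = _summarize_votes([label] * rounds)
    return unify_gep_call(p, p)


def make_evidence(fusion=None, mutation=None, pax5_iamp=False):
    from leukotype import lesions
    from leukotype.containers import FusionCall, MutationCall

    fusions = (
        [FusionCall(fusion[0], fusion[1], "fusioncatcher-style", 20)]
        if fusion
        else []
    )
    muts = [MutationCall(mutation[0], mutation[1])] if mutation else []
    ev = lesions.match_sentinels(fusions, muts)
    ev.pax5_iamp = pax5_iamp
    return ev


def make_cnv_profile(est_chrom_number=46, iamp21=False):
    from leukotype import cnv as cnv_mod
    from leukotype.containers import ChromCNVProfile

    copies = {str(c): 2 for c in range(1, 23)}
    copies["X"], copies["Y"] = 1, 1
    delta = est_chrom_number - 46
    chroms = [str(c) for c in range(1, 23)]
    i = 0
    while delta != 0:
        c = chroms[i % 22]
        if delta > 0 and copies[c] < 4:
            copies[c] += 1
            delta -= 1
        elif delta < 0 and copies[c] > 1:
            copies[c] -= 1
            delta += 1
        i += 1
    return ChromCNVProfile(
        copies=copies,
        ratios={c: 0.0 for c in copies},
        baf_scores={},
        unreliable=set(),
        est_chrom_number=est_chrom_number,
        karyotype_class=cnv_mod.karyotype_class_of(est_chrom_number),
        iamp21_flag=iamp21,
        inferred_sex="male",
    )


#: every row of the integration rule table:
#: (row id, fusion, mutation, GEP label, chromosome number, iAMP21, expected)
RULE_TABLE_ROWS = [
    ("bcl2-myc", ("IGH", "MYC"), None, "BCL2/MYC", None, False, "BCL2/MYC"),
    ("cdx2-ubtf", ("UBTF", "ATXN7L3"), None, "CDX2/UBTF", None, False, "CDX2/UBTF"),
    ("crlf2-non-ph", ("P2RY8", "CRLF2"), None, None, None, False, "CRLF2(non-Ph-like)"),
    ("dux4", ("IGH", "DUX4"), None, "DUX4", None, False, "DUX4"),
    ("etv6-runx1", ("ETV6", "RUNX1"), None, "ETV6::RUNX1", None, False, "ETV6::RUNX1"),
    ("etv6-runx1-like", None, None, "ETV6::RUNX1", None, False, "ETV6::RUNX1-like"),
    ("hlf", ("TCF3", "HLF"), None, "HLF", None, False, "HLF"),
    ("hyperdiploid", None, None, "Hyperdiploid", 54, False, "Hyperdiploid"),
    ("iamp21", None, None, "iAMP21", 46, True, "iAMP21"),
    ("ikzf1-n159y", None, ("IKZF1", "N159Y"), "IKZF1 N159Y", None, False, "IKZF1 N159Y"),
    ("kmt2a", ("KMT2A", "AFF1"), None, "KMT2A", None, False, "KMT2A"),
    ("kmt2a-like", None, None, "KMT2A", None, False, "KMT2A-like"),
    ("low-hyperdiploid", None, None, "Hyperdiploid", 48, False, "Low hyperdiploid"),
    ("low-hypodiploid", None, None, "Low hypodiploid", 35, False, "Low hypodiploid"),
    ("mef2d", ("MEF2D", "BCL9"), None, "MEF2D", None, False, "MEF2D"),
    ("near-haploid", None, None, "Hyperdiploid", 26, False, "Near haploid"),
    ("nutm1", ("ACIN1", "NUTM1"), None, "NUTM1", None, False, "NUTM1"),
    ("pax5-p80r", None, ("PAX5", "P80R"), "PAX5 P80R", None, False, "PAX5 P80R"),
    ("pax5-etv6", ("PAX5", "ETV6"), None, "PAX5::ETV6", None, False, "PAX5::ETV6"),
    ("pax5alt", ("PAX5", "NOL4L"), None, "PAX5alt", None, False, "PAX5alt"),
    ("ph", ("BCR", "ABL1"), None, "Ph/Ph-like", None, False, "Ph"),
    ("ph-like", ("EPOR", "JAK2"), None, "Ph/Ph-like", None, False, "Ph-like"),
    ("tcf3-pbx1", ("TCF3", "PBX1"), None, "TCF3::PBX1", None, False, "TCF3::PBX1"),
    ("znf384", ("EP300", "ZNF384"), None, "ZNF384", None, False, "ZNF384"),
    ("znf384-like", None, None, "ZNF384", None, False, "ZNF384-like"),
]


def run_rule_table_row(row):
    from leukotype import integrate

    _, fusion, mutation, gep_label, chrom_n, iamp21, expected = row
    gep = make_gep_prediction(gep_label)
    ev = make_evidence(fusion, mutation)
    profile = make_cnv_profile(chrom_n or 46, iamp21=iamp21)
    call = integrate.classify_integrative(gep, ev, profile)
    return call, expected
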