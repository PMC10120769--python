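"""Lesion parsing and sentinel matching: dialect detection, common-SNP
filtering, catalog mapping, and expression validation."""

import numpy as np
import pandas as pd
import pytest

from leukotype import lesions, synthetic
from leukotype.containers import FusionCall, MutationCall

FC_HEADER = (
    "Gene_1_symbol(5end_fusion_partner)\tGene_2_symbol(3end_fusion_partner)"
    "\tSpanning_pairs\tSpanning_unique_reads\n"
)
CICERO_HEADER = "gene_a\tgene_b\treadsA\treadsB\trating\n"


class TestFusionParsing:
    def test_fusioncatcher_row_normalizes_to_gene_pair(self, tmp_path):
        p = tmp_path / "fc.tsv"
        p.write_text(FC_HEADER + "BCR\tABL1\t20\t12\n")
        calls = lesions.parse_fusion_tables([p])
        assert len(calls) == 1
        assert calls[0].pair == ("BCR", "ABL1")
        assert calls[0].caller == "fusioncatcher-style"
        assert calls[0].supporting_reads == 12

    def test_empty_file_with_valid_header_yields_no_calls(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text(CICERO_HEADER)
        assert lesions.parse_fusion_tables([p]) == []

    def test_pair_reported_by_both_callers_merges_as_dual(self, tmp_path):
        fc = tmp_path / "fc.tsv"
        fc.write_text(FC_HEADER + "ETV6\tRUNX1\t9\t7\n")
        ci = tmp_path / "ci.tsv"
        ci.write_text(CICERO_HEADER + "RUNX1\tETV6\t11\t9\tHQ\n")
        calls = lesions.parse_fusion_tables([fc, ci])
        assert len(calls) == 1
        assert calls[0].caller == "dual-caller"
        assert calls[0].supporting_reads == 11  # max support kept

    def test_min_reads_filters_low_support_rows(self, tmp_path):
        p = tmp_path / "fc.tsv"
        p.write_text(FC_HEADER + "KMT2A\tAFF1\t2\t1\nBCR\tABL1\t20\t15\n")
        calls = lesions.parse_fusion_tables([p], min_reads=5)
        assert [c.pair for c in calls] == [("BCR", "ABL1")]

    def test_unknown_header_error_names_expected_columns(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("foo\tbar\n1\t2\n")
        with pytest.raises(ValueError, match="Gene_1_symbol"):
            lesions.parse_fusion_tables([p])


def write_vcf(path, rows):
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="g">',
        '##INFO=<ID=PCHANGE,Number=1,Type=String,Description="p">',
        '##INFO=<ID=POPAF,Number=1,Type=Float,Description="af">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">',
        "##contig=<ID=9>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS",
    ]
    path.write_text("\n".join(header + rows) + "\n")


class TestVCFParsing:
    def test_common_snp_at_and_above_threshold_is_removed(self, tmp_path):
        p = tmp_path / "v.vcf"
        write_vcf(p, [
            "9\t100\t.\tA\tG\t99\tPASS\tGENE=PAX5;PCHANGE=P80R;POPAF=0.0001\tGT:AD\t0/1:30,25",
            "9\t200\t.\tA\tG\t99\tPASS\tGENE=X1;PCHANGE=A1T;POPAF=0.05\tGT:AD\t0/1:30,25",
            "9\t300\t.\tA\tG\t99\tPASS\tGENE=X2;PCHANGE=A2T;POPAF=0.01\tGT:AD\t0/1:30,25",
        ])
        kept = lesions.parse_vcf_variants(p, af_threshold=0.01)
        assert [(m.gene, m.protein_change) for m in kept] == [("PAX5", "P80R")]

    def test_empty_vcf_yields_empty_list(self, tmp_path):
        p = tmp_path / "v.vcf"
        write_vcf(p, [])
        assert lesions.parse_vcf_variants(p) == []

    def test_unannotated_variant_kept_but_flagged(self, tmp_path):
        p = tmp_path / "v.vcf"
        write_vcf(p, ["9\t100\t.\tA\tG\t99\tPASS\t.\tGT:AD\t0/1:30,25"])
        kept = lesions.parse_vcf_variants(p)
        assert len(kept) == 1 and not kept[0].annotated

    def test_baf_parse_keeps_common_snps_with_depths(self, tmp_path):
        p = tmp_path / "v.vcf"
        write_vcf(p, [
            "9\t200\t.\tA\tG\t99\tPASS\tGENE=X1;PCHANGE=.;POPAF=0.4\tGT:AD\t0/1:30,30",
        ])
        calls = lesions.parse_vcf_for_baf(p)
        assert len(calls) == 1 and calls[0].vaf == pytest.approx(0.5)


def fus(g5, g3, reads=10):
    return FusionCall(g5, g3, "fusioncatcher-style", reads)


class TestSentinelMatching:
    def test_igh_crlf2_is_crlf2_rearrangement_with_kinase_evidence(self):
        ev = lesions.match_sentinels([fus("IGH", "CRLF2")], [])
        m = ev.sentinel_fusions[0]
        assert m.implied_subtype == "CRLF2-r" and m.kinase_class

    def test_pax5_p80r_mutation_implies_its_subtype(self):
        mut = MutationCall("PAX5", "P80R")
        ev = lesions.match_sentinels([], [mut])
        assert ev.sentinel_mutations[0].implied_subtype == "PAX5 P80R"

    def test_uncatalogued_fusion_stays_other(self):
        ev = lesions.match_sentinels([fus("AAA", "BBB")], [])
        assert not ev.sentinel_fusions
        assert [f.pair for f in ev.other_fusions] == [("AAA", "BBB")]

    def test_non_sentinel_pax5_mutation_counts_toward_pax5alt(self):
        ev = lesions.match_sentinels([], [MutationCall("PAX5", "R38H")])
        assert ev.sentinel_mutations[0].implied_subtype == "PAX5alt"

    def test_hotspot_genes_are_reportable_context_only(self):
        ev = lesions.match_sentinels([], [MutationCall("KRAS", "G12D")])
        assert not ev.sentinel_mutations
        assert ev.reportable_mutations[0].gene == "KRAS"

    def test_matching_is_order_independent_and_idempotent(self):
        fusions = [fus("BCR", "ABL1"), fus("IGH", "DUX4"), fus("AAA", "BBB")]
        muts = [MutationCall("IKZF1", "N159Y"), MutationCall("TP53", "R248Q")]
        e1 = lesions.match_sentinels(fusions, muts)
        e2 = lesions.match_sentinels(fusions[::-1], muts[::-1])
        key = lambda e: (
            [(str(m.lesion), m.implied_subtype) for m in e.sentinel_fusions],
            [(str(m.lesion.gene), m.implied_subtype) for m in e.sentinel_mutations],
        )
        assert key(e1) == key(e2)

    @pytest.mark.parametrize(
        "pair,subtype",
        [
            (("BCR", "ABL1"), "Ph"),
            (("ETV6", "RUNX1"), "ETV6::RUNX1"),
            (("KMT2A", "AFF1"), "KMT2A"),
            (("TCF3", "PBX1"), "TCF3::PBX1"),
            (("IGH", "DUX4"), "DUX4"),
            (("MEF2D", "BCL9"), "MEF2D"),
            (("EP300", "ZNF384"), "ZNF384"),
            (("IGH", "MYC"), "BCL2/MYC"),
            (("TCF3", "HLF"), "HLF"),
            (("ACIN1", "NUTM1"), "NUTM1"),
            (("UBTF", "ATXN7L3"), "CDX2/UBTF"),
            (("PAX5", "ETV6"), "PAX5::ETV6"),
        ],
    )
    def test_defining_fusions_map_to_their_subtypes(self, pair, subtype):
        ev = lesions.match_sentinels([fus(*pair)], [])
        assert ev.sentinel_fusions[0].implied_subtype == subtype


class TestRoundTrip:
    def test_generated_lesion_files_recover_the_truth_sentinels(
        self, tmp_path, full_catalog_cohort
    ):
        """Write VCF + both fusion dialects for one sample of every
        subtype, parse them back, and recover exactly the truth set."""
        _, truth, _ = full_catalog_cohort
        cat = lesions.load_catalog()
        seen = set()
        for rec in truth.records:
            if rec.subtype in seen:
                continue
            seen.add(rec.subtype)
            paths = synthetic.generate_vcf_and_fusion_files(rec, tmp_path, 5)
            fusions = lesions.parse_fusion_tables(
                [paths["fusioncatcher"], paths["cicero"]], min_reads=2
            )
            muts = lesions.parse_vcf_variants(paths["vcf"])
            ev = lesions.match_sentinels(fusions, muts, cat)
            got = {m.lesion.unordered for m in ev.sentinel_fusions}
            want = (
                {frozenset(g.upper() for g in rec.fusion)}
                if rec.fusion
                else set()
            )
            assert got == want, rec.subtype
            got_m = {
                (m.lesion.gene, m.lesion.protein_change)
                for m in ev.sentinel_mutations
            } | {(m.gene, m.protein_change) for m in ev.reportable_mutations}
            if rec.mutation:
                assert tuple(g.upper() for g in rec.mutation) in got_m


class TestGEPValidation:
    @pytest.fixture()
    def reference(self):
        rng = np.random.default_rng(0)
        genes = ["CRLF2", "DUX4", "OTHER"]
        values = pd.DataFrame(
            rng.normal(5, 1, size=(3, 40)),
            index=genes,
            columns=[f"r{i}" for i in range(40)],
        )
        labels = pd.Series(
            ["Ph/Ph-like"] * 5 + ["DUX4"] * 5 + ["KMT2A"] * 30,
            index=values.columns,
        )
        return values, labels

    def test_overexpressed_crlf2_marks_the_fusion_consistent(self, reference):
        values, labels = reference
        ev = lesions.match_sentinels([fus("IGH", "CRLF2")], [])
        sample = pd.Series({"CRLF2": 12.0, "DUX4": 5.0, "OTHER": 5.0})
        out = lesions.gep_validate_lesions(ev, sample, values, labels)
        assert out.sentinel_fusions[0].gep_consistency == "consistent"

    def test_median_crlf2_marks_the_fusion_inconsistent(self, reference):
        values, labels = reference
        ev = lesions.match_sentinels([fus("IGH", "CRLF2")], [])
        sample = pd.Series({"CRLF2": 5.0, "DUX4": 5.0, "OTHER": 5.0})
        out = lesions.gep_validate_lesions(ev, sample, values, labels)
        assert out.sentinel_fusions[0].gep_consistency == "inconsistent"

    def test_non_expression_coupled_fusion_stays_untested(self, reference):
        values, labels = reference
        ev = lesions.match_sentinels([fus("ETV6", "RUNX1")], [])
        sample = pd.Series({"CRLF2": 5.0, "DUX4": 5.0, "OTHER": 5.0})
        out = lesions.gep_validate_lesions(ev, sample, values, labels)
        assert out.sentinel_fusions[0].gep_consistency == "untested"
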