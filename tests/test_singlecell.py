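"""Single-cell contracts: QC filtering against a brute-force oracle,
reference annotation accuracy, and sample-level summarization."""

import gzip
import shutil

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from leukotype import classifier, deconv, featsel, normalize, singlecell, synthetic
from leukotype.containers import GEPMatrix

KMT2A_SPEC = next(
    s for s in synthetic.default_subtype_specs() if s.name == "KMT2A"
)
MIX = {"T": 0.5, "monocyte": 0.3, "NK": 0.2}


def make_sc(n_blasts=150, total=1000, seed=2, spec=KMT2A_SPEC):
    mat, bc, genes, truth = synthetic.generate_sc_matrix(
        spec, n_blasts, MIX, rng_seed=seed, n_cells_total=total
    )
    return singlecell.SCMatrix(mat, bc, genes), truth


@pytest.fixture(scope="module")
def subtype_model():
    """Bulk reference model over 8 distinct classes (includes KMT2A)."""
    specs = synthetic.make_distinct_specs(8)
    cfg = synthetic.CohortConfig(
        specs, samples_per_subtype=20, n_genes=1500, rng_seed=5
    )
    counts, truth = synthetic.generate_bulk_cohort(cfg)
    gep = normalize.vst_transform(counts)
    ranking = featsel.quick_importance_ranking(
        gep, truth.labels, counts.coding, alpha=None
    )
    top = classifier.FeatureRanking(ranking.table.iloc[:200])
    return classifier.fit_svm_model(
        GEPMatrix(gep.values.loc[top.gene_ids], gep.provenance),
        truth.labels, top, seed=1,
    )


def brute_force_qc(matrix, gene_ids, mito_frac):
    """Independent re-statement of the four QC rules."""
    dense = matrix.toarray()
    gene_keep = (dense > 0).sum(axis=0) >= 5
    dense2 = dense[:, gene_keep]
    genes_per_cell = (dense2 > 0).sum(axis=1)
    keep = genes_per_cell >= 200
    keep &= mito_frac < 0.10
    surv = genes_per_cell[keep]
    med = np.median(surv)
    mad = np.median(np.abs(surv - med))
    keep &= genes_per_cell <= med + 3 * mad
    return keep, gene_keep


class TestQCFilter:
    def test_filter_equals_brute_force_oracle(self):
        sc, _ = make_sc(seed=7)
        # plant violations: a sparse cell, a mito-heavy cell, an outlier
        dense = sc.matrix.toarray()
        dense[0] = 0
        dense[0, :100] = 1  # 100 expressed genes -> below the 200 floor
        mito_cols = [i for i, g in enumerate(sc.gene_ids) if g.startswith("MT-")]
        dense[1, mito_cols] = dense[1].sum()  # mito-dominated
        dense[2, :] += 1  # expressed-gene-count outlier
        sc2 = singlecell.SCMatrix(
            sparse.csr_matrix(dense), sc.barcodes, sc.gene_ids
        )
        filtered, report = singlecell.qc_filter(sc2)
        keep, gene_keep = brute_force_qc(
            sc2.matrix, sc2.gene_ids, sc2.mito_fraction.to_numpy()
        )
        assert set(filtered.barcodes) == set(sc2.barcodes[keep])
        assert report.n_removed_cells == int((~keep).sum())

    def test_cell_with_150_genes_is_removed(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(2.0, size=(60, 400))
        dense[0] = 0
        dense[0, :150] = 3
        sc = singlecell.SCMatrix(
            sparse.csr_matrix(dense),
            pd.Index([f"c{i}" for i in range(60)]),
            pd.Index([f"g{i}" for i in range(400)]),
        )
        filtered, _ = singlecell.qc_filter(sc)
        assert "c0" not in filtered.barcodes

    def test_cell_with_12_percent_mito_is_removed(self):
        rng = np.random.default_rng(1)
        dense = rng.poisson(3.0, size=(50, 400)).astype(float)
        genes = pd.Index(
            [f"MT-{i}" for i in range(10)] + [f"g{i}" for i in range(390)]
        )
        totals = dense[0].sum()
        dense[0, :10] = 0.12 * totals / 10 / (1 - 0.12) * (1 - 0.12) * 1.2
        sc = singlecell.SCMatrix(
            sparse.csr_matrix(dense.round()),
            pd.Index([f"c{i}" for i in range(50)]),
            genes,
        )
        assert sc.mito_fraction.iloc[0] >= 0.10
        filtered, _ = singlecell.qc_filter(sc)
        assert "c0" not in filtered.barcodes

    def test_all_cells_removed_is_an_error_with_counts(self):
        dense = np.zeros((10, 300))
        dense[:, :50] = 1  # every cell expresses only 50 genes
        sc = singlecell.SCMatrix(
            sparse.csr_matrix(dense),
            pd.Index([f"c{i}" for i in range(10)]),
            pd.Index([f"g{i}" for i in range(300)]),
        )
        with pytest.raises(ValueError, match="all cells removed"):
            singlecell.qc_filter(sc)


class TestAnnotateCells:
    def test_reference_centroid_cell_gets_its_label_with_high_score(self):
        sig = deconv.synthetic_signature_matrix()
        # a pseudo-cell exactly proportional to the T-cell profile
        counts = (sig.values["T"] * 20).round()
        sc = singlecell.SCMatrix(
            sparse.csr_matrix(counts.to_numpy()[None, :]),
            pd.Index(["c0"]),
            pd.Index(sig.values.index),
        )
        ann = singlecell.annotate_cells(sc, sig)
        assert ann.table.loc["c0", "cell_type"] == "T"
        assert ann.celltype_scores.loc["c0", "T"] > 0.9

    def test_contaminants_are_not_blasts_and_get_no_subtype(self, subtype_model):
        sc, truth = make_sc(seed=3)
        filtered, _ = singlecell.qc_filter(sc)
        ann = singlecell.annotate_cells(
            filtered, deconv.synthetic_signature_matrix(), subtype_model
        )
        t_cells = truth.reindex(ann.table.index) == "T"
        sub = ann.table.loc[t_cells.to_numpy()]
        assert (~sub["blast"]).mean() > 0.95
        assert sub.loc[~sub["blast"], "subtype"].isna().all()

    @pytest.mark.parametrize("seed", range(5))
    def test_at_least_90_percent_of_blasts_get_the_truth_subtype(
        self, subtype_model, seed
    ):
        sc, truth = make_sc(seed=seed)
        filtered, _ = singlecell.qc_filter(sc)
        ann = singlecell.annotate_cells(
            filtered, deconv.synthetic_signature_matrix(), subtype_model
        )
        is_blast = truth.reindex(ann.table.index) == "blast"
        called = ann.table.loc[is_blast.to_numpy() & ann.table["blast"].to_numpy()]
        acc = (called["subtype"] == "KMT2A").mean()
        assert acc >= 0.90

    def test_too_few_shared_genes_is_an_error(self):
        sig = deconv.synthetic_signature_matrix()
        sc = singlecell.SCMatrix(
            sparse.csr_matrix(np.ones((5, 10))),
            pd.Index([f"c{i}" for i in range(5)]),
            pd.Index([f"zz{i}" for i in range(10)]),
        )
        with pytest.raises(ValueError, match="shared"):
            singlecell.annotate_cells(sc, sig)


class TestSummarizeSample:
    def make_annotation(self, subtypes, n_t=100):
        barcodes = pd.Index([f"c{i}" for i in range(len(subtypes) + n_t)])
        table = pd.DataFrame(
            {
                "cell_type": ["pro-B1"] * len(subtypes) + ["T"] * n_t,
                "blast": [True] * len(subtypes) + [False] * n_t,
                "subtype": list(subtypes) + [pd.NA] * n_t,
            },
            index=barcodes,
        )
        return singlecell.CellAnnotation(
            table, pd.DataFrame(index=barcodes), pd.DataFrame()
        )

    def test_dominant_subtype_vote_is_reported_with_its_fraction(self):
        ann = self.make_annotation(["KMT2A"] * 90 + ["DUX4"] * 10)
        s = singlecell.summarize_sample(ann)
        assert s.subtype_call == "KMT2A"
        assert s.blast_vote_fraction == pytest.approx(0.9)
        assert not s.mixed_signal

    def test_even_four_way_split_raises_mixed_signal_flag(self):
        ann = self.make_annotation(["A", "B", "C", "D"] * 25)
        s = singlecell.summarize_sample(ann)
        assert s.mixed_signal

    def test_too_few_blasts_yields_insufficient_with_composition(self):
        ann = self.make_annotation(["KMT2A"] * 5)
        s = singlecell.summarize_sample(ann)
        assert s.subtype_call == "insufficient blasts"
        assert s.composition["T"] > 0.9

    def test_summary_is_invariant_to_cell_order(self):
        ann = self.make_annotation(["KMT2A"] * 60 + ["DUX4"] * 40)
        shuffled = singlecell.CellAnnotation(
            ann.table.sample(frac=1, random_state=0),
            ann.celltype_scores,
            ann.subtype_scores,
        )
        s1 = singlecell.summarize_sample(ann)
        s2 = singlecell.summarize_sample(shuffled)
        assert s1.subtype_call == s2.subtype_call
        assert s1.blast_vote_fraction == s2.blast_vote_fraction

    def test_low_blast_sample_still_gets_the_right_call(self, subtype_model):
        """A sample with under 20% blasts is still called correctly at the
        sample level."""
        sc, truth = make_sc(n_blasts=150, total=1000, seed=11)
        assert (truth == "blast").mean() < 0.20
        filtered, _ = singlecell.qc_filter(sc)
        ann = singlecell.annotate_cells(
            filtered, deconv.synthetic_signature_matrix(), subtype_model
        )
        s = singlecell.summarize_sample(ann)
        assert s.subtype_call == "KMT2A"
        assert not s.mixed_signal


class TestMatrixIO:
    def test_mtx_round_trip_including_gzip(self, tmp_path):
        sc, _ = make_sc(n_blasts=20, total=60, seed=4)
        synthetic.write_sc_matrix(sc.matrix, sc.barcodes, sc.gene_ids, tmp_path)
        plain = singlecell.SCMatrix.from_mtx_dir(tmp_path)
        assert (plain.matrix != sc.matrix).nnz == 0
        gz = tmp_path / "gz"
        gz.mkdir()
        for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
            with open(tmp_path / name, "rb") as fin, gzip.open(
                gz / (name + ".gz"), "wb"
            ) as fout:
                shutil.copyfileobj(fin, fout)
        zipped = singlecell.SCMatrix.from_mtx_dir(gz)
        assert (zipped.matrix != sc.matrix).nnz == 0
        assert zipped.barcodes.equals(sc.barcodes)
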