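"""Ensemble classifier contracts: round schedule, confidence arithmetic,
determinism, graph-vote behavior, and held-out accuracy on separable
synthetic classes."""

import numpy as np
import pandas as pd
import pytest

from leukotype import classifier, featsel, normalize, synthetic
from leukotype.classifier import _summarize_votes
from leukotype.containers import GEPMatrix


class TestRoundSizes:
    def test_canonical_schedule_has_eleven_rounds(self):
        sizes = classifier.make_round_sizes(1058, 100)
        assert sizes == [100, 200, 300, 400, 500, 600, 700, 800, 900, 1000, 1058]
        assert len(sizes) == 11

    def test_boundary_and_hand_cases(self):
        assert classifier.make_round_sizes(100, 100) == [100]
        assert classifier.make_round_sizes(250, 100) == [100, 200, 250]

    def test_fewer_features_than_step_warns_and_uses_one_round(self):
        with pytest.warns(UserWarning, match="single round"):
            assert classifier.make_round_sizes(40, 100) == [40]


class TestConfidence:
    def test_six_of_eleven_votes_is_reported(self):
        pred = _summarize_votes(["A"] * 6 + ["B"] * 5)
        assert pred.confidence == pytest.approx(6 / 11)
        assert pred.reported and pred.modal_label == "A"

    def test_five_of_eleven_votes_is_unclassified(self):
        pred = _summarize_votes(["A"] * 5 + ["B"] * 3 + ["C"] * 3)
        assert pred.confidence == pytest.approx(5 / 11)
        assert not pred.reported

    def test_unanimous_votes_give_confidence_one(self):
        pred = _summarize_votes(["X"] * 11)
        assert pred.confidence == 1.0 and pred.reported

    def test_confidence_ignores_round_order(self):
        votes = ["A", "B", "A", "C", "A", "A", "B", "A", "A", "C", "A"]
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = list(rng.permutation(votes))
            assert _summarize_votes(shuffled).confidence == pytest.approx(7 / 11)
            assert _summarize_votes(shuffled).modal_label == "A"


class TestSVMEnsemble:
    def test_refit_reproduces_reference_predictions(self, fitted_model):
        p1 = classifier.predict_svm_ensemble(fitted_model, fitted_model.reference)
        refit = classifier.fit_svm_model(
            fitted_model.reference,
            fitted_model.labels,
            fitted_model.ranking,
            round_sizes=fitted_model.round_sizes,
            seed=fitted_model.seed,
        )
        p2 = classifier.predict_svm_ensemble(refit, fitted_model.reference)
        for s in p1:
            assert p1[s].votes == p2[s].votes

    def test_reference_self_prediction_is_perfect(self, fitted_model):
        preds = classifier.predict_svm_ensemble(fitted_model, fitted_model.reference)
        labels = fitted_model.labels
        assert all(
            preds[s].modal_label == labels[s] and preds[s].reported
            for s in labels.index
        )

    def test_predictions_invariant_to_gene_row_order(self, fitted_model):
        test = fitted_model.reference
        shuffled = GEPMatrix(
            test.values.sample(frac=1, random_state=1), test.provenance
        )
        p1 = classifier.predict_svm_ensemble(fitted_model, test)
        p2 = classifier.predict_svm_ensemble(fitted_model, shuffled)
        for s in test.samples:
            assert p1[s].votes == p2[s].votes

    def test_single_round_ensemble_equals_single_svm(self, fitted_model):
        single = classifier.fit_svm_model(
            fitted_model.reference,
            fitted_model.labels,
            fitted_model.ranking,
            round_sizes=[300],
            seed=0,
        )
        preds = classifier.predict_svm_ensemble(single, fitted_model.reference)
        genes, scaler, clf = single.svm_rounds[0]
        direct = clf.predict(
            scaler.transform(single.reference.values.loc[genes].T.to_numpy())
        )
        for s, d in zip(single.reference.samples, direct):
            assert preds[s].votes == [str(d)]
            assert preds[s].confidence == 1.0

    def test_too_many_missing_genes_is_an_error(self, fitted_model):
        few = GEPMatrix(
            fitted_model.reference.values.iloc[:100, :2], "vst"
        )
        with pytest.raises(ValueError, match="missing"):
            classifier.predict_svm_ensemble(fitted_model, few)

    def test_class_below_two_samples_refuses_to_fit(self, fitted_model):
        labels = fitted_model.labels.copy()
        labels.iloc[0] = "LONER"
        with pytest.raises(ValueError, match="fewer than 2"):
            classifier.fit_svm_model(
                fitted_model.reference, labels, fitted_model.ranking,
                round_sizes=fitted_model.round_sizes,
            )


class TestPhenographEnsemble:
    def test_duplicated_reference_sample_votes_its_class_every_round(
        self, fitted_model
    ):
        sid = fitted_model.reference.samples[0]
        test = GEPMatrix(
            fitted_model.reference.values[[sid]].rename(columns={sid: "t"}),
            "vst",
        )
        preds = classifier.predict_phenograph_ensemble(fitted_model, test)
        truth = fitted_model.labels[sid]
        assert preds["t"].votes == [truth] * len(fitted_model.round_sizes)
        assert preds["t"].confidence == 1.0

    def test_point_at_gaussian_centroid_gets_full_confidence(self):
        rng = np.random.default_rng(4)
        n, g = 60, 40
        a = rng.normal(0, 1, size=(g, n))
        b = rng.normal(6, 1, size=(g, n))
        values = pd.DataFrame(
            np.hstack([a, b]),
            index=[f"g{i}" for i in range(g)],
            columns=[f"s{j}" for j in range(2 * n)],
        )
        labels = pd.Series(["A"] * n + ["B"] * n, index=values.columns)
        table = pd.DataFrame(
            {"importance": np.linspace(1, 0.1, g), "confirmed_in": 8},
            index=values.index,
        )
        model = classifier.fit_svm_model(
            GEPMatrix(values, "vst"), labels,
            classifier.FeatureRanking(table), round_sizes=[20, 40], seed=0,
        )
        centroid = values[labels.index[labels == "B"]].mean(axis=1)
        test = GEPMatrix(pd.DataFrame({"t": centroid}), "vst")
        preds = classifier.predict_phenograph_ensemble(model, test, k=15)
        assert preds["t"].modal_label == "B"
        assert preds["t"].confidence == 1.0

    def test_k_not_smaller_than_n_is_an_error(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="smaller than n_samples"):
            classifier.phenograph_communities(X, k=10)

    def test_reference_self_prediction_is_perfect(self, fitted_model):
        preds = classifier.predict_phenograph_ensemble(
            fitted_model, fitted_model.reference
        )
        labels = fitted_model.labels
        acc = np.mean(
            [preds[s].modal_label == labels[s] for s in labels.index]
        )
        assert acc == 1.0


class TestUnifyCall:
    def make(self, label, conf, rounds=11):
        n = round(conf * rounds)
        votes = [label] * n + [f"other{i}" for i in range(rounds - n)]
        return _summarize_votes(votes)

    def test_concordant_reported_models(self):
        out = classifier.unify_gep_call(
            self.make("Ph/Ph-like", 1.0), self.make("Ph/Ph-like", 1.0)
        )
        assert out.unified_label == "Ph/Ph-like" and out.flag == "concordant"

    def test_single_reported_model_carries_its_label(self):
        out = classifier.unify_gep_call(
            self.make("DUX4", 0.9), self.make("A", 0.4)
        )
        assert out.unified_label == "DUX4" and out.flag == "single-model"

    def test_discordant_models_keep_svm_label_with_flag(self):
        out = classifier.unify_gep_call(
            self.make("KMT2A", 0.8), self.make("DUX4", 0.8)
        )
        assert out.unified_label == "KMT2A" and out.flag == "discordant"

    def test_neither_reported_is_unclassified(self):
        out = classifier.unify_gep_call(
            self.make("A", 0.4), self.make("B", 0.4)
        )
        assert out.unified_label == "unclassified" and not out.reported


class TestHeldOutAccuracy:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_heldout_accuracy_at_least_95_percent(self, seed):
        """30 train + 15 held-out per class, 8 highly distinct classes:
        each model classifies >= 95% of held-out samples correctly."""
        specs = synthetic.make_distinct_specs(8)
        cfg = synthetic.CohortConfig(
            specs, samples_per_subtype=45, n_genes=1200, rng_seed=100 + seed
        )
        counts, truth = synthetic.generate_bulk_cohort(cfg)
        gep = normalize.vst_transform(counts)
        train, test = featsel.train_test_split_cohort(
            truth.labels, train_ratio=2 / 3, rng_seed=seed
        )
        ranking = featsel.quick_importance_ranking(
            GEPMatrix(gep.values[train], gep.provenance),
            truth.labels.loc[train],
            counts.coding,
        )
        top = classifier.FeatureRanking(ranking.table.iloc[:300])
        model = classifier.fit_svm_model(
            GEPMatrix(gep.values.loc[top.gene_ids, train], gep.provenance),
            truth.labels.loc[train],
            top,
            seed=seed,
        )
        test_gep = GEPMatrix(gep.values[test], gep.provenance)
        svm = classifier.predict_svm_ensemble(model, test_gep)
        pg = classifier.predict_phenograph_ensemble(model, test_gep)
        y = truth.labels.loc[test]
        svm_acc = np.mean([svm[s].modal_label == y[s] for s in test])
        pg_acc = np.mean([pg[s].modal_label == y[s] for s in test])
        assert svm_acc >= 0.95
        assert pg_acc >= 0.95


class TestBundle:
    def test_bundle_round_trip_reproduces_predictions(self, fitted_model, tmp_path):
        classifier.save_bundle(fitted_model, tmp_path / "bundle")
        loaded = classifier.load_bundle(tmp_path / "bundle")
        assert loaded.round_sizes == fitted_model.round_sizes
        p1 = classifier.predict_svm_ensemble(fitted_model, fitted_model.reference)
        p2 = classifier.predict_svm_ensemble(loaded, loaded.reference)
        for s in fitted_model.reference.samples:
            assert p1[s].votes == p2[s].votes

    def test_bundle_manifest_hash_is_stable(self, fitted_model, tmp_path):
        import json

        classifier.save_bundle(fitted_model, tmp_path / "b1")
        classifier.save_bundle(fitted_model, tmp_path / "b2")
        h1 = json.loads((tmp_path / "b1" / "manifest.json").read_text())
        h2 = json.loads((tmp_path / "b2" / "manifest.json").read_text())
        assert h1["content_hash"] == h2["content_hash"]
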