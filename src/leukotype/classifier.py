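"""The two GEP-based subtype prediction models with multi-round
confidence scoring.

Neither a margin-based SVM nor graph clustering yields a native
probability, so reliability is quantified by re-running each model over an
increasing schedule of top-ranked feature-gene subsets (one vote per
round); the confidence score is the fraction of rounds voting the modal
label, and a subtype is reported only when that fraction exceeds 0.5.

Model 1 is a linear one-vs-rest SVM with per-gene standardization fitted
on the reference.  Model 2 is PhenoGraph-style: reference and test samples
are clustered jointly on a Jaccard-weighted shared-neighbor KNN graph with
Louvain-family community detection, and each test sample votes the
majority reference label of its community.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .containers import (
    FeatureRanking,
    GEPMatrix,
    GEPPrediction,
    ModelPrediction,
)

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
#: fraction of a model's feature genes that may be imputed in a test sample
MISSING_GENE_CAP = 0.2


def make_round_sizes(n_features: int, step: int = 100) -> list[int]:
    """Feature-subset sizes for the multi-round ensemble.

    Sizes run step, 2*step, ... up to the largest multiple below
    ``n_features``, then ``n_features`` itself; e.g. 1,058 features at step
    100 give the canonical 11-round schedule [100, 200, ..., 1000, 1058].
    """
    if n_features < step:
        warnings.warn(
            f"n_features={n_features} < step={step}; using a single round",
            stacklevel=2,
        )
        return [n_features]
    sizes = list(range(step, n_features, step))
    sizes.append(n_features)
    return sizes


@dataclass
class ReferenceModel:
    """Curated reference expression plus fitted per-round classifier state.

    ``reference`` is restricted to the consensus feature genes (what the
    classifiers consume); ``reference_full`` optionally keeps the
    genome-wide reference expression for co-normalization, chromosome-
    ratio baselines, and lesion expression validation.
    """

    reference: GEPMatrix  # restricted to consensus feature genes
    labels: pd.Series  # GEP-class label per reference sample
    ranking: FeatureRanking
    round_sizes: list[int]
    svm_rounds: list[tuple[pd.Index, StandardScaler, LinearSVC]] = field(
        default_factory=list
    )
    seed: int = 0
    reference_full: GEPMatrix | None = None

    def __post_init__(self) -> None:
        if any(
            b <= a for a, b in zip(self.round_sizes, self.round_sizes[1:])
        ):
            raise ValueError("round_sizes must be strictly increasing")
        if self.round_sizes[-1] > len(self.ranking.gene_ids):
            raise ValueError("last round exceeds the consensus feature list")
        small = self.labels.value_counts()
        small = small[small < 3]
        if len(small):
            log.warning(
                "classes with fewer than 3 reference samples: %s",
                ", ".join(small.index),
            )

    @property
    def feature_genes(self) -> pd.Index:
        return self.ranking.gene_ids[: self.round_sizes[-1]]

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique())


def fit_svm_model(
    reference: GEPMatrix,
    labels: pd.Series,
    ranking: FeatureRanking,
    round_sizes: list[int] | None = None,
    *,
    step: int = 100,
    C: float = 1.0,
    seed: int = 0,
    reference_full: GEPMatrix | None = None,
) -> ReferenceModel:
    """Fit one linear one-vs-rest SVM per ensemble round.

    Each round uses the top-k genes of the importance ranking with a
    per-gene standardizer fitted on the reference.  Deterministic: the
    primal liblinear problem has a unique solution, so refits reproduce
    predictions exactly.
    """
    counts = labels.value_counts()
    if (counts < 2).any():
        bad = ", ".join(counts[counts < 2].index)
        raise ValueError(f"classes with fewer than 2 samples: {bad}")
    if round_sizes is None:
        round_sizes = make_round_sizes(len(ranking.gene_ids), step)
    model = ReferenceModel(
        reference=reference,
        labels=labels,
        ranking=ranking,
        round_sizes=list(round_sizes),
        seed=seed,
        reference_full=reference_full,
    )
    y = labels.loc[reference.samples].to_numpy()
    for size in model.round_sizes:
        genes = ranking.top(size)
        X = reference.values.loc[genes].T.to_numpy()
        scaler = StandardScaler().fit(X)
        clf = LinearSVC(C=C, dual=False, max_iter=5000)
        clf.fit(scaler.transform(X), y)
        model.svm_rounds.append((genes, scaler, clf))
    return model


def _align_test(model: ReferenceModel, test: GEPMatrix) -> pd.DataFrame:
    """Restrict/impute the test matrix to the model's feature-gene space."""
    genes = model.feature_genes
    missing = genes.difference(test.genes)
    if len(missing) / len(genes) > MISSING_GENE_CAP:
        raise ValueError(
            f"{len(missing)}/{len(genes)} model feature genes missing from "
            f"test data (cap {MISSING_GENE_CAP:.0%}); co-normalize against "
            "the reference first"
        )
    aligned = test.values.reindex(genes)
    if len(missing):
        med = model.reference.values.median(axis=1)
        for g in missing:
            aligned.loc[g] = med.loc[g]
        log.warning("imputed %d missing feature genes", len(missing))
    return aligned


def _summarize_votes(votes: list[str], threshold: float = 0.5) -> ModelPrediction:
    counts = Counter(votes)
    top = max(counts.values())
    modal = min(label for label, c in counts.items() if c == top)
    confidence = top / len(votes)
    return ModelPrediction(
        votes=votes,
        modal_label=modal,
        confidence=confidence,
        reported=confidence > threshold and modal != UNASSIGNED,
    )


def predict_svm_ensemble(
    model: ReferenceModel, test: GEPMatrix, threshold: float = 0.5
) -> dict[str, ModelPrediction]:
    """One SVM vote per round; confidence = modal-vote fraction."""
    aligned = _align_test(model, test)
    votes: dict[str, list[str]] = {s: [] for s in test.samples}
    for genes, scaler, clf in model.svm_rounds:
        X = aligned.loc[genes].T.to_numpy()
        pred = clf.predict(scaler.transform(X))
        for s, p in zip(test.samples, pred):
            votes[s].append(str(p))
    return {s: _summarize_votes(v, threshold) for s, v in votes.items()}


def phenograph_communities(
    X: np.ndarray, k: int = 30, seed: int = 0, resolution: float = 1.0
) -> np.ndarray:
    """PhenoGraph-style clustering: Jaccard-weighted KNN graph + Louvain-
    family (RB-configuration) community detection with a fixed seed."""
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_samples={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neighbor_sets = [set(row[1:]) for row in idx]
    edges, weights = [], []
    for i in range(n):
        for j in neighbor_sets[i]:
            if j <= i and i in neighbor_sets[j]:
                continue  # avoid double-adding mutual edges
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = inter / union if union else 0.0
            if w > 0:
                edges.append((i, int(j)))
                weights.append(w)
    g = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def predict_phenograph_ensemble(
    model: ReferenceModel,
    test: GEPMatrix,
    k: int = 30,
    threshold: float = 0.5,
) -> dict[str, ModelPrediction]:
    """Per round, cluster reference + test jointly and vote each test
    sample's community majority reference label.

    A community without reference members, or with a tied majority, votes
    ``unassigned`` for that round (never a coin flip).
    """
    aligned = _align_test(model, test)
    ref_labels = model.labels.loc[model.reference.samples].to_numpy()
    n_ref = model.reference.values.shape[1]
    # k larger than the smallest reference class would force its members
    # into mixed neighborhoods and merge communities across classes
    min_class = int(model.labels.value_counts().min())
    votes: dict[str, list[str]] = {s: [] for s in test.samples}
    for genes, scaler, _clf in model.svm_rounds:
        ref_X = scaler.transform(model.reference.values.loc[genes].T.to_numpy())
        test_X = scaler.transform(aligned.loc[genes].T.to_numpy())
        joint = np.vstack([ref_X, test_X])
        kk = max(2, min(k, joint.shape[0] // 3, min_class))
        comm = phenograph_communities(joint, k=kk, seed=model.seed)
        for t, s in enumerate(test.samples):
            members = comm == comm[n_ref + t]
            ref_members = ref_labels[members[:n_ref]]
            if len(ref_members) == 0:
                votes[s].append(UNASSIGNED)
                continue
            counts = Counter(ref_members)
            best = max(counts.values())
            winners = [lbl for lbl, c in counts.items() if c == best]
            votes[s].append(winners[0] if len(winners) == 1 else UNASSIGNED)
    return {s: _summarize_votes(v, threshold) for s, v in votes.items()}


def unify_gep_call(
    svm: ModelPrediction | None, pg: ModelPrediction | None
) -> GEPPrediction:
    """Combine the two models' calls into one GEP-level label.

    Both reported and equal -> concordant; both reported but different ->
    discordant, with the SVM label carried forward (it resolves multiple
    subtypes better) but flagged so the rule engine can weigh both; one
    reported -> that label with a single-model flag; neither ->
    unclassified.
    """
    s_ok = svm is not None and svm.reported
    p_ok = pg is not None and pg.reported
    if s_ok and p_ok:
        if svm.modal_label == pg.modal_label:
            return GEPPrediction(svm, pg, svm.modal_label, "concordant")
        return GEPPrediction(svm, pg, svm.modal_label, "discordant")
    if s_ok:
        return GEPPrediction(svm, pg, svm.modal_label, "single-model")
    if p_ok:
        return GEPPrediction(svm, pg, pg.modal_label, "single-model")
    return GEPPrediction(svm, pg, "unclassified", "unclassified")


# --------------------------------------------------------------------------
# model bundle persistence (text files + manifest; SVMs refit on load)

def save_bundle(model: ReferenceModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model.reference.values.to_csv(out / "reference.tsv", sep="\t", index_label="gene")
    if model.reference_full is not None:
        model.reference_full.values.to_csv(
            out / "reference_full.tsv", sep="\t", index_label="gene"
        )
    model.labels.rename("gep_class").to_csv(
        out / "labels.tsv", sep="\t", index_label="sample"
    )
    model.ranking.to_tsv(out / "feature_ranking.tsv")
    manifest = {
        "format_version": 1,
        "round_sizes": [int(s) for s in model.round_sizes],
        "seed": int(model.seed),
        "provenance": model.reference.provenance,
        "n_reference_samples": int(model.reference.values.shape[1]),
        "content_hash": _bundle_hash(model),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _bundle_hash(model: ReferenceModel) -> str:
    h = hashlib.sha256()
    h.update(model.reference.values.round(6).to_csv().encode())
    h.update(model.labels.to_csv().encode())
    h.update(model.ranking.table.round(6).to_csv().encode())
    return h.hexdigest()[:16]


def load_bundle(bundle_dir: str | Path) -> ReferenceModel:
    """Load a bundle and deterministically refit the per-round SVMs."""
    d = Path(bundle_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    values = pd.read_csv(d / "reference.tsv", sep="\t", index_col=0)
    values.index = values.index.astype(str)
    labels = pd.read_csv(d / "labels.tsv", sep="\t", index_col=0)["gep_class"]
    labels.index = labels.index.astype(str)
    ranking = FeatureRanking.from_tsv(d / "feature_ranking.tsv")
    provenance = manifest.get("provenance", "vst")
    full = None
    if (d / "reference_full.tsv").exists():
        fv = pd.read_csv(d / "reference_full.tsv", sep="\t", index_col=0)
        fv.index = fv.index.astype(str)
        full = GEPMatrix(fv, provenance=provenance)
    return fit_svm_model(
        GEPMatrix(values, provenance=provenance),
        labels,
        ranking,
        round_sizes=manifest["round_sizes"],
        seed=manifest["seed"],
        reference_full=full,
    )
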