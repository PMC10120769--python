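"""Balanced-cohort construction, Boruta feature selection, consensus
feature ranking, and iterative curation of the expression reference.

The selection pipeline addresses a skewed cohort: per-subtype sample sizes
are equalized (subsampling major classes, SMOTE-interpolating minor ones)
at eight schedule sizes, Boruta is run on each balanced cohort, and only
genes confirmed in all eight runs enter the consensus list, ranked by mean
importance.  Only protein-coding genes are offered to selection so that
mRNA and total-RNA libraries behave alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .containers import FeatureRanking, GEPMatrix

log = logging.getLogger(__name__)

#: per-subtype sample sizes of the balanced-cohort schedule
SMOTE_SCHEDULE = (10, 25, 50, 75, 100, 150, 200, 250)


# --------------------------------------------------------------------------
# SMOTE balancing

def smote_balance(
    gep: GEPMatrix,
    labels: pd.Series,
    target_n: int,
    k_neighbors: int = 5,
    rng_seed: int = 0,
) -> tuple[GEPMatrix, pd.Series]:
    """Equalize class sizes at ``target_n`` samples per class.

    Classes above ``target_n`` are subsampled without replacement; classes
    below are augmented with synthetic points x_i + u * (x_nn - x_i) where
    u ~ Uniform(0, 1) and x_nn is one of the k nearest same-class
    neighbors (k capped at class size - 1).
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    X = gep.values.T  # samples x genes
    out_rows, out_labels, out_names = [], [], []
    for cls in sorted(labels.unique()):
        members = labels.index[labels == cls]
        if len(members) < 2:
            raise ValueError(
                f"class {cls!r} has a single sample; cannot interpolate"
            )
        Xc = X.loc[members].to_numpy()
        if len(members) >= target_n:
            pick = rng.choice(len(members), size=target_n, replace=False)
            for j, idx in enumerate(pick):
                out_rows.append(Xc[idx])
                out_names.append(f"{cls}|{j}")
                out_labels.append(cls)
            continue
        for j in range(len(members)):
            out_rows.append(Xc[j])
            out_names.append(f"{cls}|{j}")
            out_labels.append(cls)
        k = min(k_neighbors, len(members) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)
        for j in range(target_n - len(members)):
            i = int(rng.integers(len(members)))
            neigh = idx[i][1:][int(rng.integers(k))]
            u = rng.uniform()
            out_rows.append(Xc[i] + u * (Xc[neigh] - Xc[i]))
            out_names.append(f"{cls}|syn{j}")
            out_labels.append(cls)
    balanced = pd.DataFrame(
        np.vstack(out_rows).T, index=gep.genes, columns=out_names
    )
    return (
        GEPMatrix(balanced, provenance=gep.provenance),
        pd.Series(out_labels, index=out_names, name="subtype"),
    )


# --------------------------------------------------------------------------
# Boruta

@dataclass
class BorutaResult:
    status: pd.Series  # per gene: confirmed | rejected
    importance: pd.Series  # per gene mean importance over iterations
    n_iter: int


def boruta_select(
    gep: GEPMatrix,
    labels: pd.Series,
    alpha: float = 0.01,
    max_iter: int = 100,
    rng_seed: int = 0,
    *,
    n_estimators: int = 500,
    coding_mask: pd.Series | None = None,
) -> BorutaResult:
    """Boruta all-relevant feature selection with shadow features.

    Each iteration appends a shuffled shadow copy of every candidate gene,
    fits a random forest, and records a "hit" for genes whose importance
    beats the maximum shadow importance.  Two-sided binomial tests with
    Bonferroni correction confirm or reject genes; genes still tentative at
    ``max_iter`` are rejected.
    """
    if labels.nunique() < 2:
        raise ValueError("Boruta needs at least 2 classes")
    genes = gep.genes
    if coding_mask is not None:
        genes = genes[coding_mask.reindex(genes).fillna(False).astype(bool)]
    X_all = gep.values.loc[genes].T.to_numpy()
    y = labels.loc[gep.samples].to_numpy()
    rng = np.random.default_rng(rng_seed)
    n_genes = len(genes)

    hits = np.zeros(n_genes, dtype=int)
    trials = np.zeros(n_genes, dtype=int)
    imp_sum = np.zeros(n_genes)
    imp_n = np.zeros(n_genes, dtype=int)
    status = np.full(n_genes, "tentative", dtype=object)

    for it in range(1, max_iter + 1):
        active = status == "tentative"
        if not active.any():
            break
        Xa = X_all[:, active]
        shadow = Xa.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(np.hstack([Xa, shadow]), y)
        imp = forest.feature_importances_
        real_imp = imp[: Xa.shape[1]]
        shadow_max = imp[Xa.shape[1]:].max()
        active_idx = np.where(active)[0]
        hits[active_idx] += (real_imp > shadow_max).astype(int)
        trials[active_idx] += 1
        imp_sum[active_idx] += real_imp
        imp_n[active_idx] += 1

        if it >= 5:
            # Bonferroni over the *initial* feature count: correcting by
            # the shrinking active set would loosen the threshold as
            # rejections accumulate and admit chance-correlated noise
            corrected = alpha / max(n_genes, 1)
            for g in active_idx:
                p_hi = stats.binom.sf(hits[g] - 1, trials[g], 0.5)
                p_lo = stats.binom.cdf(hits[g], trials[g], 0.5)
                if p_hi < corrected / 2:
                    status[g] = "confirmed"
                elif p_lo < corrected / 2:
                    status[g] = "rejected"

    n_tent = int((status == "tentative").sum())
    if n_tent:
        log.info("Boruta: %d tentative features rejected at max_iter", n_tent)
    status[status == "tentative"] = "rejected"
    importance = np.where(imp_n > 0, imp_sum / np.maximum(imp_n, 1), 0.0)
    return BorutaResult(
        status=pd.Series(status, index=genes, name="status"),
        importance=pd.Series(importance, index=genes, name="importance"),
        n_iter=it,
    )


def consensus_features(runs: list[BorutaResult]) -> FeatureRanking:
    """Genes confirmed in all eight resampled runs, ranked by mean importance."""
    if len(runs) != 8:
        raise ValueError(f"consensus requires exactly 8 runs, got {len(runs)}")
    universe = runs[0].status.index
    for r in runs[1:]:
        if not r.status.index.equals(universe):
            raise ValueError("mismatched gene universes across Boruta runs")
    confirmed_in = sum((r.status == "confirmed").astype(int) for r in runs)
    keep = confirmed_in[confirmed_in == 8].index
    importance = sum(r.importance for r in runs) / len(runs)
    table = pd.DataFrame(
        {"importance": importance.loc[keep], "confirmed_in": 8}, index=keep
    )
    table = table.sort_values(
        ["importance"], ascending=False, kind="mergesort"
    )
    # deterministic tie-break by gene ID
    table = (
        table.reset_index()
        .sort_values(["importance", "index"], ascending=[False, True], kind="mergesort")
        .set_index("index")
    )
    table.index.name = "gene"
    return FeatureRanking(table)


def quick_importance_ranking(
    gep: GEPMatrix,
    labels: pd.Series,
    coding_mask: pd.Series | None = None,
    alpha: float | None = 0.01,
) -> FeatureRanking:
    """One-way-ANOVA F ranking of genes: a fast stand-in ordering.

    Used when a fitted model is needed without paying for the full
    eightfold Boruta consensus.  Like Boruta's confirmed set, the ranking
    keeps only genes with discriminative evidence (Benjamini-Hochberg FDR
    below ``alpha``); padding the list with noise genes would poison the
    later, larger ensemble rounds.  ``alpha=None`` keeps every gene.
    """
    genes = gep.genes
    if coding_mask is not None:
        genes = genes[coding_mask.reindex(genes).fillna(False).astype(bool)]
    X = gep.values.loc[genes]
    groups = [
        X.loc[:, labels.index[labels == cls]].to_numpy()
        for cls in sorted(labels.unique())
    ]
    f, p = stats.f_oneway(*[g.T for g in groups])
    f = np.where(np.isfinite(f), f, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    table = pd.DataFrame({"importance": f, "confirmed_in": 8}, index=genes)
    if alpha is not None:
        from statsmodels.stats.multitest import multipletests

        keep = multipletests(p, alpha=alpha, method="fdr_bh")[0]
        table = table.loc[keep]
    table.index.name = "gene"
    table = (
        table.reset_index()
        .sort_values(["importance", "gene"], ascending=[False, True], kind="mergesort")
        .set_index("gene")
    )
    return FeatureRanking(table)


# --------------------------------------------------------------------------
# reference curation

def curate_reference(
    gep: GEPMatrix,
    lesion_labels: pd.Series,
    k: int = 15,
    max_rounds: int = 5,
    rng_seed: int = 0,
    reducer=None,
    n_top_variable: int = 500,
) -> tuple[pd.Index, pd.DataFrame]:
    """Iteratively drop samples whose expression neighborhood disagrees
    with their lesion-based label.

    Each round clusters the current samples with a PhenoGraph-style graph
    (see :mod:`leukotype.classifier`) and embeds them in 2-D; a sample is
    dropped if its community's majority label OR its k-nearest-neighbor
    majority label in the embedding disagrees with its lesion label.
    Classes are never reduced below 3 samples; iteration stops at a fixed
    point or ``max_rounds``.

    Returns the retained sample index and a log of drops (sample, round,
    reason).
    """
    from .classifier import phenograph_communities

    if (lesion_labels.value_counts() < 3).any():
        raise ValueError("every class needs at least 3 samples for curation")
    current = pd.Index(gep.samples)
    drops = []
    # cluster and embed on the most variable genes (MAD-ranked), the
    # standard practice for expression maps: distances over the full gene
    # space are diluted by uninformative genes
    mad = (gep.values.sub(gep.values.median(axis=1), axis=0)).abs().median(axis=1)
    top_genes = mad.sort_values(ascending=False).index[:n_top_variable]
    for rnd in range(1, max_rounds + 1):
        X = gep.values.loc[top_genes, current].T.to_numpy()
        y = lesion_labels.loc[current]
        # cap k by the smallest class so communities cannot be forced to
        # straddle classes, which would drop perfectly good samples
        min_class = int(y.value_counts().min())
        communities = phenograph_communities(
            X, k=min(30, max(2, len(current) // 3), max(2, min_class)),
            seed=rng_seed,
        )
        if reducer is None:
            # a nonlinear 2-D embedding: a linear projection cannot keep
            # many classes apart in two dimensions and would trigger
            # spurious neighborhood disagreements
            emb_reducer = TSNE(
                n_components=2,
                random_state=rng_seed,
                init="pca",
                perplexity=min(30.0, max(5.0, (len(current) - 1) / 3)),
            )
        else:
            emb_reducer = reducer
        emb = emb_reducer.fit_transform(X)
        kk = min(k, len(current) - 1)
        nn = NearestNeighbors(n_neighbors=kk + 1).fit(emb)
        _, idx = nn.kneighbors(emb)

        to_drop = []
        counts = y.value_counts().to_dict()
        for i, sid in enumerate(current):
            own = y.iloc[i]
            comm_members = y[communities == communities[i]]
            comm_major = comm_members.mode().iloc[0]
            knn_major = y.iloc[idx[i][1:]].mode().iloc[0]
            reason = None
            if comm_major != own:
                reason = f"community majority {comm_major!r}"
            elif knn_major != own:
                reason = f"KNN majority {knn_major!r}"
            if reason and counts[own] > 3:
                to_drop.append(sid)
                counts[own] -= 1
                drops.append({"sample": sid, "round": rnd, "reason": reason})
        if not to_drop:
            break
        current = current.difference(pd.Index(to_drop), sort=False)
    return current, pd.DataFrame(drops, columns=["sample", "round", "reason"])


def train_test_split_cohort(
    labels: pd.Series, train_ratio: float = 2 / 3, rng_seed: int = 0
) -> tuple[pd.Index, pd.Index]:
    """Stratified split keeping train:test around the conventional 2:1."""
    rng = np.random.default_rng(rng_seed)
    train, test = [], []
    for cls in sorted(labels.unique()):
        members = list(labels.index[labels == cls])
        rng.shuffle(members)
        cut = int(round(len(members) * train_ratio))
        cut = min(max(cut, 1), len(members) - 1) if len(members) > 1 else 1
        train += members[:cut]
        test += members[cut:]
    return pd.Index(train), pd.Index(test)
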