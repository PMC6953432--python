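"""Repeated-cross-validated kNN classification of condition phenotypes.

Per-animal electrophysiological (or behavioral) feature vectors are
classified with a pipeline of quantile transformation, mutual-information
feature selection ("select percentile"), and a k-nearest-neighbors
classifier. The dataset is repeatedly (default 500 times) split into a
stratified 2/3 training and 1/3 validation set; hyper-parameters (number
of quantiles, selection percentile, number of neighbors, neighbor
weighting, leaf size) are tuned on each training set by an inner 3-fold
grid search, and accuracy is scored on the untouched validation third. The
median over repetitions is the reported accuracy. The fitted per-repetition
pipelines form an ensemble that can vote on entirely new animals (e.g., a
treated rescue group), and a 2D t-SNE embedding with a nearest-neighbor
class field visualizes the decision space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_classif
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import (
    KNeighborsClassifier,
    KNeighborsRegressor,
    NearestNeighbors,
)
from sklearn.preprocessing import QuantileTransformer

from .core import FeatureTable

DEFAULT_N_ITER = 500

# Hyper-parameter grid for the inner 3-fold search. The tuned parameters
# are the number of quantiles of the transform, the selection percentile,
# and the kNN neighbor count, weighting and leaf size.
GRID = {
    "n_quantiles": (5, 10, 25),
    "percentile": (40, 60, 80, 100),
    "n_neighbors": (1, 3, 5, 7),
    "weights": ("uniform", "distance"),
    "leaf_size": (10, 30),
}


@dataclass
class FittedPipeline:
    """One tuned and refitted pipeline from a single CV repetition."""

    transformer: QuantileTransformer
    selected: np.ndarray  # boolean feature mask
    knn: KNeighborsClassifier
    params: dict

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xt = self.transformer.transform(X)[:, self.selected]
        return self.knn.predict(Xt)


@dataclass
class CVResult:
    accuracies: np.ndarray  # per-iteration held-out accuracy
    median_accuracy: float
    chosen_params: list[dict]
    classes: np.ndarray
    feature_names: list[str]
    pipelines: list[FittedPipeline] = field(repr=False, default_factory=list)
    seed: int | None = None


def _select_mask(mi_scores: np.ndarray, percentile: int) -> np.ndarray:
    """Boolean mask of the top ``percentile`` % features by MI score."""
    n = mi_scores.size
    k = max(1, int(np.ceil(n * percentile / 100.0)))
    order = np.argsort(-mi_scores, kind="stable")
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return mask


def _fit_transform_cache(
    X_tr: np.ndarray, y_tr: np.ndarray, rs: int
) -> dict[int, tuple[QuantileTransformer, np.ndarray, np.ndarray]]:
    """Per n_quantiles: fitted transformer, transformed X, MI scores.

    The transform and the mutual-information scores do not depend on the
    kNN sub-grid, so computing them once per (fold, n_quantiles) gives the
    same search result as a full grid at a fraction of the cost.
    """
    cache = {}
    for nq in GRID["n_quantiles"]:
        qt = QuantileTransformer(
            n_quantiles=min(nq, X_tr.shape[0]),
            output_distribution="uniform",
            random_state=rs,
        )
        Xt = qt.fit_transform(X_tr)
        mi = mutual_info_classif(Xt, y_tr, random_state=rs)
        cache[nq] = (qt, Xt, mi)
    return cache


def _knn_scores(
    Xt_tr: np.ndarray, y_tr: np.ndarray, Xt_va: np.ndarray, y_va: np.ndarray,
    n_classes: int,
) -> dict[tuple[int, str], float]:
    """Validation accuracy for every (n_neighbors, weights) pair.

    One neighbor query at the largest k serves the whole kNN sub-grid:
    predictions for smaller k use prefixes of the sorted neighbor list,
    and uniform/distance weighting reuse the same distances. Leaf size
    never changes predictions (it only tunes tree traversal), so scores
    are shared across leaf sizes.
    """
    k_max = min(max(GRID["n_neighbors"]), Xt_tr.shape[0])
    nn = NearestNeighbors(n_neighbors=k_max).fit(Xt_tr)
    dist, idx = nn.kneighbors(Xt_va)
    labels = y_tr[idx]  # (n_va, k_max) integer class codes
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    # exact hits get all the weight, as in standard distance-weighted kNN
    inv[~np.isfinite(inv)] = 1e12
    out = {}
    for k in GRID["n_neighbors"]:
        kk = min(k, k_max)
        for w in GRID["weights"]:
            wts = np.ones_like(dist[:, :kk]) if w == "uniform" else inv[:, :kk]
            votes = np.zeros((labels.shape[0], n_classes))
            for c in range(n_classes):
                votes[:, c] = np.where(labels[:, :kk] == c, wts, 0.0).sum(axis=1)
            pred = votes.argmax(axis=1)  # ties: smallest class index
            out[(k, w)] = float((pred == y_va).mean())
    return out


def _inner_grid_search(X: np.ndarray, y: np.ndarray, rs: int) -> dict:
    """Stratified 3-fold grid search over the full pipeline grid.

    The quantile transform and mutual-information scores are computed once
    per (fold, n_quantiles) and shared across the downstream sub-grid;
    the search result is identical to fitting every combination.
    """
    classes, y_codes = np.unique(y, return_inverse=True)
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=rs)
    combos = list(product(GRID["n_quantiles"], GRID["percentile"]))
    scores: dict[tuple, float] = {}
    for tr_idx, va_idx in skf.split(X, y_codes):
        X_tr, y_tr = X[tr_idx], y_codes[tr_idx]
        X_va, y_va = X[va_idx], y_codes[va_idx]
        cache = _fit_transform_cache(X_tr, y_tr, rs)
        for nq, perc in combos:
            qt, Xt, mi = cache[nq]
            mask = _select_mask(mi, perc)
            Xv = qt.transform(X_va)
            for (k, w), acc in _knn_scores(
                Xt[:, mask], y_tr, Xv[:, mask], y_va, len(classes)
            ).items():
                for leaf in GRID["leaf_size"]:
                    scores[(nq, perc, k, w, leaf)] = (
                        scores.get((nq, perc, k, w, leaf), 0.0) + acc
                    )
    ordered = [
        (nq, perc, k, w, leaf)
        for nq in GRID["n_quantiles"]
        for perc in GRID["percentile"]
        for k in GRID["n_neighbors"]
        for w in GRID["weights"]
        for leaf in GRID["leaf_size"]
    ]
    best = max(ordered, key=lambda c: scores[c])  # ties: first in grid order
    nq, perc, k, w, leaf = best
    return {
        "n_quantiles": nq,
        "percentile": perc,
        "n_neighbors": k,
        "weights": w,
        "leaf_size": leaf,
    }


def _fit_with_params(
    X: np.ndarray, y: np.ndarray, params: dict, rs: int
) -> FittedPipeline:
    qt = QuantileTransformer(
        n_quantiles=min(params["n_quantiles"], X.shape[0]),
        output_distribution="uniform",
        random_state=rs,
    )
    Xt = qt.fit_transform(X)
    mi = mutual_info_classif(Xt, y, random_state=rs)
    mask = _select_mask(mi, params["percentile"])
    knn = KNeighborsClassifier(
        n_neighbors=min(params["n_neighbors"], X.shape[0]),
        weights=params["weights"],
        leaf_size=params["leaf_size"],
    )
    knn.fit(Xt[:, mask], y)
    return FittedPipeline(transformer=qt, selected=mask, knn=knn, params=params)


def tune_and_score(
    table: FeatureTable,
    n_iter: int = DEFAULT_N_ITER,
    seed: int | None = None,
) -> CVResult:
    """Repeated nested-CV accuracy of the quantile/MI-selection/kNN pipeline.

    Each of the ``n_iter`` repetitions draws a stratified 2/3-1/3 split,
    tunes hyper-parameters by inner stratified 3-fold grid search on the
    training 2/3, refits on that 2/3, and scores on the held-out 1/3.
    """
    if table.labels is None:
        raise ValueError("tune_and_score needs a labeled feature table")
    X, y = table.X, table.y
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 3:
        raise ValueError("each class needs >= 3 animals for inner 3-fold CV")
    rng = np.random.default_rng(seed)
    accs = np.zeros(n_iter)
    params_list: list[dict] = []
    pipelines: list[FittedPipeline] = []
    for it in range(n_iter):
        rs = int(rng.integers(0, 2**31 - 1))
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=1 / 3, stratify=y, random_state=rs
        )
        best = _inner_grid_search(X_tr, y_tr, rs)
        pipe = _fit_with_params(X_tr, y_tr, best, rs)
        accs[it] = float((pipe.predict(X_te) == y_te).mean())
        params_list.append(best)
        pipelines.append(pipe)
    return CVResult(
        accuracies=accs,
        median_accuracy=float(np.median(accs)),
        chosen_params=params_list,
        classes=classes,
        feature_names=table.feature_names,
        pipelines=pipelines,
        seed=seed,
    )


def predict_heldout(result: CVResult, new_table: FeatureTable) -> dict:
    """Ensemble vote of all per-repetition pipelines on new animals.

    Returns per-animal majority class and vote fraction, plus the
    group-level fraction of animals assigned to each class.
    """
    if new_table.feature_names != result.feature_names:
        raise ValueError("feature columns do not match the training table")
    X = new_table.X
    votes = np.stack([p.predict(X) for p in result.pipelines])  # iter x animal
    per_animal = []
    for j, animal in enumerate(new_table.data.index):
        counts = pd.Series(votes[:, j]).value_counts()
        per_animal.append(
            {
                "animal": animal,
                "predicted_class": counts.index[0],
                "vote_fraction": float(counts.iloc[0] / votes.shape[0]),
            }
        )
    majorities = pd.Series([a["predicted_class"] for a in per_animal])
    group_fraction = {
        str(c): float((majorities == c).mean()) for c in result.classes
    }
    return {"per_animal": per_animal, "group_fraction": group_fraction}


def decision_map(
    table: FeatureTable,
    result: CVResult,
    grid_size: int = 200,
    seed: int | None = None,
    perplexity: float | None = None,
):
    """2D t-SNE embedding with a nearest-neighbor class field.

    The feature space is reduced to two dimensions with t-SNE; the
    classifier's decision space is approximated by k-nearest-neighbor
    regression of the ensemble-predicted classes on the embedded
    coordinates, evaluated over a dense grid covering the embedding — a
    Voronoi-like tessellation when k = 1.
    """
    X = table.X
    if X.shape[0] < 5:
        raise ValueError("decision map needs >= 5 animals")
    perp = perplexity if perplexity is not None else min(30.0, (X.shape[0] - 1) / 3)
    emb = TSNE(
        n_components=2, perplexity=perp, random_state=seed, init="pca"
    ).fit_transform(X)
    votes = np.stack([p.predict(X) for p in result.pipelines])
    predicted = np.array(
        [pd.Series(votes[:, j]).value_counts().index[0] for j in range(X.shape[0])]
    )
    class_codes = np.searchsorted(result.classes, predicted)
    knr = KNeighborsRegressor(n_neighbors=1)
    knr.fit(emb, class_codes.astype(float))
    pad = 0.05 * np.ptp(emb, axis=0)
    xs = np.linspace(emb[:, 0].min() - pad[0], emb[:, 0].max() + pad[0], grid_size)
    ys = np.linspace(emb[:, 1].min() - pad[1], emb[:, 1].max() + pad[1], grid_size)
    gx, gy = np.meshgrid(xs, ys)
    field = knr.predict(np.c_[gx.ravel(), gy.ravel()]).reshape(gx.shape)
    coords = pd.DataFrame(
        {
            "animal": table.data.index,
            "tsne1": emb[:, 0],
            "tsne2": emb[:, 1],
            "predicted_class": predicted,
        }
    )
    if table.labels is not None:
        coords["label"] = table.labels.to_numpy()
    return {"embedding": coords, "grid_x": xs, "grid_y": ys, "class_field": field}


def plot_decision_map(dmap: dict, ax=None):
    """Render the embedding over the class field (matplotlib axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.pcolormesh(
        dmap["grid_x"], dmap["grid_y"], dmap["class_field"],
        cmap="coolwarm", alpha=0.3, shading="auto",
    )
    emb = dmap["embedding"]
    hue = "label" if "label" in emb else "predicted_class"
    for cls, sub in emb.groupby(hue):
        ax.scatter(sub["tsne1"], sub["tsne2"], label=str(cls), s=25)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(frameon=False)
    return ax
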