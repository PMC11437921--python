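"""Biomarker-panel evaluation: univariate bootstrap ROC, PLS-DA with
VIP feature ranking, balanced Monte-Carlo cross-validation over
increasing panel sizes, and PCA scores/loadings for biplots.

The multivariate workflow follows the common metabolomics/proteomics
recipe: a two-latent-variable partial least squares discriminant
analysis is fit on stratified two-thirds training splits, features are
ranked by their variable importance in projection (VIP), models are
refit on the top-k features and scored on the held-out third, and the
whole procedure is repeated (50 Monte-Carlo iterations) to estimate
accuracy, pooled ROC AUC with percentile confidence intervals, and
per-feature average importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .diffexp import mann_whitney_auc

__all__ = [
    "PlsModel",
    "ClassifierReport",
    "univariate_roc_ci",
    "plsda_fit",
    "vip_scores",
    "mccv_evaluate",
    "pca_scores_loadings",
]


def univariate_roc_ci(
    values: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 500,
    seed: Union[int, np.random.Generator] = 0,
) -> tuple[float, float, float]:
    """Bootstrap mean AUC with a percentile 95% CI for a single marker.

    The marker is oriented so the reported AUC is >= 0.5 (classification
    convention); resampling is stratified within class.  Returns
    ``(auc_mean, ci_low, ci_high)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    point = mann_whitney_auc(values, labels)
    oriented = values if point >= 0.5 else -values
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("both classes need >= 2 members")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate([rng.choice(pos, pos.size), rng.choice(neg, neg.size)])
        aucs[b] = mann_whitney_auc(oriented[take], labels[take])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(aucs.mean()), float(lo), float(hi)


@dataclass
class PlsModel:
    """A fitted PLS-DA model on standardized features.

    ``weights`` columns are unit-norm NIPALS weight vectors; ``scores``
    are the sample projections; ``explained_y_ss`` is the y
    sum-of-squares captured by each latent variable (the SS_a entering
    the VIP formula).  Prediction thresholds the continuous PLS score
    at the midpoint of the training class means.
    """

    n_components: int
    feature_names: list[str]
    weights: np.ndarray  # features x components, unit columns
    x_loadings: np.ndarray
    scores: np.ndarray  # samples x components
    y_loadings: np.ndarray  # components
    explained_y_ss: np.ndarray  # components
    explained_y_fraction: np.ndarray
    center: np.ndarray = field(repr=False)
    scale: np.ndarray = field(repr=False)
    threshold: float = 0.5
    _pls: PLSRegression = field(repr=False, default=None)

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Continuous PLS regression scores for new samples."""
        return self._pls.predict(self.transform_x(X)).ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard 0/1 class calls at the training-midpoint threshold."""
        return (self.decision_scores(X) > self.threshold).astype(int)


def plsda_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 2,
    feature_names: Optional[Sequence[str]] = None,
) -> PlsModel:
    """Fit PLS-DA (NIPALS) on column-standardized features.

    ``y`` is coded 0/1.  Zero-variance features are dropped from the
    model (their weights and VIP are zero) with a warning.  Raises if
    ``n_components`` exceeds ``min(n_samples - 1, n_features)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be samples x features matching y")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be coded 0/1")
    n, p = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds the rank bound min({n - 1}, {p})"
        )
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("feature_names length must match X columns")

    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    dead = sd == 0.0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance features dropped from the PLS model",
            stacklevel=2,
        )
    scale = np.where(dead, 1.0, sd)
    Xs = (X - center) / scale  # dead features become all-zero columns -> zero weights

    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(Xs, y)

    T = pls.x_scores_
    q = pls.y_loadings_.ravel()
    ss = (q**2) * (T**2).sum(axis=0)  # y sum-of-squares per latent variable
    ss_total = ((y - y.mean()) ** 2).sum()
    frac = ss / ss_total if ss_total > 0 else np.zeros_like(ss)

    W = pls.x_weights_.copy()
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W /= norms

    train_scores = pls.predict(Xs).ravel()
    mean1 = train_scores[y == 1].mean()
    mean0 = train_scores[y == 0].mean()
    model = PlsModel(
        n_components=n_components,
        feature_names=names,
        weights=W,
        x_loadings=pls.x_loadings_,
        scores=T,
        y_loadings=q,
        explained_y_ss=ss,
        explained_y_fraction=frac,
        center=center,
        scale=scale,
        threshold=float((mean0 + mean1) / 2.0),
        _pls=pls,
    )
    return model


def vip_scores(model: PlsModel) -> np.ndarray:
    """Variable importance in projection for every feature.

    ``VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a )``
    with p the feature count and SS_a the y sum-of-squares explained by
    latent variable a.  Satisfies ``sum_j VIP_j^2 = p``.
    """
    ss = model.explained_y_ss
    if ss.sum() <= 0:
        raise ValueError("model explains no y-variance; VIP undefined")
    p = len(model.feature_names)
    contrib = (model.weights**2) @ ss  # weights already unit-norm per component
    return np.sqrt(p * contrib / ss.sum())


@dataclass
class ClassifierReport:
    """MCCV panel-size evaluation summary.

    ``per_k`` has one row per panel size k: mean validation accuracy,
    pooled-validation AUC and the 2.5/97.5 percentile CI of per-
    iteration AUCs.  ``importance`` holds each feature's average VIP and
    selection frequency over iterations.  ``best_k`` is the smallest k
    attaining the maximum mean accuracy.
    """

    per_k: pd.DataFrame
    importance: pd.DataFrame
    best_k: int


def _stratified_split(
    y: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        perm = rng.permutation(members)
        n_train = int(round(train_frac * members.size))
        n_train = min(max(n_train, 1), members.size - 1)  # both sides non-empty per class
        train_idx.append(perm[:n_train])
        val_idx.append(perm[n_train:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def mccv_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    feature_counts: Sequence[int],
    n_iter: int = 50,
    n_components: int = 2,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
    train_frac: float = 2.0 / 3.0,
    importance: str = "all",
) -> ClassifierReport:
    """Balanced Monte-Carlo cross-validation of PLS-DA panels.

    Per iteration: a stratified 2/3 train / 1/3 validation split; a full
    PLS-DA fit on the training split ranks features by VIP (ties broken
    by input order, i.e. by protein identifier when the caller sorts
    columns); for each k the model is refit on the top-k features and
    scored on the validation third.  Accuracy is averaged over
    iterations; validation scores pooled over iterations form one ROC
    per k, with a CI from the 2.5/97.5 percentiles of per-iteration
    AUCs.  Per-iteration randomness comes from seeds spawned off the
    master ``seed`` with a counter (``SeedSequence([seed, i])``).

    ``importance='all'`` averages each feature's full-model VIP over all
    iterations, counting 0 when the feature was not selected (not in the
    top ``max(feature_counts)``); ``'selected'`` averages only over
    iterations where it was selected.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    feature_counts = sorted(set(int(k) for k in feature_counts))
    p = X.shape[1]
    if max(feature_counts) > p:
        raise ValueError(f"requested panel size {max(feature_counts)} > {p} features")
    if min(np.bincount(y)) < 3:
        raise ValueError("both classes need >= 3 members for 2/3-1/3 splits")
    if importance not in ("all", "selected"):
        raise ValueError("importance must be 'all' or 'selected'")
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(p)]

    k_max = max(feature_counts)
    acc = {k: [] for k in feature_counts}
    iter_auc = {k: [] for k in feature_counts}
    pooled_scores = {k: [] for k in feature_counts}
    pooled_labels = {k: [] for k in feature_counts}
    vip_sum = np.zeros(p)
    vip_count = np.zeros(p)
    selected = np.zeros(p)

    for i in range(n_iter):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        tr, va = _stratified_split(y, train_frac, rng)
        full = plsda_fit(
            X[tr], y[tr], n_components=min(n_components, min(tr.size - 1, p)), feature_names=names
        )
        vip = vip_scores(full)
        order = np.argsort(-vip, kind="stable")
        top = order[:k_max]
        selected[top] += 1
        if importance == "all":
            masked = np.zeros(p)
            masked[top] = vip[top]
            vip_sum += masked
            vip_count += 1
        else:
            vip_sum[top] += vip[top]
            vip_count[top] += 1

        for k in feature_counts:
            cols = order[:k]
            sub = plsda_fit(
                X[tr][:, cols],
                y[tr],
                n_components=min(n_components, k, tr.size - 1),
                feature_names=[names[j] for j in cols],
            )
            scores = sub.decision_scores(X[va][:, cols])
            preds = (scores > sub.threshold).astype(int)
            acc[k].append(float((preds == y[va]).mean()))
            iter_auc[k].append(mann_whitney_auc(scores, y[va]))
            pooled_scores[k].append(scores)
            pooled_labels[k].append(y[va])

    rows = []
    for k in feature_counts:
        pooled = mann_whitney_auc(
            np.concatenate(pooled_scores[k]), np.concatenate(pooled_labels[k])
        )
        lo, hi = np.percentile(iter_auc[k], [2.5, 97.5])
        rows.append(
            {
                "k": k,
                "accuracy": float(np.mean(acc[k])),
                "auc": pooled,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    per_k = pd.DataFrame(rows)
    best_acc = per_k["accuracy"].max()
    best_k = int(per_k.loc[per_k["accuracy"] == best_acc, "k"].min())

    with np.errstate(invalid="ignore"):
        mean_vip = np.where(vip_count > 0, vip_sum / np.maximum(vip_count, 1), 0.0)
    imp = pd.DataFrame(
        {
            "feature": names,
            "mean_vip": mean_vip,
            "selection_frequency": selected / n_iter,
        }
    ).sort_values("mean_vip", ascending=False, kind="stable").reset_index(drop=True)
    return ClassifierReport(per_k=per_k, importance=imp, best_k=best_k)


def pca_scores_loadings(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-centered SVD decomposition for biplots.

    Returns ``(scores, loadings, variance_fractions)`` with scores the
    left singular vectors scaled by singular values, orthonormal
    loadings, and the sign convention that the largest-magnitude
    loading of each component is positive.  Over the full rank the
    variance fractions are non-increasing and sum to 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("X must be samples x features with >= 3 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not Xc.any():
        raise ValueError("degenerate input: all samples identical after centering")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt.T
    for a in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            U[:, a] *= -1
    scores = U * S
    frac = S**2 / (S**2).sum()
    return scores, loadings, frac
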