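"""Per-protein bootstrap ROC with a permutation null and threshold-walk
q-values.

For every protein the discrimination between the positive group (PSP)
and a comparator group (or pooled union of groups) is summarized by the
ROC AUC under stratified bootstrap resampling (mean and SD over
``n_boot`` resamples).  The same bootstrap is repeated after a single
global permutation of the group labels (the permutation is shared by
all proteins, preserving inter-protein correlation), and q-values are
obtained by walking a threshold down the observed AUCs and taking the
ratio of permuted to observed exceedance counts, monotonized by a
running minimum.  Proteins with q below the cutoff are called up
(AUC > 0.5) or down (AUC < 0.5).
"""

from __future__ import annotations

from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import ROLE_CLINICAL, AbundanceMatrix, SampleMeta

__all__ = [
    "mann_whitney_auc",
    "bootstrap_auc",
    "bootstrap_auc_matrix",
    "permutation_qvalues",
    "run_differential",
]


def mann_whitney_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC as the normalized Mann-Whitney U statistic.

    ``auc = [#(pos > neg) + 0.5 * #(pos == neg)] / (n_pos * n_neg)``,
    with the positive class marked by ``labels == 1`` (truthy).  Ties
    count one half via midranks.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.ndim != 1 or values.shape != labels.shape:
        raise ValueError("values and labels must be 1-D and equally long")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(values)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _auc_rows(X: np.ndarray, n_pos: int) -> np.ndarray:
    """Row-wise AUC for a matrix whose first ``n_pos`` columns are the
    positive class (midrank tie handling)."""
    ranks = rankdata(X, axis=1, method="average")
    n_neg = X.shape[1] - n_pos
    u = ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def bootstrap_auc_matrix(
    X: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 500,
    seed: Union[int, np.random.Generator] = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified bootstrap AUC mean/SD for every row of ``X`` at once.

    Each bootstrap resamples the positive and negative class separately,
    with replacement, to their own sizes; one set of resample indices is
    shared across rows (each row's marginal distribution is the same as
    under independent per-row resampling).  Returns ``(auc_mean,
    auc_sd)`` arrays; SD uses the n-1 denominator.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=bool)
    if X.shape[1] != labels.size:
        raise ValueError("labels length must match number of columns")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("both classes need >= 2 members for the bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aucs = np.empty((n_boot, X.shape[0]))
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)]
        )
        aucs[b] = _auc_rows(X[:, take], n_pos=pos.size)
    return aucs.mean(axis=0), aucs.std(axis=0, ddof=1)


def bootstrap_auc(
    values: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 500,
    seed: Union[int, np.random.Generator] = 0,
) -> tuple[float, float]:
    """Stratified bootstrap mean and SD of the AUC for one marker."""
    mean, sd = bootstrap_auc_matrix(
        np.asarray(values, dtype=float)[None, :], labels, n_boot=n_boot, seed=seed
    )
    return float(mean[0]), float(sd[0])


def permutation_qvalues(
    observed: np.ndarray, permuted: np.ndarray, n_permutations: int = 1
) -> np.ndarray:
    """q-values from a threshold walk over observed vs permuted AUCs.

    Two independent branches: proteins with observed mean AUC above 0.5
    are walked downward from the top (thresholds at each observed
    value, counts inclusive ``>=``), proteins below 0.5 are mirrored
    (ascending walk, ``<=``).  At each threshold the false-discovery
    ratio is ``#(permuted beyond t) / n_permutations / #(observed
    beyond t)``; a protein's q is the running minimum of that ratio over
    thresholds at or below its own extremeness (the standard q-value
    monotonization), clipped to [0, 1].  Proteins at exactly 0.5 get
    q = 1.

    ``permuted`` may hold values pooled from several permutations, in
    which case ``n_permutations`` scales the numerator.
    """
    observed = np.asarray(observed, dtype=float)
    permuted = np.asarray(permuted, dtype=float)
    if observed.ndim != 1 or permuted.ndim != 1:
        raise ValueError("observed and permuted must be 1-D")
    if permuted.size != observed.size * n_permutations:
        raise ValueError(
            "permuted must hold n_permutations values per observed protein "
            f"({observed.size} x {n_permutations} != {permuted.size})"
        )
    q = np.ones_like(observed)
    perm_sorted = np.sort(permuted)

    upper = observed > 0.5
    if upper.any():
        vals = observed[upper]
        order = np.argsort(-vals, kind="stable")
        v = vals[order]
        n_obs_ge = np.searchsorted(-v, -v, side="right")  # inclusive >= with ties
        n_perm_ge = permuted.size - np.searchsorted(perm_sorted, v, side="left")
        fdr = (n_perm_ge / n_permutations) / n_obs_ge
        qs = np.minimum.accumulate(fdr[::-1])[::-1]  # running min, least-extreme end up
        out = np.empty_like(qs)
        out[order] = qs
        q[upper] = out

    lower = observed < 0.5
    if lower.any():
        vals = observed[lower]
        order = np.argsort(vals, kind="stable")
        v = vals[order]
        n_obs_le = np.searchsorted(v, v, side="right")
        n_perm_le = np.searchsorted(perm_sorted, v, side="right")
        fdr = (n_perm_le / n_permutations) / n_obs_le
        qs = np.minimum.accumulate(fdr[::-1])[::-1]
        out = np.empty_like(qs)
        out[order] = qs
        q[lower] = out

    return np.clip(q, 0.0, 1.0)


def run_differential(
    matrix: AbundanceMatrix,
    design: Sequence[SampleMeta],
    comparison: tuple[str, Iterable[str]] = ("PSP", ("PD", "HC")),
    n_boot: int = 500,
    q_cutoff: float = 0.01,
    n_permutations: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap-ROC differential abundance over a corrected matrix.

    ``comparison = (positive_group, comparator_groups)``; the comparator
    may pool several groups (e.g. PD plus HC) with equal per-sample
    weight.  Returns one row per protein with columns ``auc_mean``,
    ``auc_sd``, ``q_value`` and ``direction`` (up / down / null),
    sorted by q then by |AUC - 0.5| descending.  Deterministic given
    ``seed``.
    """
    positive, comparators = comparison
    comparators = tuple(comparators)
    if not comparators:
        raise ValueError("comparator group set is empty")
    meta = {s.sample_id: s for s in design}
    known_groups = {s.diagnosis for s in design if s.role == ROLE_CLINICAL}
    for g in (positive, *comparators):
        if g not in known_groups:
            raise ValueError(f"unknown group label {g!r}")

    cols, labels = [], []
    for c in matrix.sample_ids:
        s = meta.get(c)
        if s is None or s.role != ROLE_CLINICAL:
            continue
        if s.diagnosis == positive:
            cols.append(c)
            labels.append(True)
        elif s.diagnosis in comparators:
            cols.append(c)
            labels.append(False)
    labels = np.array(labels, dtype=bool)
    if labels.sum() == 0 or (~labels).sum() == 0:
        raise ValueError("comparison groups not present in the matrix")

    X = matrix.data[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix must be complete (run filter_complete first)")

    rng = np.random.default_rng(seed)
    auc_mean, auc_sd = bootstrap_auc_matrix(X, labels, n_boot=n_boot, seed=rng)

    perm_means = []
    for _ in range(n_permutations):
        perm_labels = rng.permutation(labels)  # one global permutation, all proteins
        pm, _ = bootstrap_auc_matrix(X, perm_labels, n_boot=n_boot, seed=rng)
        perm_means.append(pm)
    q = permutation_qvalues(
        auc_mean, np.concatenate(perm_means), n_permutations=n_permutations
    )

    direction = np.where(
        (q < q_cutoff) & (auc_mean > 0.5),
        "up",
        np.where((q < q_cutoff) & (auc_mean < 0.5), "down", "null"),
    )
    table = pd.DataFrame(
        {
            "protein_id": matrix.protein_ids,
            "auc_mean": auc_mean,
            "auc_sd": auc_sd,
            "q_value": q,
            "direction": direction,
        }
    )
    table["_extremity"] = (table["auc_mean"] - 0.5).abs()
    table = (
        table.sort_values(["q_value", "_extremity"], ascending=[True, False], kind="stable")
        .drop(columns="_extremity")
        .reset_index(drop=True)
    )
    return table
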