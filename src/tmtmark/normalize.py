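"""Two-step normalization, complete-case filtering and QC metrics.

The normalization mirrors standard practice for large multi-batch TMT
studies: reporter abundances are first expressed as log2 ratios to the
master pool carried in every batch (removing the dominant, protein-wise
multiplicative batch effect), then residual batch location/scale effects
are harmonized with parametric empirical-Bayes batch correction
(ComBat).  Missing values are never imputed: proteins not quantified in
every sample are dropped (complete-case analysis).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ROLE_CLINICAL,
    ROLE_MASTER_POOL,
    ROLE_QC,
    SCALE_LOG2_CORRECTED,
    SCALE_LOG2_RATIO,
    SCALE_RAW,
    AbundanceMatrix,
    QcMetrics,
    SampleMeta,
)


def _sample_map(design: Sequence[SampleMeta]) -> dict[str, SampleMeta]:
    return {s.sample_id: s for s in design}


def mp_normalize(raw: AbundanceMatrix, design: Sequence[SampleMeta]) -> AbundanceMatrix:
    """Express every channel as the log2 ratio to its batch master pool.

    ``value[p, s] = log2(raw[p, s] / raw[p, MP(batch(s))])``.  Missing
    raw values propagate.  If the master-pool value for a protein is
    missing or non-positive, that protein becomes missing for the whole
    batch (with a warning).  Master-pool columns are dropped from the
    output; the scale advances to ``log2_ratio``.
    """
    if raw.scale != SCALE_RAW:
        raise ValueError(f"mp_normalize expects a raw matrix, got scale {raw.scale!r}")
    meta = _sample_map(design)
    missing_meta = [c for c in raw.sample_ids if c not in meta]
    if missing_meta:
        raise ValueError(f"samples missing from design: {missing_meta[:5]}")

    mp_by_batch: dict[int, str] = {}
    for s in design:
        if s.role == ROLE_MASTER_POOL and s.sample_id in raw.data.columns:
            if s.batch in mp_by_batch:
                raise ValueError(f"batch {s.batch} has more than one master-pool column")
            mp_by_batch[s.batch] = s.sample_id

    out = {}
    n_bad_mp = 0
    for col in raw.sample_ids:
        s = meta[col]
        if s.role == ROLE_MASTER_POOL:
            continue
        if s.batch not in mp_by_batch:
            raise ValueError(f"batch {s.batch} has no master-pool column in the matrix")
        mp = raw.data[mp_by_batch[s.batch]].to_numpy(dtype=float)
        bad = ~(mp > 0)  # NaN or non-positive master-pool entries
        n_bad_mp += int(bad.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.log2(raw.data[col].to_numpy(dtype=float) / mp)
        ratio[bad] = np.nan
        out[col] = ratio
    if n_bad_mp:
        warnings.warn(
            "master-pool value missing or non-positive for some (protein, batch) pairs; "
            "those entries were set to missing",
            stacklevel=2,
        )
    return AbundanceMatrix(pd.DataFrame(out, index=raw.data.index), SCALE_LOG2_RATIO)


def filter_complete(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Keep exactly the proteins quantified in every sample (row order
    preserved).  May return an empty matrix."""
    keep = ~matrix.data.isna().any(axis=1)
    return AbundanceMatrix(matrix.data.loc[keep].copy(), matrix.scale)


def combat_correct(
    matrix: AbundanceMatrix, design: Sequence[SampleMeta]
) -> AbundanceMatrix:
    """Remove residual batch location/scale effects by parametric
    empirical-Bayes adjustment (the published ComBat algorithm).

    Per protein the data are standardized to grand mean / pooled
    variance, per-batch location and scale estimates are shrunk toward
    batch-level priors (normal / inverse-gamma, moment-matched), and the
    adjusted values are back-transformed.  No covariates enter the
    model: block randomization is what protects the group signal, and a
    warning is emitted if diagnosis groups are visibly unbalanced across
    batches.  Zero-variance proteins are left unchanged (with a
    warning).  Requires a complete matrix and >= 2 samples per batch.
    """
    if matrix.scale not in (SCALE_LOG2_RATIO, SCALE_LOG2_CORRECTED):
        raise ValueError("combat_correct expects a log2-scale matrix (run mp_normalize first)")
    if matrix.data.isna().any().any():
        raise ValueError("matrix must be complete (run filter_complete first)")
    meta = _sample_map(design)
    try:
        batches = np.array([meta[c].batch for c in matrix.sample_ids])
    except KeyError as e:
        raise ValueError(f"sample missing from design: {e}") from e

    unique, counts = np.unique(batches, return_counts=True)
    if (counts < 2).any():
        small = unique[counts < 2].tolist()
        raise ValueError(f"batches with fewer than 2 samples cannot be corrected: {small}")

    _warn_if_groups_unbalanced(matrix.sample_ids, meta, batches)

    if len(unique) == 1:
        return AbundanceMatrix(matrix.data.copy(), SCALE_LOG2_CORRECTED)

    values = matrix.data.to_numpy(dtype=float)
    row_var = values.var(axis=1)
    constant = row_var == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance proteins left unchanged by batch correction",
            stacklevel=2,
        )

    corrected = values.copy()
    if (~constant).any():
        import anndata as ad

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import scanpy as sc

            adata = ad.AnnData(
                X=values[~constant].T.astype(np.float64),
                obs=pd.DataFrame(
                    {"batch": pd.Categorical([str(b) for b in batches])},
                    index=matrix.sample_ids,
                ),
            )
            sc.pp.combat(adata, key="batch")
        corrected[~constant] = adata.X.T
    return AbundanceMatrix(
        pd.DataFrame(corrected, index=matrix.data.index, columns=matrix.data.columns),
        SCALE_LOG2_CORRECTED,
    )


def _warn_if_groups_unbalanced(
    sample_ids: Sequence[str], meta: dict[str, SampleMeta], batches: np.ndarray
) -> None:
    """Batch correction without a group covariate can absorb group signal
    if diagnosis groups are unevenly spread over batches; warn then."""
    table: dict[tuple[int, str], int] = {}
    diagnoses = set()
    for sid, b in zip(sample_ids, batches):
        s = meta[sid]
        if s.role == ROLE_CLINICAL:
            diagnoses.add(s.diagnosis)
            table[(b, s.diagnosis)] = table.get((b, s.diagnosis), 0) + 1
    for g in diagnoses:
        per_batch = [table.get((b, g), 0) for b in np.unique(batches)]
        if per_batch and max(per_batch) - min(per_batch) > 1:
            warnings.warn(
                "diagnosis groups are unbalanced across batches; batch correction "
                "without a group covariate may absorb group signal",
                stacklevel=3,
            )
            return


def compute_qc_metrics(
    matrix: AbundanceMatrix, design: Sequence[SampleMeta]
) -> QcMetrics:
    """Per-protein CV (from un-logged QC values) and signal-to-noise.

    The CV is SD/mean of ``2**value`` over QC channels (sample SD, n-1
    denominator).  S/N is the per-protein ratio of the clinical log2 SD
    (biological + technical variation) to the QC log2 SD (technical
    only); a QC SD of exactly zero yields a +inf sentinel with a
    warning.  Requires >= 2 QC and >= 2 clinical columns.
    """
    if matrix.scale not in (SCALE_LOG2_RATIO, SCALE_LOG2_CORRECTED):
        raise ValueError("compute_qc_metrics expects a log2-scale matrix")
    meta = _sample_map(matrix_design_subset(matrix, design))
    qc_cols = [c for c in matrix.sample_ids if meta[c].role == ROLE_QC]
    clin_cols = [c for c in matrix.sample_ids if meta[c].role == ROLE_CLINICAL]
    if len(qc_cols) < 2:
        raise ValueError(f"need >= 2 QC columns, found {len(qc_cols)}")
    if len(clin_cols) < 2:
        raise ValueError(f"need >= 2 clinical columns, found {len(clin_cols)}")

    qc_log2 = matrix.data[qc_cols].to_numpy(dtype=float)
    clin_log2 = matrix.data[clin_cols].to_numpy(dtype=float)
    qc_lin = np.exp2(qc_log2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cv = np.nanstd(qc_lin, axis=1, ddof=1) / np.nanmean(qc_lin, axis=1)
        sd_qc = np.nanstd(qc_log2, axis=1, ddof=1)
        sd_clin = np.nanstd(clin_log2, axis=1, ddof=1)
    n_qc_obs = (~np.isnan(qc_log2)).sum(axis=1)
    defined = n_qc_obs >= 2

    zero_sd = defined & (sd_qc == 0.0)
    if zero_sd.any():
        warnings.warn(
            f"{int(zero_sd.sum())} proteins have zero QC SD; S/N reported as +inf",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sd_qc > 0, sd_clin / sd_qc, np.inf)
    table = pd.DataFrame(
        {"cv": cv, "sd_clinical": sd_clin, "sd_qc": sd_qc, "snr": snr},
        index=matrix.data.index,
    ).loc[defined]
    return QcMetrics(table)


def matrix_design_subset(
    matrix: AbundanceMatrix, design: Sequence[SampleMeta]
) -> list[SampleMeta]:
    """Design entries for the samples present in the matrix, validating
    that none are unknown."""
    meta = {s.sample_id: s for s in design}
    out = []
    for c in matrix.sample_ids:
        if c not in meta:
            raise ValueError(f"sample {c!r} missing from design")
        out.append(meta[c])
    return out


def pca_batch_diagnostic(
    matrix: AbundanceMatrix,
    design: Optional[Sequence[SampleMeta]] = None,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the leading principal components, for visual
    batch-effect assessment.

    Proteins (features) are mean-centered; no scaling.  Returns a
    DataFrame of per-sample scores (columns ``PC1..PCk`` plus ``batch``
    when a design is given) and the per-component explained-variance
    fractions (which sum to <= 1).
    """
    if matrix.n_samples < 3:
        raise ValueError("PCA diagnostic needs at least 3 samples")
    if matrix.data.isna().any().any():
        raise ValueError("matrix must be complete")
    X = matrix.data.to_numpy(dtype=float).T  # samples x proteins
    Xc = X - X.mean(axis=0, keepdims=True)
    n_components = min(n_components, min(Xc.shape))
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * S[:n_components]
    total = (Xc**2).sum()
    frac = (S[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    df = pd.DataFrame(
        scores, index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    if design is not None:
        meta = _sample_map(design)
        df["batch"] = [meta[c].batch if c in meta else None for c in matrix.sample_ids]
    return df, frac
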