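"""Shared data containers for the TMT biomarker-discovery pipeline.

The pipeline moves protein-by-sample abundance tables through a fixed
sequence of scale states:

``raw``
    reporter-ion style intensities, strictly positive where present,
    missing values allowed;
``log2_ratio``
    log2 of the sample/master-pool ratio within each batch (missing
    values propagate from raw);
``log2_corrected``
    the same values after empirical-Bayes batch correction (complete,
    no missing values).

:class:`AbundanceMatrix` enforces those states so a function can declare
which stage of the pipeline it expects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

ROLE_CLINICAL = "clinical"
ROLE_MASTER_POOL = "master_pool"
ROLE_QC = "qc"
ROLES = (ROLE_CLINICAL, ROLE_MASTER_POOL, ROLE_QC)

DIAGNOSES = ("PSP", "PD", "HC")
SEXES = ("F", "M")

SCALE_RAW = "raw"
SCALE_LOG2_RATIO = "log2_ratio"
SCALE_LOG2_CORRECTED = "log2_corrected"
SCALES = (SCALE_RAW, SCALE_LOG2_RATIO, SCALE_LOG2_CORRECTED)


@dataclass
class SampleMeta:
    """Identity, demographics and multiplex placement of one sample.

    Clinical samples carry a diagnosis, sex and age; master-pool and QC
    entries are pooled/aliquoted material and carry none.  ``batch`` and
    ``channel`` are unset until the sample has been placed on a plex by
    :func:`tmtmark.simulate.block_randomize`.
    """

    sample_id: str
    role: str = ROLE_CLINICAL
    diagnosis: Optional[str] = None
    sex: Optional[str] = None
    age: Optional[float] = None
    batch: Optional[int] = None
    channel: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == ROLE_CLINICAL:
            if self.diagnosis is None or self.sex is None or self.age is None:
                raise ValueError(
                    f"clinical sample {self.sample_id!r} must carry diagnosis, sex and age"
                )
            if self.age <= 0:
                raise ValueError(f"age must be positive, got {self.age}")
        else:
            if self.diagnosis is not None or self.sex is not None or self.age is not None:
                raise ValueError(
                    f"{self.role} sample {self.sample_id!r} must not carry demographics"
                )


def validate_design(design: Sequence[SampleMeta], channels: Optional[Sequence[str]] = None) -> None:
    """Check the placement invariants of a finished multiplex design.

    Raises ``ValueError`` if a batch lacks exactly one master pool, the
    master pool is not on the last channel, or a (batch, channel) slot
    is used twice.
    """
    placed = [s for s in design if s.batch is not None]
    by_batch: dict[int, list[SampleMeta]] = {}
    for s in placed:
        by_batch.setdefault(s.batch, []).append(s)
    for b, members in sorted(by_batch.items()):
        mps = [s for s in members if s.role == ROLE_MASTER_POOL]
        if len(mps) != 1:
            raise ValueError(f"batch {b} has {len(mps)} master-pool entries, expected 1")
        if channels is not None and mps[0].channel != channels[-1]:
            raise ValueError(
                f"batch {b}: master pool on channel {mps[0].channel!r}, expected {channels[-1]!r}"
            )
        slots = [s.channel for s in members]
        if len(slots) != len(set(slots)):
            raise ValueError(f"batch {b} assigns a channel more than once")


@dataclass
class AbundanceMatrix:
    """Proteins x samples abundance values with an explicit scale state.

    ``data`` is a DataFrame indexed by protein identifier with one column
    per sample identifier.  Raw values must be strictly positive where
    present; missing values (NaN) are allowed on the ``raw`` and
    ``log2_ratio`` scales only.
    """

    data: pd.DataFrame
    scale: str = SCALE_RAW

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("protein and sample identifiers must be unique")
        vals = self.data.to_numpy(dtype=float)
        if self.scale == SCALE_RAW:
            present = ~np.isnan(vals)
            if np.any(vals[present] <= 0):
                raise ValueError("raw abundance values must be strictly positive where present")
        elif self.scale == SCALE_LOG2_CORRECTED:
            if np.isnan(vals).any():
                raise ValueError("batch-corrected matrix must be complete")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.scale)


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated abundance matrix.

    ``effect`` is the signed log2 group effect per protein (exactly 0 for
    non-differential proteins, +/- delta otherwise); ``sigma`` the
    per-protein residual SD of clinical channels on the log2 scale;
    ``batch_shift`` the additive log2 offset per (protein, batch);
    ``batch_scale`` the per-batch multiplicative inflation of technical
    noise SD.
    """

    protein_ids: list[str]
    baseline: np.ndarray
    effect: np.ndarray
    sigma: np.ndarray
    batch_shift: pd.DataFrame  # proteins x batches
    batch_scale: pd.Series  # per batch
    missing_rate: float
    affected_group: str = "PSP"

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if np.any(self.batch_scale.to_numpy() <= 0):
            raise ValueError("batch_scale must be positive")

    @property
    def is_differential(self) -> np.ndarray:
        return self.effect != 0.0


@dataclass
class QcMetrics:
    """Per-protein technical-variation summary from embedded QC channels.

    ``table`` is indexed by protein id with columns ``cv`` (SD/mean of
    un-logged QC values), ``sd_clinical``, ``sd_qc`` (SDs of log2
    values), and ``snr`` (sd_clinical / sd_qc; +inf sentinel when the QC
    SD is exactly zero).
    """

    table: pd.DataFrame

    def summary(self, percentiles: Sequence[float] = (0.5, 0.95)) -> pd.DataFrame:
        """Distribution summary excluding non-finite sentinel values."""
        finite = self.table.replace([np.inf, -np.inf], np.nan)
        return finite.describe(percentiles=list(percentiles))
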