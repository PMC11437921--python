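"""Synthetic cohorts, block-randomized TMT designs and abundance matrices.

This module generates data with the statistical structure of a
three-group CSF biomarker study quantified by multi-batch isobaric
labeling (11-plex TMT): 40 PSP, 40 PD and 40 healthy-control samples
spread over 13 batches, a master pool (an equal-volume mix of all
clinical samples) in the last channel of every batch, and a QC aliquot
embedded in 10 of the 13 batches.  Every generated matrix comes with a
:class:`~tmtmark.datatypes.SimulationTruth` recording which proteins are
differential, so downstream statistics can be validated against known
ground truth.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DIAGNOSES,
    ROLE_CLINICAL,
    ROLE_MASTER_POOL,
    ROLE_QC,
    SCALE_RAW,
    AbundanceMatrix,
    SampleMeta,
    SimulationTruth,
)

#: Reporter channels of an 11-plex TMT kit, in labeling order.  The
#: master pool occupies the last channel (131C).
CHANNELS_11PLEX = (
    "126", "127N", "127C", "128N", "128C",
    "129N", "129C", "130N", "130C", "131", "131C",
)

#: Cohort demographics used as generator defaults (group mean age in
#: years and proportion of female participants).
DEFAULT_AGE_MEAN = {"HC": 67.7, "PD": 64.1, "PSP": 68.8}
DEFAULT_FEMALE_PROP = {"HC": 0.675, "PD": 0.475, "PSP": 0.60}
#: Age SD back-computed from the group 95% CIs (half-width ~2.2 y, n=40).
DEFAULT_AGE_SD = 7.1

MIN_AGE = 18.0


def generate_cohort(
    n_per_group: int,
    age_mean_by_group: Optional[Dict[str, float]] = None,
    age_sd: float = DEFAULT_AGE_SD,
    female_prop_by_group: Optional[Dict[str, float]] = None,
    seed: int = 0,
) -> list[SampleMeta]:
    """Draw a clinical cohort of ``3 * n_per_group`` samples.

    Ages are normal per group (truncated below at 18 years).  Sex counts
    are fixed at the expected counts ``round(n_per_group * prop)`` per
    group with randomized ordering, mirroring a real recruited cohort
    table rather than a Bernoulli draw.

    Parameters
    ----------
    n_per_group
        Samples per diagnosis group (>= 1).
    age_mean_by_group, female_prop_by_group
        Maps keyed by diagnosis; default to the package's cohort table.
    age_sd
        Common age SD in years.
    seed
        Seeds all randomness; identical seeds give identical cohorts.
    """
    if n_per_group < 1:
        raise ValueError(f"n_per_group must be >= 1, got {n_per_group}")
    age_means = dict(DEFAULT_AGE_MEAN if age_mean_by_group is None else age_mean_by_group)
    female_props = dict(
        DEFAULT_FEMALE_PROP if female_prop_by_group is None else female_prop_by_group
    )
    for g, p in female_props.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"female proportion for {g} must be in [0, 1], got {p}")

    rng = np.random.default_rng(seed)
    cohort: list[SampleMeta] = []
    for group in DIAGNOSES:
        ages = rng.normal(age_means[group], age_sd, size=n_per_group)
        ages = np.maximum(ages, MIN_AGE)
        n_female = int(round(n_per_group * female_props[group]))
        sexes = np.array(["F"] * n_female + ["M"] * (n_per_group - n_female))
        rng.shuffle(sexes)
        for i in range(n_per_group):
            cohort.append(
                SampleMeta(
                    sample_id=f"{group}-{i + 1:03d}",
                    role=ROLE_CLINICAL,
                    diagnosis=group,
                    sex=str(sexes[i]),
                    age=float(ages[i]),
                )
            )
    return cohort


def _greedy_quota(
    n_items: int,
    capacity: np.ndarray,
    tie_fill: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Distribute ``n_items`` over batches one at a time, always topping
    up a batch with the fewest items of this stratum (ties broken by the
    lowest ``tie_fill + quota``, then at random), subject to the
    remaining per-batch ``capacity``.  Guarantees a per-batch spread of
    at most one whenever capacity allows."""
    quota = np.zeros_like(capacity)
    for _ in range(n_items):
        feasible = np.flatnonzero(capacity - quota > 0)
        if feasible.size == 0:
            raise ValueError("insufficient batch capacity during allocation")
        own = quota[feasible]
        cand = feasible[own == own.min()]
        total = tie_fill[cand] + quota[cand]
        best = cand[total == total.min()]
        quota[rng.choice(best)] += 1
    return quota


def _interleaved_group_quota(
    group_sizes: dict[str, int],
    counts: np.ndarray,
    rng: np.random.Generator,
    max_attempts: int = 20,
) -> dict[str, np.ndarray]:
    """Joint per-(group, batch) quota allocation.

    Items are placed one at a time, always drawing from the group with
    the most members left, into the feasible batch with the fewest
    members of that group (ties: most remaining capacity, then random).
    Interleaving the groups keeps capacity consumption even so no group
    is forced into leftover slots.  The result is verified (per-group
    spread over batches <= 1) and reallocated with fresh randomness on
    the rare capacity-forced violation."""
    best = None
    for _ in range(max_attempts):
        quota = {g: np.zeros_like(counts) for g in group_sizes}
        left = dict(group_sizes)
        cap_left = counts.copy()
        while any(v > 0 for v in left.values()):
            most = max(left.values())
            g = rng.choice(sorted(k for k, v in left.items() if v == most))
            feasible = np.flatnonzero(cap_left > 0)
            own = quota[g][feasible]
            cand = feasible[own == own.min()]
            room = cap_left[cand]
            pick = rng.choice(cand[room == room.max()])
            quota[g][pick] += 1
            cap_left[pick] -= 1
            left[g] -= 1
        spread = max(int(q.max() - q.min()) for q in quota.values())
        if best is None or spread < best[0]:
            best = (spread, quota)
        if spread <= 1:
            break
    return best[1]


def block_randomize(
    cohort: Sequence[SampleMeta],
    n_batches: int,
    channels: Sequence[str] = CHANNELS_11PLEX,
    n_qc_batches: int = 0,
    seed: int = 0,
    n_restarts: int = 50,
    n_swaps: int = 500,
) -> list[SampleMeta]:
    """Assign clinical samples to batches/channels, balanced on
    diagnosis, sex and age, and add master-pool and QC entries.

    Each batch receives exactly one master pool on the last channel; a
    QC aliquot goes to a random non-master-pool channel in exactly
    ``n_qc_batches`` randomly chosen batches.  Diagnosis and sex counts
    per batch are balanced to within one of proportional allocation by
    construction; batch mean ages are balanced by a randomized-restart
    dealing pass (best of ``n_restarts``) followed by a same-stratum
    swap hill-climb (``n_swaps`` proposals) minimizing the sum of
    squared standardized batch age-mean deviations.

    Returns a new list: placed copies of the clinical samples followed
    by the master-pool and QC entries, ordered by batch and channel.
    """
    clinical = [s for s in cohort if s.role == ROLE_CLINICAL]
    if not clinical:
        raise ValueError("cohort contains no clinical samples")
    if n_qc_batches > n_batches:
        raise ValueError("n_qc_batches cannot exceed n_batches")
    n_channels = len(channels)
    capacity = n_batches * n_channels
    demand = len(clinical) + n_batches + n_qc_batches
    if demand > capacity:
        raise ValueError(
            f"infeasible design: {len(clinical)} clinical + {n_batches} MP + "
            f"{n_qc_batches} QC > {n_batches} x {n_channels} slots"
        )

    rng = np.random.default_rng(seed)
    batches = np.arange(1, n_batches + 1)
    qc_batches = set(
        int(b) for b in rng.choice(batches, size=n_qc_batches, replace=False)
    )
    # clinical capacity per batch after reserving MP (and QC where present)
    cap = np.array(
        [n_channels - 1 - (1 if b in qc_batches else 0) for b in batches], dtype=int
    )
    if cap.min() < 0:
        raise ValueError("too few channels to host master pool and QC")

    # per-batch clinical counts: even-fill allocation respecting capacity
    counts = _greedy_quota(len(clinical), cap, np.zeros_like(cap), rng)

    # group quotas per batch, then sex quotas within each group
    groups = sorted({s.diagnosis for s in clinical})
    by_group = {g: [s for s in clinical if s.diagnosis == g] for g in groups}
    group_quota = _interleaved_group_quota(
        {g: len(by_group[g]) for g in groups}, counts, rng
    )

    # within each group, split the quota between sexes, balancing the
    # *overall* per-batch female count
    female_fill = np.zeros_like(counts)
    cell_quota: dict[tuple[str, str], np.ndarray] = {}
    for g in groups:
        females = [s for s in by_group[g] if s.sex == "F"]
        fq = _greedy_quota(len(females), group_quota[g], female_fill, rng)
        cell_quota[(g, "F")] = fq
        cell_quota[(g, "M")] = group_quota[g] - fq
        female_fill = female_fill + fq

    # deal members of each (group, sex) cell into batches; restart with
    # fresh shuffles and keep the assignment with the best age balance
    cohort_ages = np.array([s.age for s in clinical])
    age_mean, age_sd = cohort_ages.mean(), max(cohort_ages.std(), 1e-9)

    def deal(cell_rng: np.random.Generator) -> dict[int, list[SampleMeta]]:
        assign: dict[int, list[SampleMeta]] = {int(b): [] for b in batches}
        for (g, sex), quota in cell_quota.items():
            members = [s for s in by_group[g] if s.sex == sex]
            order = cell_rng.permutation(len(members))
            pos = 0
            for bi, q in enumerate(quota):
                for _ in range(int(q)):
                    assign[int(batches[bi])].append(members[order[pos]])
                    pos += 1
        return assign

    def score(assign: dict[int, list[SampleMeta]]) -> float:
        total = 0.0
        for b, members in assign.items():
            if members:
                z = (np.mean([s.age for s in members]) - age_mean) / age_sd
                total += len(members) * z * z
        return total

    best_assign, best_score = None, math.inf
    for _ in range(max(1, n_restarts)):
        a = deal(rng)
        sc = score(a)
        if sc < best_score:
            best_assign, best_score = a, sc
    assert best_assign is not None

    # same-(group, sex) swap hill-climb to tighten per-batch mean ages
    flat = [(b, i) for b, members in best_assign.items() for i in range(len(members))]
    for _ in range(n_swaps):
        if len(flat) < 2:
            break
        (b1, i1), (b2, i2) = (flat[k] for k in rng.choice(len(flat), size=2, replace=False))
        if b1 == b2:
            continue
        s1, s2 = best_assign[b1][i1], best_assign[b2][i2]
        if (s1.diagnosis, s1.sex) != (s2.diagnosis, s2.sex):
            continue
        before = score(best_assign)
        best_assign[b1][i1], best_assign[b2][i2] = s2, s1
        if score(best_assign) >= before:
            best_assign[b1][i1], best_assign[b2][i2] = s1, s2  # revert

    # channel placement: MP last, QC random non-MP channel, clinical shuffled
    design: list[SampleMeta] = []
    for b in batches:
        b = int(b)
        members = best_assign[b]
        open_channels = list(channels[:-1])
        perm = rng.permutation(len(open_channels))
        slots = [open_channels[i] for i in perm]
        if b in qc_batches:
            qc_channel = slots.pop(0)
        if len(members) > len(slots):
            raise AssertionError("internal allocation error: batch over capacity")
        placed = []
        for s, ch in zip(members, slots):
            placed.append(
                SampleMeta(
                    sample_id=s.sample_id, role=ROLE_CLINICAL, diagnosis=s.diagnosis,
                    sex=s.sex, age=s.age, batch=b, channel=ch,
                )
            )
        if b in qc_batches:
            placed.append(
                SampleMeta(sample_id=f"QC-b{b:02d}", role=ROLE_QC, batch=b, channel=qc_channel)
            )
        placed.append(
            SampleMeta(
                sample_id=f"MP-b{b:02d}", role=ROLE_MASTER_POOL, batch=b, channel=channels[-1]
            )
        )
        order = {ch: k for k, ch in enumerate(channels)}
        placed.sort(key=lambda s: order[s.channel])
        design.extend(placed)
    n_placed = sum(1 for s in design if s.role == ROLE_CLINICAL)
    if n_placed != len(clinical):
        raise AssertionError(
            f"internal allocation error: placed {n_placed} of {len(clinical)} clinical samples"
        )
    return design


def simulate_tmt(
    design: Sequence[SampleMeta],
    n_proteins: int = 1409,
    frac_differential: float = 0.17,
    delta: float = 0.433,
    sigma: float = 0.338,
    batch_shift_sd: float = 0.25,
    missing_rate: float = 0.007,
    seed: int = 0,
    *,
    tech_sd: float = 0.10,
    batch_scale_sd: float = 0.0,
    baseline_mean: float = 16.0,
    baseline_sd: float = 3.0,
    affected_group: str = "PSP",
) -> tuple[AbundanceMatrix, SimulationTruth]:
    """Simulate a raw TMT-style abundance matrix over a finished design.

    The generative model, all on the log2 scale:

    * per-protein baseline ``N(baseline_mean, baseline_sd**2)``;
    * a fraction ``frac_differential`` of proteins carries a signed
      effect ``+/- delta`` in the affected group (half up, half down);
    * clinical channel ``= baseline + effect + N(0, sigma)`` --- sigma
      is the *total* per-channel SD (biological plus technical), which
      is how it is estimated from real TMT experiments;
    * the master pool is the linear-scale mean of all clinical true
      abundances (an equal-volume mix), measured per batch with
      technical noise ``N(0, tech_sd)``;
    * the QC channel shares one fixed latent profile (one control
      donor, no group effect) across batches, measured with technical
      noise;
    * every channel in batch ``b`` receives the additive shift
      ``batch_shift[p, b] ~ N(0, batch_shift_sd)`` (a multiplicative
      batch effect on the raw scale); ``batch_scale_sd > 0``
      additionally inflates technical noise per batch (log-normal).

    Raw values are ``2**log2_value``; entries of clinical and QC
    channels (never the master pool) are masked missing-completely-at-
    random at ``missing_rate``.

    Returns the raw :class:`AbundanceMatrix` and the
    :class:`SimulationTruth` behind it.  Deterministic given ``seed``.
    """
    if not 0.0 <= frac_differential <= 1.0:
        raise ValueError("frac_differential must be in [0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    samples = [s for s in design if s.batch is not None]
    if not samples:
        raise ValueError("design has no placed samples")
    batch_ids = sorted({s.batch for s in samples})
    for b in batch_ids:
        mps = [s for s in samples if s.batch == b and s.role == ROLE_MASTER_POOL]
        if len(mps) != 1:
            raise ValueError(f"batch {b} must contain exactly one master pool")
    clinical = [s for s in samples if s.role == ROLE_CLINICAL]
    if not clinical:
        raise ValueError("design contains no clinical samples")

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_proteins)))
    protein_ids = [f"P{i + 1:0{width}d}" for i in range(n_proteins)]

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_proteins)
    effect = np.zeros(n_proteins)
    n_da = int(round(frac_differential * n_proteins))
    if n_da:
        da_idx = rng.choice(n_proteins, size=n_da, replace=False)
        signs = np.ones(n_da)
        signs[n_da // 2:] = -1.0  # half up, half down (extra one goes up)
        rng.shuffle(signs)
        effect[da_idx] = signs * delta

    n_batches = len(batch_ids)
    batch_pos = {b: i for i, b in enumerate(batch_ids)}
    batch_shift = (
        rng.normal(0.0, batch_shift_sd, size=(n_proteins, n_batches))
        if batch_shift_sd > 0
        else np.zeros((n_proteins, n_batches))
    )
    batch_scale = (
        np.exp(rng.normal(0.0, batch_scale_sd, size=n_batches))
        if batch_scale_sd > 0
        else np.ones(n_batches)
    )

    # latent (pre-measurement) log2 profiles
    clin_latent: dict[str, np.ndarray] = {}
    for s in clinical:
        bump = effect if s.diagnosis == affected_group else 0.0
        clin_latent[s.sample_id] = baseline + bump + rng.normal(0.0, sigma, n_proteins)
    qc_latent = baseline + rng.normal(0.0, sigma, n_proteins)
    mp_latent = np.log2(
        np.mean([np.exp2(v) for v in clin_latent.values()], axis=0)
    )

    cols = {}
    for s in samples:
        bi = batch_pos[s.batch]
        shift = batch_shift[:, bi]
        if s.role == ROLE_CLINICAL:
            # channel noise is already inside sigma (total per-channel SD)
            log2_val = clin_latent[s.sample_id] + shift
        else:
            tech = (
                rng.normal(0.0, tech_sd * batch_scale[bi], n_proteins)
                if tech_sd > 0
                else np.zeros(n_proteins)
            )
            latent = qc_latent if s.role == ROLE_QC else mp_latent
            log2_val = latent + shift + tech
        cols[s.sample_id] = np.exp2(log2_val)

    data = pd.DataFrame(cols, index=protein_ids)

    if missing_rate > 0:
        maskable = [s.sample_id for s in samples if s.role != ROLE_MASTER_POOL]
        mask = rng.random((n_proteins, len(maskable))) < missing_rate
        block = data[maskable].to_numpy()
        block[mask] = np.nan
        data[maskable] = block

    truth = SimulationTruth(
        protein_ids=protein_ids,
        baseline=baseline,
        effect=effect,
        sigma=np.full(n_proteins, sigma),
        batch_shift=pd.DataFrame(batch_shift, index=protein_ids, columns=batch_ids),
        batch_scale=pd.Series(batch_scale, index=batch_ids),
        missing_rate=missing_rate,
        affected_group=affected_group,
    )
    return AbundanceMatrix(data, SCALE_RAW), truth
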