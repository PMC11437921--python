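# Methods

This note documents the statistical model behind `tmtmark`, the
defaults and their rationale, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Study design model

A cohort of `3 × n_per_group` clinical samples (diagnoses PSP/PD/HC) is
generated with group-specific age means (defaults 68.8/64.1/67.7 years,
common SD 7.1, truncated at 18) and group-specific female proportions
(defaults 0.60/0.475/0.675).  Sex counts are fixed at
`round(n · prop)` per group rather than drawn Bernoulli: a recruited
cohort is a fixed table of counts, and the fixed-count convention makes
the generator's demographic summaries exactly reproducible.

`block_randomize` places clinical samples on `B` batches of `C`
channels with the master pool always in the last channel and a QC
aliquot on a random non-MP channel in `n_qc_batches` randomly chosen
batches.  Allocation proceeds in three balanced stages: per-batch
clinical counts (even fill under capacity), joint per-(group, batch)
quotas (interleaved greedy, verified to a per-group spread ≤ 1 across
batches, re-randomized in the rare capacity-forced violation), and
per-(group, sex) quotas (greedy, tie-broken toward even overall female
counts).  Ages are balanced by a randomized-restart dealing pass
(50 restarts) followed by 500 same-stratum swap proposals minimizing
`Σ_b n_b z_b²`, `z_b` the standardized batch age-mean deviation.  Any
assignment satisfying the balance invariants is acceptable; this
scheme reaches per-batch diagnosis and sex spreads of ≤ 1 and batch
mean ages within ~1 year of the cohort mean at the default scale.

## Abundance model

All signal structure lives on the log2 scale; raw values are
`2^(log2 value)`.

* per-protein baseline `N(16, 3²)` (an arbitrary intensity scale
  spanning a realistic dynamic range);
* a fraction `frac_differential` of proteins carries a signed group
  effect `±δ` in the affected group (PSP), half up and half down
  (odd counts favor up by one);
* clinical channel `= baseline + effect + N(0, σ)`.  σ (default 0.338)
  is the **total** per-channel SD — biological plus technical — because
  that is what is estimable from real TMT experiments and what enters
  the power calculation;
* the master pool is the linear-scale mean of all clinical true
  abundances (an equal-volume mix), re-measured in every batch with
  technical noise `N(0, tech_sd)`; the QC channel is one fixed latent
  profile (`baseline + N(0, σ)`, one control donor, no group effect)
  measured per batch the same way.  `tech_sd` defaults to 0.10 log2
  units, putting QC CVs around 7–10% and S/N near σ/tech_sd ≈ 3.4, the
  regime where almost all proteins show S/N ≥ 1;
* every channel of batch `b` receives the additive shift
  `N(0, batch_shift_sd)` per (protein, batch) — a multiplicative batch
  effect on the raw scale (default 0.25; the batch-correction
  acceptance check uses 0.5).  `batch_scale_sd > 0` optionally inflates
  per-batch technical noise log-normally (default off, so the
  clinical-SD invariant is exact);
* clinical and QC entries (never the MP) go missing completely at
  random at `missing_rate` (default 0.007, chosen so complete-case
  survival over ~130 channels is ≈ 39%, i.e. a 3,653-protein
  identification list shrinks to a ≈ 1,400-protein analysis matrix).

Because the MP carries the same batch shift as its co-batched channels,
MP ratios cancel the simulated shift exactly; the residual batch effect
in the normalized data is the MP's own measurement noise — which is
precisely why a second, empirical-Bayes correction step exists.

What the generator does **not** emulate: reporter-ion ratio
compression/interference, peptide-to-protein rollup, informative
(abundance-dependent) missingness, and correlated protein modules.
Passing tests therefore demonstrate the statistics behave correctly
under the stated sampling model, not that real CSF data meet that
model.

## Normalization and QC

`mp_normalize` computes `log2(raw / MP(batch))` and drops MP columns;
missing propagates, and a non-positive/missing MP entry turns the whole
(protein, batch) into missing with a warning.  `filter_complete` keeps
exactly the all-present rows.  `combat_correct` is the published
parametric empirical-Bayes location/scale batch adjustment (delegated
to `scanpy.pp.combat`), with no covariates — block randomization is
what protects the group signal, and a warning is emitted if diagnosis
counts are visibly unbalanced across batches.  Zero-variance proteins
pass through unchanged with a warning; batches need ≥ 2 samples; a
single-batch matrix is returned unchanged.

EB shrinkage means the correction is deliberately *not* exact: a small
remnant of each batch offset survives (large when batches are small
and offsets are comparable to noise, negligible in the 13-batch,
shift ≳ noise regime).  Tests assert the EB-consistent behavior —
≥ 95% of a two-batch shift removed at n = 60/batch, near-idempotency,
< 5% residual across-batch variance per protein at the study scale —
rather than exact location removal, which no faithful EB implementation
satisfies.

CV is computed from un-logged QC values as sample SD (n−1) over mean;
S/N is the ratio of clinical to QC log2 SDs, with a `+inf` sentinel
(excluded from summaries) when the QC SD is exactly 0.  The sample-SD
convention (n−1) is used everywhere, matching common statistical
software.

## Differential abundance

The per-protein statistic is the Mann–Whitney AUC (midrank ties).  The
bootstrap is stratified — each class resampled with replacement to its
own size — which preserves class sizes and rules out empty-class
resamples; mean and sample SD are taken over `n_boot = 500` resamples.
Inside `run_differential` one set of resample indices per draw is
shared across proteins (vectorized ranking); each protein's marginal
bootstrap distribution is identical to independent per-protein
resampling.

The null uses **one** global label permutation by default (shared by
all proteins, preserving inter-protein correlation); `n_permutations`
can be raised for a stabler null, pooling counts.  The q-value walk
runs separately for AUC > 0.5 (descending thresholds, inclusive ≥
counts) and AUC < 0.5 (mirrored); the FDR ratio is permuted/observed
(the direction that yields q ∈ [0, 1]), monotonized by a running
minimum from the least-extreme end so q is non-decreasing in rank
within each branch; AUC exactly 0.5 gets q = 1.  Output is sorted by q,
then |AUC − 0.5| descending.

## Classification

PLS-DA standardizes features (mean 0, SD 1; zero-variance features are
excluded with a warning), codes y as 0/1 and fits NIPALS PLS
(`sklearn.cross_decomposition.PLSRegression`, two latent variables by
default).  Class prediction thresholds the continuous PLS score at the
midpoint of the training class means — the upstream tooling's rule is
undocumented, and the midpoint is the natural symmetric choice.  VIP
uses unit-norm weight columns and the per-component explained-y
sum-of-squares; `Σ VIP² = p` is asserted in the test suite.

MCCV draws stratified 2/3–1/3 splits (class proportions preserved on
both sides), ranks features by full-model training VIP (ties broken by
input column order, i.e. protein identifier when columns are sorted),
refits on each top-k and scores the validation third.  Reported per k:
mean accuracy, pooled-validation AUC, and a 2.5/97.5 percentile CI of
per-iteration AUCs.  `best_k` is the smallest k attaining maximal mean
accuracy.  Average importance defaults to the mean full-model VIP over
all iterations with 0 when a feature falls outside the top
`max(feature_counts)` (option: mean over selected iterations only).
Per-iteration randomness derives from `SeedSequence([seed, i])` — a
documented counter scheme, reproducible and below 2³¹.

PCA (both the batch diagnostic and the biplot decomposition) is
column-centered SVD, no scaling; biplot loadings are orthonormal with
the largest-magnitude loading of each component made positive.

## Enrichment

One-sided enrichment only: `P(X ≥ overlap)` by the hypergeometric upper
tail, identical to Fisher's exact test on the 2×2 table (the test suite
checks the two scipy routes against each other and against an explicit
tail sum).  Marker sets are intersected with the background, the query
must be contained in the background, and identifiers are collapsed
case-insensitively.  P-values are raw — no correction across sets.  The
recommended background is the quantified (complete-case) protein list,
not the full identification list; both are accepted.

## Power planning

Exact two-sided, equal-n, pooled-variance noncentral-t power.  The far
opposite tail can underflow to NaN in scipy's `nct` for large
noncentrality; it is treated as zero there (it is < 1e-15 whenever this
happens).  `min_sample_size` solves the *continuous* n with power
exactly at target (as R's `power.t.test` does) and by default rounds to
the nearest integer — the convention under which design numbers are
conventionally quoted; at the default design (δ = 0.433, σ = 0.338,
α = 1e-4, power 0.8) the continuous solution is 31.08, reported as 31,
whose exact power is 0.798.  `conservative="ceil"` instead returns the
smallest n whose power truly reaches the target (32 here), satisfying
the round-trip guarantee `power(n) ≥ target > power(n−1)`.

## Problem sizes in tests

Unit tests run on 300-protein, 24-sample simulations; the acceptance
checks run the full chain at the study scale (1,409 proteins,
120 clinical samples, 13 batches, 500 bootstrap resamples, 10 seeds for
the calibration and recovery medians), sizes chosen to estimate the
reported rates with comfortable Monte-Carlo margins while keeping the
suite quick on a single CPU.

## Known limitations

* The generator's missingness is MCAR; real TMT missingness is largely
  detection-driven and batch-structured.
* One label permutation gives a serviceable but noisy null; the
  q-values inherit that noise (mitigate with `n_permutations`).
* ComBat without covariates can absorb group signal under batch/group
  confounding; the package warns but does not model covariates.
* PLS-DA is the only classifier; no probability calibration or nested
  tuning is provided.
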