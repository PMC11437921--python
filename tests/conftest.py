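"""Shared fixtures: a small but complete study design plus simulated
matrices, generated programmatically (no stored data)."""

from __future__ import annotations

import numpy as np
import pytest

from tmtmark import (
    block_randomize,
    combat_correct,
    filter_complete,
    generate_cohort,
    mp_normalize,
    simulate_tmt,
)

CHANNELS8 = ("126", "127N", "127C", "128N", "128C", "129N", "129C", "131C")


@pytest.fixture(scope="session")
def small_design():
    """24 clinical samples (8 per group) over 4 batches of 8 channels,
    QC in 3 batches, master pool everywhere."""
    cohort = generate_cohort(8, seed=7)
    return block_randomize(
        cohort, n_batches=4, channels=CHANNELS8, n_qc_batches=3, seed=7
    )


@pytest.fixture(scope="session")
def small_sim(small_design):
    """Raw matrix with 10% differential proteins, mild batch effects and
    sparse missingness, plus its ground truth."""
    return simulate_tmt(
        small_design,
        n_proteins=300,
        frac_differential=0.1,
        delta=0.433,
        sigma=0.338,
        batch_shift_sd=0.25,
        missing_rate=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_pipeline(small_design, small_sim):
    """(ratio, complete, corrected) stages of the normalization chain."""
    raw, _ = small_sim
    ratio = mp_normalize(raw, small_design)
    complete = filter_complete(ratio)
    corrected = combat_correct(complete, small_design)
    return ratio, complete, corrected


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
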