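"""Bootstrap-ROC differential abundance with permutation q-values.

Runs the core statistic on a simulated study: per protein, the AUC
separating PSP from the pooled PD + HC group is summarized over 500
stratified bootstrap resamples; a global label permutation provides the
null, and threshold-walk q-values call proteins up- or down-regulated
at q < 0.01.  Ground truth from the simulator scores the calls.
"""

import numpy as np

from tmtmark import (
    CHANNELS_11PLEX, block_randomize, combat_correct, filter_complete,
    generate_cohort, mp_normalize, run_differential, simulate_tmt,
)

design = block_randomize(generate_cohort(40, seed=3), 13, CHANNELS_11PLEX, 10, seed=3)
raw, truth = simulate_tmt(
    design, n_proteins=1409, frac_differential=0.17, delta=0.433, sigma=0.338,
    missing_rate=0.0, seed=3,
)
matrix = combat_correct(filter_complete(mp_normalize(raw, design)), design)

table = run_differential(
    matrix, design, comparison=("PSP", ("PD", "HC")), n_boot=500, q_cutoff=0.01, seed=3
)

called = table[table["direction"] != "null"]
effect = dict(zip(truth.protein_ids, truth.effect))
true_da = {p for p in table["protein_id"] if effect[p] != 0}
hits = set(called["protein_id"]) & true_da

print(f"proteins analyzed: {len(table)}")
print(f"called at q < 0.01: {len(called)} "
      f"({(called['direction'] == 'up').sum()} up, {(called['direction'] == 'down').sum()} down)")
print(f"sensitivity: {len(hits) / len(true_da):.2f}   "
      f"empirical FDR: {len(set(called['protein_id']) - true_da) / max(len(called), 1):.3f}")
print("\nmost extreme calls (AUC far from 0.5 = strong separation):")
print(called.head(8).to_string(index=False,
      formatters={"auc_mean": "{:.3f}".format, "auc_sd": "{:.3f}".format,
                  "q_value": "{:.4f}".format}))
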