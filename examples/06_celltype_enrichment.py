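"""Cell-type overrepresentation of a differential protein set.

Builds a synthetic background of 1,000 quantified proteins and four
synthetic cell-type marker sets, plants a neuron-biased query (as a
neurodegeneration CSF signature would be), and tests each set with the
one-sided Fisher exact (hypergeometric upper-tail) test.
"""

import numpy as np

from tmtmark import fisher_enrichment

rng = np.random.default_rng(4)
background = [f"PROT{i:04d}" for i in range(1000)]

marker_sets = {
    "neuron": background[0:80],
    "astrocyte": background[80:140],
    "microglia": background[140:190],
    "oligodendrocyte": background[190:240],
}

# a 60-protein query: half drawn from neuronal markers, the rest diffuse
query = list(rng.choice(background[0:80], size=30, replace=False))
query += list(rng.choice(background[240:], size=30, replace=False))

results = fisher_enrichment(query, background, marker_sets)
print(f"query: {len(query)} proteins; background: {len(background)}\n")
print(f"{'cell type':<16}{'overlap':>8}{'set size':>9}{'p value':>12}")
for r in results:
    print(f"{r.set_name:<16}{r.overlap:>8}{r.set_size:>9}{r.p_value:>12.3g}")
print(
    "\nThe planted neuronal signal gives a tiny p-value; unrelated sets sit"
    "\nnear p = 1.  P-values are reported raw, one test per marker set."
)
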