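"""All-pairs model comparison: a pairwise Spearman table.

Three synthetic 'methods' model the same region: two independently sample
the looped ground-truth network, the third an unlooped chain.  Each
ensemble is reduced to one mean distance matrix (trajectory-style outputs
would use mode="final" instead) and all pairs are scored.
"""

from chrombench import (
    SpringNetworkSpec,
    ensemble_reduce,
    pairwise_table,
    sample_ensemble,
    table_to_square,
)

loops = ((30, 90, 8.0), (120, 180, 8.0))
ensembles = [
    sample_ensemble(SpringNetworkSpec(n_beads=214, loops=loops, seed=1),
                    300, label="method_A"),
    sample_ensemble(SpringNetworkSpec(n_beads=214, loops=loops, seed=2),
                    300, label="method_B"),
    sample_ensemble(SpringNetworkSpec(n_beads=214, seed=3),
                    300, label="no_loops"),
]
matrices = [ensemble_reduce(e, "mean") for e in ensembles]
table = table_to_square(pairwise_table(matrices, "spearman"))
print(table.round(3))
# The two loop-constrained methods correlate near 1 with each other and
# noticeably less with the unlooped chain — the metric sees the loops.
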