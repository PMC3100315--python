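"""Score cell-type samples against lineage gene sets with single-sample GSEA.

Simulates five cell-type groups with five disjoint 80-gene lineage sets
planted at 1.5-fold enrichment, computes the rank-based enrichment score
of every set in every sample, and asks how often the matching set wins.
"""

import numpy as np

from xsub import SimConfig, enrichment_matrix, simulate_lineage_sets

sim = simulate_lineage_sets(SimConfig(seed=42))
enr = enrichment_matrix(sim.matrix, sim.sets)

print(f"ES matrix: {len(enr.set_names)} sets x {len(enr.sample_ids)} samples, "
      f"weight exponent p = {enr.config.weight_exponent}")
first = enr.sample_ids[0]
print(f"\nsample {first} (cell type {sim.cell_types[first]}), ES per set:")
print(enr.scores[first].round(3).to_string())

top = enr.scores.idxmax(axis=0)
hit = np.mean([top[s] == sim.cell_types[s] for s in enr.sample_ids])
print(f"\nmatching lineage set has the top ES in {100 * hit:.0f}% of samples")
# Positive ES for the matching set and near-zero/negative ES elsewhere show
# the walk statistic picks up a coherent 1.5-fold shift of 80 genes even
# against a 1-SD spread of baseline expression.
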