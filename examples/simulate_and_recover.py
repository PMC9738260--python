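"""Ground-truth check of the whole pipeline on a synthetic cohort.

Builds a block-structured toy design (3 response groups x 4 single-allele
beads, disjoint eplet blocks), simulates 300 patients under the
eplet-driven response model, and runs standardize -> Minkowski/Ward ->
cut -> exclusivity -> driver filters, scoring the result against the truth.
"""

from epletclust.simulate import SimulationParams, block_design, recovery_experiment

registry, panel, blocks = block_design()
params = SimulationParams(seed=42)  # 300 patients, default noise/reactivity

result = recovery_experiment(registry, panel, params, k=3, true_blocks=blocks)

print(f"bead-grouping ARI vs design blocks: {result.ari:.3f}")
print(f"driver recall:    {result.recall:.3f}")
print(f"driver precision: {result.precision:.3f}")
print(f"retained eplets:  {', '.join(result.retained)}")

# ARI = 1 means the Ward tree cut recovered the three designed bead blocks
# exactly; recall/precision compare the nominated drivers with the eplets
# the simulated patients were actually sensitized to.
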