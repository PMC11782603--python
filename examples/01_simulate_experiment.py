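"""Generate a synthetic two-condition SEC-TMT experiment with known truth.

Creates a full-overlap global dataset and a no-overlap phospho dataset for
two conditions x two replicates, and prints what was planted.
"""

from secmx import GeneratorConfig, simulate_experiment

sim = simulate_experiment(GeneratorConfig(seed=1, n_proteins=50))

print(f"records:        {len(sim.records)} reporter measurements")
print(f"design:         {len(sim.design.entries)} channels, scheme={sim.design.scheme}")
print(f"proteins:       {sim.truth.states['protein'].nunique()} "
      f"with {len(sim.truth.states)} assembly states")
changed = (sim.truth.states["log2fc_drawn"] != 0).sum()
print(f"planted change: {changed} states carry a fold change")
print(f"phospho:        {len(sim.truth.phospho)} phosphopeptides pinned to states")
print(sim.truth.states.head(4).to_string(index=False))
# Each row is one planted Gaussian elution state: its apex fraction, width,
# relative occupancy, the fold change planted between conditions, and the
# protein's monomer mass used later for monomer/complex classification.
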