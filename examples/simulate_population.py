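"""Simulate a small FEF population and write the canonical CSV schema.

Builds the seven default cell archetypes under acetylcholine iontophoresis,
simulates every trial of the three-stimulus dimming task, and writes
trials/spikes/waveforms tables plus a ground-truth sidecar.
"""

from fefattn import TaskDesign, simulate_population, study_population
from fefattn.io import write_population

design = TaskDesign(n_trials_per_condition=10)
cells, labels = simulate_population(
    study_population("ACh"), cells_per_archetype=2, design=design, seed=7
)

write_population(cells, "example_data", labels)

n_trials = sum(len(c.trials) for c in cells)
n_spikes = sum(t.spikes_ms.size for c in cells for t in c.trials)
print(f"cells:  {len(cells)}  (archetypes: {sorted(set(labels))})")
print(f"trials: {n_trials}  (12 conditions x {design.n_trials_per_condition} trials per cell)")
print(f"spikes: {n_spikes}")
print("wrote example_data/{trials,spikes,waveforms}.csv + ground_truth.json")
# Each trial carries its attention/direction/drug labels and event times,
# so every downstream analysis window (stimulus, cue, predimming) exists.
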