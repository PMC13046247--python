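"""Simulate a spike-in calibrated meiotic ChIP-seq experiment.

Builds a small 4-chromosome genome, plants DSB hotspots / axis sites /
centromeres / coldspots, and simulates two tagged-ChIP replicates plus an
untagged control at a 1:10 spike-in mixture.
"""
from calchip import (OccupancyModel, expected_spike_fraction,
                     make_genome_layout, plant_features, simulate_experiment)

layout = make_genome_layout(4, [300_000] * 4)
features = plant_features(layout, n_hotspots=120, n_axis=40, n_centromere=4,
                          n_coldspots=25, min_gap=500, seed=1)
print("planted features:", features.class_counts())

model = OccupancyModel()
chip_frac = expected_spike_fraction(layout, features, model, mixing_ratio=0.1)
print(f"expected chip spike fraction from the 1:10 mixture: {chip_frac:.4f}")

exp = simulate_experiment(layout, features, model, n_reads=200_000, seed=1,
                          mixing_ratio=0.1)
for sample in exp.samples:
    print(sample.sample_id, sample.status_counts())

# The sidecar table records expected vs realized reads per mixture component,
# the ground truth that downstream recovery tests check against.
gt = exp.ground_truth
comp = gt[(gt["kind"] == "component") & (gt["sample_id"] == "chip_rep1")]
print("\nground truth (chip_rep1, first components):")
print(comp.head(5).to_string(index=False))
# Each row: a read-generating component; expected_reads is the mixture mass
# share, realized_reads the sampled count (they agree to Monte-Carlo error).
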