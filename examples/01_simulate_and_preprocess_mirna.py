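"""Spot-level miRNA preprocessing on a simulated triplicate-spot experiment.

Builds six GenePix-style arrays (two treatment groups, triplicate spots,
negative controls, 2% flagged spots, 10% of probes at background level),
then runs the full chain: background subtraction, per-array detection
threshold T, log2 transform, trimmed-mean normalization factor N,
triplicate collapse, and the all-samples-in-one-group detection filter.
"""

from concordx import SimConfig, preprocess_mirna, simulate_spot_arrays

config = SimConfig(
    n_probes=300,
    groups=[("DM", 3), ("MWCNT_10ug", 3)],
    planted_effects=[("probe_00150", "MWCNT_10ug", 2.0)],
    noise_sd=0.25,
    flag_rate=0.02,
    frac_undetectable=0.10,
    seed=11,
)
arrays, truth = simulate_spot_arrays(config)
matrix, detected, qc = preprocess_mirna(arrays)

print(qc.round(3))
print(f"\nprobes detected: {len(detected)} / {config.n_probes}")
print("planted probe retained:", "probe_00150" in detected)

# T is the intensity a probe must exceed to count as detected (log2 scale
# after normalization); N recentres arrays so intensities are comparable.
# The 10% of probes simulated at negative-control level should be gone.
low = {f"probe_{i:05d}" for i in range(30)}
print("background-level probes removed:", len(low - set(detected)), "/", len(low))
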