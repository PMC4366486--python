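"""Simulate the three ecospace-filling scenarios and compare occupancy.

Under the early-burst scenario most modes of life are exploited while
taxonomic diversity is still low; under the time-constant scenario mode
occupancy simply tracks genus diversity; under late filling, modes become
available progressively and occupancy lags diversity.
"""

from ecospace import ScenarioConfig, range_through, simulate_dataset, stage_mode_counts

for scenario in ("early_burst", "time_constant", "late_filling"):
    sim = simulate_dataset(
        ScenarioConfig(scenario=scenario, n_stages=30, mode_pool_size=20,
                       origination=15, seed=11)
    )
    occ = range_through(sim.records, sim.timescale)
    rows = []
    for name in (sim.timescale.names[4], sim.timescale.names[-1]):
        counts = stage_mode_counts(occ, name)
        rows.append(f"{name}: X={counts.N:3d} genera in S={counts.S:2d} modes")
    print(f"{scenario:>14}:  " + "   ".join(rows))

print(
    "\nEach line shows an early and the final stage: the late-filling run "
    "reaches far fewer modes early on than the early-burst run at a similar "
    "genus count."
)
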