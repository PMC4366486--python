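"""Rarefy ecological modes against genus diversity for single stages.

The analytic estimator gives the expected number of distinct modes of life
in a random subsample of n genera from a stage assemblage (without
replacement), with its standard deviation; the Monte-Carlo estimator
cross-checks it by resampling.
"""

import numpy as np

from ecospace import (
    ScenarioConfig,
    range_through,
    rarefaction_curve,
    simulate_dataset,
    stage_mode_counts,
)

sim = simulate_dataset(
    ScenarioConfig(scenario="late_filling", n_stages=40, mode_pool_size=30,
                   origination=25, seed=5)
)
occ = range_through(sim.records, sim.timescale)

for stage in (sim.timescale.names[6], sim.timescale.names[-2]):
    counts = stage_mode_counts(occ, stage)
    grid = np.array([5, 10, 20, min(40, counts.N)])
    analytic = rarefaction_curve(counts, grid, method="analytic", stage=stage)
    mc = rarefaction_curve(counts, grid, method="monte_carlo", reps=2000, seed=1, stage=stage)
    print(f"stage {stage} (X={counts.N}, S={counts.S}):")
    for n, a, se, m in zip(grid, analytic.mean_modes, analytic.se_modes, mc.mean_modes):
        print(f"  n={n:3d}  E[modes]={a:5.2f} ± {se:4.2f}   (Monte-Carlo {m:5.2f})")

print(
    "\nAt every common subsample size the late stage's curve runs above the "
    "early stage's: the hallmark of a late-filling history."
)
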