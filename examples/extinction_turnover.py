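"""Mode turnover and extinction selectivity across a programmed pulse.

A diversity-selective extinction pulse (per-mode loss rising with mode
occupancy) is simulated mid-history; the turnover counts modes lost at the
boundary and regained during recovery, and the selectivity regression
recovers the programmed diversity-dependence as a negative slope.
"""

import numpy as np

from ecospace import Pulse, ScenarioConfig, mode_turnover, range_through, simulate_dataset
from ecospace.calibration import stage_window
from ecospace.extinction_dynamics import selectivity_regression

p = np.arange(1, 25) ** -0.5
# origination collapses in the two stages after the pulse, then recovers
origination = [40] * 13 + [2, 5] + [40] * 5
sim = simulate_dataset(
    ScenarioConfig(
        scenario="time_constant", n_stages=20, mode_pool_size=24,
        origination=origination, extinction_prob=0.25,
        mode_probabilities=tuple(p / p.sum()),
        pulses=(Pulse(stage=12, fraction=0.6, selectivity=1.5),), seed=8,
    )
)
occ = range_through(sim.records, sim.timescale)
window = stage_window(sim.timescale, pre_stages=(10, 12), post_stages=(13, 13),
                      recovery_stages=(13, 16), name="pulse")

turnover = mode_turnover(occ, window)
reg = selectivity_regression(occ, window)
print(f"modes lost at the boundary: {turnover.lost}")
print(f"modes new/recovered within the recovery interval: {turnover.gained}")
print(f"selectivity regression: slope={reg.slope:.4f}, R2={reg.r2:.3f}, "
      f"P={reg.p:.3g}, N={reg.n} modes")
print(
    "\nThe negative slope means genus-rich modes lost proportionally more "
    "diversity across the pulse, as programmed (selectivity beta = 1.5, pulse fraction 0.6)."
)
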