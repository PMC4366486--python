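"""Class-level diversity-ecology coupling and the era GLS.

Per stage, Pearson's r correlates log genus count with log mode count across
Linnaean classes (classes with < 10 genera dropped; stages with < 3 classes
dropped).  A generalized least-squares model with one mean per era and
exponentially decaying temporal autocorrelation then asks whether the
coupling strength differs between eras (likelihood-ratio test), and a
cross-time regression asks whether early mode counts predict later diversity.
"""

from ecospace import (
    ScenarioConfig,
    cross_time_class_regression,
    fit_gls_era_model,
    range_through,
    simulate_dataset,
    stage_class_correlation_series,
)

sim = simulate_dataset(
    ScenarioConfig(scenario="time_constant", n_stages=60, mode_pool_size=60,
                   origination=40, n_classes=6, class_mode_coupling=0.5, seed=12)
)
occ = range_through(sim.records, sim.timescale)
series = stage_class_correlation_series(occ, min_genera=10, min_classes=3)
print(f"correlation series: {len(series)} stages retained")
print(series.groupby("era")["r"].describe()[["count", "mean", "std"]].round(3))

full, lrt, reduced = fit_gls_era_model(series)
print(f"\nera means: " + ", ".join(f"{e}={m:.3f}" for e, m in full.era_means.items()))
print(f"rho={full.rho:.1f} Myr, sigma2={full.sigma2:.4f}")
print(f"LRT={lrt.statistic:.2f}, df={lrt.df}, P={lrt.p:.3g}")

mid = sim.timescale.names[len(sim.timescale) // 4]
reg = cross_time_class_regression(occ, mid, "phanerozoic_total")
print(f"\n{mid} mode counts -> total diversity: R2={reg.r2:.3f}, P={reg.p:.3g}, "
      f"N={reg.n} classes")
print(
    "\nWith no programmed era effect the LRT should be insignificant; the "
    "cross-time R2 reflects the class-to-mode coupling built into the run."
)
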