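"""Synthetic genus tables with known ecospace-filling dynamics.

The generator emulates the statistical structure the analyses assume: genera
originate stage by stage over an ordered synthetic timescale, each is
assigned a Linnaean class and one mode of life, persists under a per-stage
extinction probability, and its first/last appearances are recorded as stage
intervals with consistent ages.  Three scenarios control how the mode
assignment evolves:

* ``time_constant`` — one fixed multinomial over the full mode pool for all
  time: the null scenario, under which every stage assemblage is an iid
  sample from the same genus-to-mode relationship;
* ``early_burst`` — all modes available from the first stage, with
  rich-get-richer assignment (probability proportional to current occupancy
  plus an innovation mass 1/concentration), so evenness decays and
  rarefaction trajectories flatten through time;
* ``late_filling`` — modes become available progressively per an innovation
  schedule and draws are restricted to available modes, so the per-genus
  mode richness and rarefaction trajectories rise through time.

Extinction pulses can be programmed at chosen stages: the per-mode loss
fraction scales with mode occupancy raised to a selectivity exponent, so a
positive exponent makes diverse modes lose proportionally more genera — the
signal the selectivity regression is designed to recover.  The default mode
abundance distribution is 1/rank (log-series-like), a realistic uneven
rank-abundance shape.

Everything is driven by one seeded generator, so a fixed seed yields
byte-identical output.  A matching synthetic :class:`~ecospace.data_model.
Timescale` (uniform stage durations, eras in contiguous blocks) is emitted
alongside the records, so no real timescale is needed for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    EcologicalMode,
    EcospaceError,
    GenusRecord,
    GeologicStage,
    Timescale,
    ValidationError,
)

__all__ = [
    "Pulse",
    "ScenarioConfig",
    "SimulationResult",
    "simulate_dataset",
    "synthetic_timescale",
    "mode_pool_triples",
    "simulate_correlation_series",
]

SCENARIOS = ("early_burst", "time_constant", "late_filling")


@dataclass(frozen=True)
class Pulse:
    """An extinction pulse at the end of one stage.

    ``fraction`` is the baseline per-genus loss probability at the pulse;
    ``selectivity`` (beta >= 0) scales the per-mode loss with relative mode
    occupancy, ``p_mode = fraction * (occ_mode / mean_occ) ** beta`` (capped
    at 0.95).  ``selectivity = 0`` is an unselective pulse.
    """

    stage: int
    fraction: float
    selectivity: float = 0.0


@dataclass
class ScenarioConfig:
    """Parameters of one simulated ecospace-filling history.

    Defaults describe a modest Phanerozoic-like history: 30 stages of 5 Myr,
    a 10-mode pool with 1/rank abundance, 12 originations per stage against
    a 0.3 per-stage extinction probability (equilibrium standing diversity
    around 40 genera per stage), and 5 classes.
    """

    scenario: str = "time_constant"
    n_stages: int = 30
    stage_duration: float = 5.0
    mode_pool_size: int = 10
    origination: int | Sequence[int] = 12
    extinction_prob: float = 0.3
    innovation_schedule: Sequence[int] | None = None
    concentration: float = 1.0
    pulses: Sequence[Pulse] = field(default_factory=tuple)
    n_classes: int = 5
    class_mode_coupling: float = 0.0
    mode_probabilities: Sequence[float] | None = None
    seed: int = 0

    def origination_schedule(self) -> np.ndarray:
        if np.isscalar(self.origination):
            return np.full(self.n_stages, int(self.origination), dtype=np.int64)
        sched = np.asarray(self.origination, dtype=np.int64)
        if sched.shape != (self.n_stages,):
            raise ValidationError(
                f"origination schedule length {sched.shape} != n_stages {self.n_stages}"
            )
        return sched

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}; use one of {SCENARIOS}")
        if self.n_stages < 1:
            raise ValidationError("n_stages must be >= 1")
        if self.stage_duration <= 0:
            raise ValidationError("stage_duration must be positive")
        if not 1 <= self.mode_pool_size <= 216:
            raise ValidationError("mode_pool_size must lie in 1..216")
        if not 0.0 <= self.extinction_prob <= 1.0:
            raise ValidationError("extinction_prob must lie in [0, 1]")
        if (self.origination_schedule() < 0).any():
            raise ValidationError("origination counts must be non-negative")
        if self.n_classes < 1:
            raise ValidationError("n_classes must be >= 1")
        if not 0.0 <= self.class_mode_coupling <= 1.0:
            raise ValidationError("class_mode_coupling must lie in [0, 1]")
        if self.concentration <= 0:
            raise ValidationError("concentration must be positive")
        for p in self.pulses:
            if not 0 <= p.stage < self.n_stages:
                raise ValidationError(f"pulse stage {p.stage} outside 0..{self.n_stages - 1}")
            if not 0.0 <= p.fraction <= 1.0:
                raise ValidationError("pulse fraction must lie in [0, 1]")
            if p.selectivity < 0:
                raise ValidationError("pulse selectivity must be >= 0")
        if self.innovation_schedule is not None:
            sched = np.asarray(self.innovation_schedule)
            if sched.shape != (self.mode_pool_size,):
                raise ValidationError(
                    "innovation_schedule must give one availability stage per mode"
                )
            if (sched < 0).any() or (sched >= self.n_stages).any():
                raise ValidationError("innovation stages must lie in 0..n_stages-1")
            if sched.min() != 0:
                raise ValidationError("at least one mode must be available from stage 0")
        if self.mode_probabilities is not None:
            p = np.asarray(self.mode_probabilities, dtype=float)
            if p.shape != (self.mode_pool_size,) or (p < 0).any() or p.sum() <= 0:
                raise ValidationError("mode_probabilities must be a non-negative vector over the pool")


def mode_pool_triples(pool_size: int) -> list[EcologicalMode]:
    """The first ``pool_size`` modes of the 6x6x6 cube in lexicographic
    (tiering, motility, feeding) order."""
    out = []
    for t in range(1, 7):
        for m in range(1, 7):
            for f in range(1, 7):
                out.append(EcologicalMode(t, m, f))
                if len(out) == pool_size:
                    return out
    return out


def synthetic_timescale(
    n_stages: int, stage_duration: float = 5.0, n_eras: int = 3
) -> Timescale:
    """Uniform-duration synthetic timescale, oldest first, with eras as
    contiguous blocks labelled Era_1..Era_k (oldest to youngest)."""
    width = len(str(n_stages))
    bounds = np.linspace(0, n_eras, n_stages, endpoint=False).astype(int)
    stages = [
        GeologicStage(
            name=f"S{i + 1:0{width}d}",
            base_age=(n_stages - i) * stage_duration,
            top_age=(n_stages - i - 1) * stage_duration,
            period=f"Period_{bounds[i] + 1}",
            era=f"Era_{bounds[i] + 1}",
        )
        for i in range(n_stages)
    ]
    return Timescale(stages)


@dataclass
class SimulationResult:
    """A simulated genus table plus its generating ground truth."""

    records: list[GenusRecord]
    timescale: Timescale
    truth: dict


def _default_probabilities(pool_size: int) -> np.ndarray:
    p = 1.0 / np.arange(1, pool_size + 1)
    return p / p.sum()


def simulate_dataset(config: ScenarioConfig) -> SimulationResult:
    """Simulate one genus table under the configured scenario.

    Per stage: new genera originate per the origination schedule, each
    receiving a class and a mode of life per the scenario rules; then every
    living genus goes extinct with the base probability, or with the
    mode-occupancy-dependent pulse probability at pulse stages.  Survivors
    at the youngest stage have their last appearance there (range-through to
    the top of the timescale).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    M = config.mode_pool_size
    modes = mode_pool_triples(M)
    p_full = (
        np.asarray(config.mode_probabilities, dtype=float)
        if config.mode_probabilities is not None
        else _default_probabilities(M)
    )
    p_full = p_full / p_full.sum()

    if config.scenario == "late_filling":
        if config.innovation_schedule is not None:
            avail_stage = np.asarray(config.innovation_schedule, dtype=np.int64)
        else:  # linear schedule: pool fills evenly across the history
            avail_stage = np.floor(
                np.arange(M) * config.n_stages / M
            ).astype(np.int64)
            avail_stage[0] = 0
    else:
        avail_stage = np.zeros(M, dtype=np.int64)

    # round-robin partition of modes among classes (used when coupling > 0)
    class_modes = [np.arange(c, M, config.n_classes) for c in range(config.n_classes)]
    class_modes = [cm if cm.size else np.arange(M) for cm in class_modes]

    orig = config.origination_schedule()
    pulses = {p.stage: p for p in config.pulses}

    occupancy = np.zeros(M, dtype=np.int64)  # standing genus count per mode
    living: list[dict] = []
    finished: list[dict] = []
    standing = np.zeros(config.n_stages, dtype=np.int64)
    genus_id = 0

    for s in range(config.n_stages):
        for _ in range(int(orig[s])):
            cls = int(rng.integers(config.n_classes))
            available = np.flatnonzero(avail_stage <= s)
            if (
                config.class_mode_coupling > 0.0
                and rng.random() < config.class_mode_coupling
            ):
                candidates = np.intersect1d(class_modes[cls], available)
                if candidates.size == 0:
                    candidates = available
            else:
                candidates = available
            if config.scenario == "early_burst":
                w = occupancy[candidates] + 1.0 / config.concentration
            else:
                w = p_full[candidates]
            mode_idx = int(rng.choice(candidates, p=w / w.sum()))
            occupancy[mode_idx] += 1
            genus_id += 1
            living.append({"id": genus_id, "class": cls, "mode": mode_idx, "fad": s})

        standing[s] = len(living)

        # extinction at the end of the stage
        if s in pulses:
            pulse = pulses[s]
            occupied = occupancy > 0
            mean_occ = occupancy[occupied].mean() if occupied.any() else 1.0
            with np.errstate(divide="ignore"):
                rel = np.where(occupied, occupancy / mean_occ, 0.0)
            p_die_mode = np.minimum(pulse.fraction * rel ** pulse.selectivity, 0.95)
        else:
            p_die_mode = np.full(M, config.extinction_prob)

        survivors = []
        for g in living:
            if s == config.n_stages - 1 or rng.random() < p_die_mode[g["mode"]]:
                g["lad"] = s
                finished.append(g)
                occupancy[g["mode"]] -= 1
            else:
                survivors.append(g)
        living = survivors

    timescale = synthetic_timescale(config.n_stages, config.stage_duration)
    names = timescale.names
    width = len(str(max(genus_id, 1)))
    records = [
        GenusRecord(
            taxon_name=f"G{g['id']:0{width}d}",
            phylum=f"Phylum_{g['class'] % 3 + 1}",
            class_=f"Class_{g['class'] + 1}",
            fad_age=timescale[g["fad"]].base_age,
            fad_int=names[g["fad"]],
            lad_age=timescale[g["lad"]].top_age,
            lad_int=names[g["lad"]],
            mode=modes[g["mode"]],
            eco_ref="synthetic",
        )
        for g in sorted(finished, key=lambda g: g["id"])
    ]

    truth = {
        "scenario": config.scenario,
        "pool_probabilities": p_full.tolist(),
        "mode_availability_stage": avail_stage.tolist(),
        "available_mode_count": [
            int((avail_stage <= s).sum()) for s in range(config.n_stages)
        ],
        "standing_diversity": standing.tolist(),
        "pulses": [asdict(p) for p in config.pulses],
        "n_genera": len(records),
        "seed": config.seed,
    }
    return SimulationResult(records=records, timescale=timescale, truth=truth)


# ---------------------------------------------------------------------------
# Correlation-series simulator (for the GLS era model)


def simulate_correlation_series(
    era_means: dict[str, float],
    *,
    n_stages: int = 90,
    stage_duration: float = 5.0,
    sigma2: float = 0.02,
    rho: float = 30.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a per-stage correlation series with known era structure.

    Stage midpoints are uniformly spaced; eras occupy contiguous blocks in
    the order given (oldest first).  Values are drawn from a Gaussian
    process ``y ~ MVN(mu(era), sigma2 * exp(-|dt|/rho))`` — the generating
    model of the era GLS — and returned in the same DataFrame layout as
    :func:`stage_class_correlation_series` (``n_classes`` is a placeholder).
    Simulated values are not clipped to [-1, 1]; keep era means moderate.
    """
    if sigma2 <= 0 or rho <= 0:
        raise EcospaceError("sigma2 and rho must be positive")
    eras = list(era_means)
    ts = synthetic_timescale(n_stages, stage_duration, n_eras=len(eras))
    t = np.array([s.midpoint for s in ts])
    era_idx = np.linspace(0, len(eras), n_stages, endpoint=False).astype(int)
    mu = np.array([era_means[eras[i]] for i in era_idx])
    cov = sigma2 * np.exp(-np.abs(t[:, None] - t[None, :]) / rho)
    rng = np.random.default_rng(seed)
    y = rng.multivariate_normal(mu, cov, method="cholesky")
    return pd.DataFrame(
        {
            "stage": ts.names,
            "midpoint": t,
            "era": [eras[i] for i in era_idx],
            "r": y,
            "n_classes": np.full(n_stages, -1),
        }
    )
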