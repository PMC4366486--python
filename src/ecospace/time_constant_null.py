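"""Time-constant null model for the number of occupied ecological modes.

The null hypothesis is that one fixed multinomial relationship between genera
and modes of life holds across all of geologic time.  A pool of mode
frequencies is tabulated over the whole occurrence table (or a variant; see
:func:`build_pool`), and for every stage with standing genus diversity X,
X modes are drawn from the pool and the number of distinct modes recorded.
Repeating this (10,000 replicates by default) yields a per-stage 95%
confidence envelope for the expected mode count under the time-constant
scenario; observed counts are then classified as below, within or above the
envelope.

Three pooling variants are supported:

* ``genus_weighted`` — mode frequencies summed over all genus-by-stage
  occurrences (each occurrence counts once), the primary construction;
* ``stage_weighted`` — the mean of per-stage *relative* frequencies, giving
  every stage identical influence regardless of its genus count, which
  avoids biasing low-diversity early stages towards the mode spectrum of
  diverse recent stages;
* ``holocene_only`` — the frequencies of a single named reference bin.

Draws are with replacement (multinomial) by default: the pool is a frequency
table and per-stage draw counts can approach the pool size, which would make
without-replacement sampling ill-defined for the non-integer stage-weighted
pool.  Without-replacement (multivariate hypergeometric) sampling is
available for integer-weight pools via ``replacement=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    EcologicalMode,
    EcospaceError,
    ModeCountVector,
    OccurrenceTable,
    TimescaleError,
    stage_mode_counts,
)

__all__ = [
    "ModePool",
    "NullEnvelope",
    "build_pool",
    "time_constant_envelope",
    "classify_observation",
]

POOL_VARIANTS = ("genus_weighted", "stage_weighted", "holocene_only")


@dataclass
class ModePool:
    """Pooled mode weights defining the time-constant null distribution."""

    weights: dict[EcologicalMode, float]
    variant: str

    def __post_init__(self) -> None:
        if not self.weights or not any(w > 0 for w in self.weights.values()):
            raise EcospaceError("mode pool needs at least one positive weight")
        if any(w < 0 for w in self.weights.values()):
            raise EcospaceError("mode pool weights must be non-negative")

    @property
    def S(self) -> int:
        return sum(1 for w in self.weights.values() if w > 0)

    @property
    def modes(self) -> list[EcologicalMode]:
        return [m for m, w in self.weights.items() if w > 0]

    def probabilities(self) -> np.ndarray:
        w = np.array([v for v in self.weights.values() if v > 0], dtype=float)
        return w / w.sum()

    def integer_counts(self) -> np.ndarray:
        w = np.array([v for v in self.weights.values() if v > 0])
        counts = np.round(w).astype(np.int64)
        if not np.allclose(w, counts):
            raise EcospaceError(
                f"{self.variant} pool has non-integer weights; "
                "without-replacement sampling is only defined for count pools"
            )
        return counts


def build_pool(
    occurrences: OccurrenceTable,
    variant: str = "genus_weighted",
    reference_stage: str | None = None,
) -> ModePool:
    """Tabulate the mode pool for the time-constant null model."""
    if variant not in POOL_VARIANTS:
        raise EcospaceError(f"unknown pool variant {variant!r}; use one of {POOL_VARIANTS}")
    if len(occurrences) == 0:
        raise EcospaceError("cannot build a mode pool from an empty occurrence table")

    if variant == "holocene_only":
        if reference_stage is None:
            raise EcospaceError("holocene_only pooling requires a reference_stage")
        counts = stage_mode_counts(occurrences, reference_stage)
        if counts.S == 0:
            raise TimescaleError(f"reference stage {reference_stage!r} holds no occurrences")
        return ModePool(weights={m: float(c) for m, c in counts.items()}, variant=variant)

    if variant == "genus_weighted":
        grouped = occurrences.frame.groupby(
            ["tiering", "motility", "feeding"], sort=True
        ).size()
        weights = {EcologicalMode(*k): float(v) for k, v in grouped.items()}
        return ModePool(weights=weights, variant=variant)

    # stage_weighted: mean of per-stage relative frequencies
    per_stage = (
        occurrences.frame.groupby(["stage", "tiering", "motility", "feeding"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    per_stage["rel"] = per_stage["n"] / per_stage.groupby("stage")["n"].transform("sum")
    n_stages = per_stage["stage"].nunique()
    mean_rel = (
        per_stage.groupby(["tiering", "motility", "feeding"])["rel"].sum() / n_stages
    )
    weights = {EcologicalMode(*k): float(v) for k, v in mean_rel.items()}
    return ModePool(weights=weights, variant=variant)


@dataclass
class NullEnvelope:
    """Per-stage confidence envelope for the expected mode count.

    ``frame`` columns: ``stage, X, lower, mean, upper`` with one row per
    stage in input order; ``lower``/``upper`` are the alpha/2 and 1-alpha/2
    replicate percentiles rounded outward to integers (mode counts are
    integers, and outward rounding keeps coverage conservative).
    """

    frame: pd.DataFrame
    reps: int
    alpha: float
    seed: int | None = None
    variant: str = ""

    def bounds(self, stage: str) -> tuple[float, float]:
        row = self.frame.loc[self.frame["stage"] == stage]
        if row.empty:
            raise TimescaleError(f"stage {stage!r} not in envelope")
        return float(row["lower"].iloc[0]), float(row["upper"].iloc[0])


def _stage_rng(seed: int | None, stage_index: int) -> np.random.Generator:
    # substream per (seed, stage index): results do not depend on the order
    # in which stages are evaluated
    entropy = [stage_index] if seed is None else [int(seed), stage_index]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def time_constant_envelope(
    pool: ModePool,
    stage_genus_counts: dict[str, int] | pd.Series,
    *,
    reps: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    replacement: bool = True,
) -> NullEnvelope:
    """Monte-Carlo envelope for the distinct-mode count at each stage's X.

    For every stage, ``reps`` replicates each draw X modes from the pool and
    record how many distinct modes appear; the envelope is the
    (alpha/2, 1-alpha/2) percentile band with the replicate mean.  Stage
    order in ``stage_genus_counts`` fixes the per-stage RNG substreams.
    """
    if reps < 1:
        raise EcospaceError("reps must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise EcospaceError(f"alpha must lie in (0, 1), got {alpha}")

    if isinstance(stage_genus_counts, pd.Series):
        items = list(stage_genus_counts.items())
    else:
        items = list(stage_genus_counts.items())

    probs = pool.probabilities()
    pool_counts = pool.integer_counts() if not replacement else None

    rows = []
    for idx, (stage, X) in enumerate(items):
        X = int(X)
        if X < 0:
            raise EcospaceError(f"stage {stage!r}: negative genus count {X}")
        rng = _stage_rng(seed, idx)
        if X == 0:
            lower = mean = upper = 0.0
        else:
            if replacement:
                draws = rng.multinomial(X, probs, size=reps)
            else:
                if X > pool_counts.sum():
                    raise EcospaceError(
                        f"stage {stage!r}: X={X} exceeds pool size "
                        f"{pool_counts.sum()} for without-replacement draws"
                    )
                draws = rng.multivariate_hypergeometric(pool_counts, X, size=reps)
            distinct = (draws > 0).sum(axis=1)
            q_lo, q_hi = np.percentile(
                distinct, [100 * alpha / 2, 100 * (1 - alpha / 2)]
            )
            lower = float(np.floor(q_lo))
            upper = float(np.ceil(q_hi))
            mean = float(distinct.mean())
        rows.append({"stage": stage, "X": X, "lower": lower, "mean": mean, "upper": upper})

    frame = pd.DataFrame(rows, columns=["stage", "X", "lower", "mean", "upper"])
    return NullEnvelope(frame=frame, reps=reps, alpha=alpha, seed=seed, variant=pool.variant)


def classify_observation(
    envelope: NullEnvelope, observed_modes: dict[str, int] | pd.Series
) -> pd.Series:
    """Classify each stage's observed mode count against its envelope.

    Returns a Series of ``below`` / ``within`` / ``above`` indexed by stage;
    bounds are inclusive (an observation equal to a bound is ``within``).
    """
    obs = pd.Series(dict(observed_modes))
    env_stages = list(envelope.frame["stage"])
    missing = [s for s in env_stages if s not in obs.index]
    extra = [s for s in obs.index if s not in env_stages]
    if missing or extra:
        raise EcospaceError(
            f"stage mismatch between envelope and observations "
            f"(missing={missing[:5]}, extra={extra[:5]})"
        )
    out = {}
    for row in envelope.frame.itertuples(index=False):
        s_obs = obs[row.stage]
        if s_obs < row.lower:
            out[row.stage] = "below"
        elif s_obs > row.upper:
            out[row.stage] = "above"
        else:
            out[row.stage] = "within"
    return pd.Series(out, name="position")
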