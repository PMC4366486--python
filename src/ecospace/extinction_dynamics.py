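"""Mode-of-life turnover and selectivity across mass-extinction boundaries.

Two era-bounding events are built in: the Permian/Triassic (P/Tr, ~252 Ma)
and Cretaceous/Paleogene (K/Pg, 66 Ma) extinctions.  Pre-extinction windows
follow the convention that diversity decline begins before the formal
boundary: 262.5-251.7 Ma at the P/Tr; the K/Pg comparison spans 69.05-63 Ma
with the 66 Ma boundary dividing pre from post.  Turnover counts modes lost
(occupied before, unoccupied after) and modes gained or recovered during a
~20 Myr recovery interval.  Selectivity is measured by ordinary
least-squares regression of the proportional change in genus diversity
within each mode, (N_post - N_pre)/N_pre, on pre-extinction diversity
N_pre, over modes occupied in both windows; a negative slope means diverse
modes lost proportionally more genera.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .data_model import (
    EcologicalMode,
    EcospaceError,
    OccurrenceTable,
    Timescale,
    TimescaleError,
)

__all__ = [
    "ExtinctionWindow",
    "TurnoverResult",
    "RegressionResult",
    "ptr_window",
    "kpg_window",
    "mode_turnover",
    "selectivity_regression",
]

#: P/Tr pre-extinction window (Ma): decline begins before the 252 Ma boundary.
PTR_PRE = (262.5, 251.7)
#: K/Pg comparison window (Ma), divided at the 66 Ma boundary.
KPG_SPAN = (69.05, 63.0)
KPG_BOUNDARY = 66.0
#: Default recovery-interval length after the boundary (Myr).
RECOVERY_MYR = 20.0


@dataclass(frozen=True)
class ExtinctionWindow:
    """Age windows bracketing a mass extinction, ordered old to young."""

    name: str
    pre_interval: tuple[float, float]
    post_interval: tuple[float, float]
    recovery_interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        intervals = [self.pre_interval, self.post_interval]
        if self.recovery_interval is not None:
            intervals.append(self.recovery_interval)
        for old, young in intervals:
            if old <= young:
                raise EcospaceError(
                    f"window {self.name!r}: interval ({old}, {young}) must run old -> young"
                )
        if self.pre_interval[1] < self.post_interval[0] - 1e-9:
            raise EcospaceError(
                f"window {self.name!r}: pre and post intervals overlap or are out of order"
            )


def ptr_window(
    timescale: Timescale, recovery_myr: float = RECOVERY_MYR
) -> ExtinctionWindow:
    """P/Tr window: pre 262.5-251.7 Ma; post = the first bin younger than
    251.7 Ma; recovery = the ``recovery_myr`` following the pre-window end."""
    boundary = PTR_PRE[1]
    post_bins = timescale.stages_in_interval(boundary, 0.0)
    if not post_bins:
        raise TimescaleError("timescale has no bin younger than the P/Tr boundary")
    first_post = post_bins[0]
    return ExtinctionWindow(
        name="PTr",
        pre_interval=PTR_PRE,
        post_interval=(boundary, first_post.top_age),
        recovery_interval=(boundary, max(boundary - recovery_myr, 0.0)),
    )


def kpg_window(
    timescale: Timescale, recovery_myr: float = RECOVERY_MYR
) -> ExtinctionWindow:
    """K/Pg window: the 69.05-63 Ma span divided at the 66 Ma boundary."""
    return ExtinctionWindow(
        name="KPg",
        pre_interval=(KPG_SPAN[0], KPG_BOUNDARY),
        post_interval=(KPG_BOUNDARY, KPG_SPAN[1]),
        recovery_interval=(KPG_BOUNDARY, max(KPG_BOUNDARY - recovery_myr, 0.0)),
    )


@dataclass
class TurnoverResult:
    """Modes lost at, and gained/recovered after, an extinction boundary."""

    window: str
    lost: int
    gained: int
    lost_modes: set[EcologicalMode]
    gained_modes: set[EcologicalMode]


@dataclass
class RegressionResult:
    """OLS summary: slope, intercept, R^2, slope p-value, point count."""

    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def _interval_modes(occ: OccurrenceTable, interval: tuple[float, float]) -> set[EcologicalMode]:
    sub = occ.interval_frame(*interval)
    return set(occ.modes_of(sub.drop_duplicates(["tiering", "motility", "feeding"])))


def _interval_mode_diversity(
    occ: OccurrenceTable, interval: tuple[float, float]
) -> dict[EcologicalMode, int]:
    """Distinct genera per mode across the union of the interval's bins."""
    sub = occ.interval_frame(*interval).drop_duplicates(
        ["taxon_name", "tiering", "motility", "feeding"]
    )
    grouped = sub.groupby(["tiering", "motility", "feeding"], sort=True).size()
    return {EcologicalMode(*k): int(v) for k, v in grouped.items()}


def mode_turnover(
    occurrences: OccurrenceTable, window: ExtinctionWindow, timescale: Timescale | None = None
) -> TurnoverResult:
    """Count modes lost across the boundary and gained during recovery.

    Lost modes are occupied somewhere in the pre interval and nowhere in the
    post interval.  Gained (new or recovered) modes are occupied in the
    recovery interval but unoccupied in the first (oldest) post-extinction
    bin — the immediate post-crisis state is the baseline for recovery.
    """
    ts = timescale or occurrences.timescale
    pre_modes = _interval_modes(occurrences, window.pre_interval)
    post_modes = _interval_modes(occurrences, window.post_interval)
    lost_modes = pre_modes - post_modes

    gained_modes: set[EcologicalMode] = set()
    if window.recovery_interval is not None:
        first_post = ts.stages_in_interval(*window.post_interval)[0]
        baseline = _interval_modes(occurrences, (first_post.base_age, first_post.top_age))
        recovery_modes = _interval_modes(occurrences, window.recovery_interval)
        gained_modes = recovery_modes - baseline

    return TurnoverResult(
        window=window.name,
        lost=len(lost_modes),
        gained=len(gained_modes),
        lost_modes=lost_modes,
        gained_modes=gained_modes,
    )


def selectivity_regression(
    occurrences: OccurrenceTable,
    window: ExtinctionWindow,
    timescale: Timescale | None = None,
) -> RegressionResult:
    """Diversity-dependence of extinction losses across a boundary.

    For each mode occupied in both the pre and post windows, the response is
    the proportional diversity change (N_post - N_pre)/N_pre and the
    predictor the raw pre-extinction genus count N_pre; modes absent from
    either window are excluded.  Fits ordinary least squares and reports the
    slope with its p-value, R^2 and the number of modes used.
    """
    pre = _interval_mode_diversity(occurrences, window.pre_interval)
    post = _interval_mode_diversity(occurrences, window.post_interval)
    shared = sorted(set(pre) & set(post))
    if len(shared) < 3:
        raise EcospaceError(
            f"window {window.name!r}: only {len(shared)} modes occupied in both "
            "the pre and post intervals; need >= 3 for a regression"
        )
    n_pre = np.array([pre[m] for m in shared], dtype=float)
    n_post = np.array([post[m] for m in shared], dtype=float)
    response = (n_post - n_pre) / n_pre

    if np.ptp(response) == 0.0:  # constant proportional change: nothing to explain
        return RegressionResult(
            slope=0.0, intercept=float(response[0]), r2=0.0, p=1.0, n=len(shared)
        )

    X = sm.add_constant(n_pre)
    fit = sm.OLS(response, X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        p=float(fit.pvalues[1]),
        n=len(shared),
    )
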