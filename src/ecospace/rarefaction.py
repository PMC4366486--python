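"""Rarefaction of ecological modes as a function of genus subsample size.

For a stage assemblage with mode counts ``N_1..N_S`` (``N`` genera in ``S``
modes), classical hypergeometric rarefaction gives the expected number of
distinct modes in a random subsample of ``n`` genera drawn without
replacement:

    E[S_n] = S - sum_i C(N - N_i, n) / C(N, n)

with the exact variance obtained from the mode inclusion and co-inclusion
probabilities (the Heck-van Belle-Simberloff estimator applied to modes
rather than species).  A Monte-Carlo estimator is provided for cross-checks;
its "s.e." is the across-subsample standard deviation of the distinct-mode
count, the quantity shaded around per-stage curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .data_model import EcospaceError, ModeCountVector

__all__ = ["RarefactionCurve", "expected_modes_analytic", "rarefaction_curve", "default_grid"]


@dataclass
class RarefactionCurve:
    """Expected distinct-mode count (and spread) across subsample sizes."""

    stage: str
    grid: np.ndarray
    mean_modes: np.ndarray
    se_modes: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int64)
        self.mean_modes = np.asarray(self.mean_modes, dtype=float)
        self.se_modes = np.asarray(self.se_modes, dtype=float)


def _log_comb(a: np.ndarray, n: int) -> np.ndarray:
    """log C(a, n) with C(a, n) = 0 (log -> -inf) for a < n."""
    a = np.asarray(a, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(a + 1) - gammaln(n + 1) - gammaln(a - n + 1)
    return np.where(a >= n, out, -np.inf)


def expected_modes_analytic(
    counts: ModeCountVector, n: int
) -> tuple[float, float]:
    """Exact mean and variance of the distinct-mode count at subsample size n.

    Subsampling is of genera, without replacement.  Returns ``(0.0, 0.0)``
    for ``n == 0``; raises for ``n < 0`` or ``n > N``.
    """
    N = counts.N
    if n < 0 or n > N:
        raise EcospaceError(f"subsample size n={n} outside [0, N={N}]")
    if n == 0 or counts.S == 0:
        return 0.0, 0.0

    ci = counts.counts_array().astype(float)
    log_cNn = _log_comb(np.array(N, dtype=float), n)
    # absence probability of each mode: C(N - N_i, n) / C(N, n)
    q = np.exp(_log_comb(N - ci, n) - log_cNn)
    mean = counts.S - q.sum()

    # joint absence of mode pairs: C(N - N_i - N_j, n) / C(N, n)
    qij = np.exp(_log_comb(N - ci[:, None] - ci[None, :], n) - log_cNn)
    cov = qij - q[:, None] * q[None, :]
    np.fill_diagonal(cov, q * (1.0 - q))
    var = float(cov.sum())
    return float(mean), max(var, 0.0)


def default_grid(N: int, max_points: int = 40) -> np.ndarray:
    """Subsample-size grid: every integer up to N for small assemblages,
    otherwise ~``max_points`` log-spaced sizes always including 1 and N."""
    if N <= 0:
        return np.array([], dtype=np.int64)
    if N <= 50:
        return np.arange(1, N + 1, dtype=np.int64)
    grid = np.unique(
        np.round(np.geomspace(1, N, max_points)).astype(np.int64)
    )
    grid[-1] = N
    return np.unique(grid)


def rarefaction_curve(
    counts: ModeCountVector,
    grid: np.ndarray | None = None,
    *,
    method: str = "analytic",
    reps: int = 1000,
    seed: int | None = None,
    stage: str = "",
) -> RarefactionCurve:
    """Rarefaction curve for one assemblage.

    ``method="analytic"`` evaluates the hypergeometric expectation and its
    standard deviation exactly; ``method="monte_carlo"`` draws ``reps``
    subsamples without replacement per grid size and reports the
    across-replicate mean and standard deviation.  Monte-Carlo runs are
    reproducible from ``seed``.
    """
    N = counts.N
    if grid is None:
        grid = default_grid(N)
    grid = np.asarray(grid, dtype=np.int64)
    if grid.size and (grid.min() < 0 or grid.max() > N):
        raise EcospaceError(f"grid sizes must lie in [0, N={N}]")

    if method == "analytic":
        stats = [expected_modes_analytic(counts, int(n)) for n in grid]
        mean = np.array([m for m, _ in stats])
        se = np.sqrt([v for _, v in stats])
    elif method in ("monte_carlo", "mc"):
        if reps < 1:
            raise EcospaceError("monte_carlo rarefaction needs reps >= 1")
        rng = np.random.default_rng(seed)
        pop = np.repeat(np.arange(counts.S), counts.counts_array())
        richness = np.empty((reps, grid.size), dtype=np.int64)
        for r in range(reps):
            perm = rng.permutation(pop)
            # position of each mode's first occurrence in the permuted order
            _, first_idx = np.unique(perm, return_index=True)
            first_idx.sort()
            richness[r] = np.searchsorted(first_idx, grid, side="left")
        mean = richness.mean(axis=0)
        se = richness.std(axis=0, ddof=1) if reps > 1 else np.zeros(grid.size)
        method = "monte_carlo"
    else:
        raise EcospaceError(f"unknown rarefaction method {method!r}")

    return RarefactionCurve(stage=stage, grid=grid, mean_modes=mean, se_modes=se, method=method)
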