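"""Coupling between taxonomic diversity and modes of life within classes.

Per geologic stage, the Pearson correlation r between log genus count and
log distinct-mode count is computed across Linnaean classes (classes with
fewer than 10 genera in that stage are excluded as too small to estimate a
mode count; stages retaining fewer than 3 classes are dropped).  The
resulting time series of correlation coefficients is modelled by generalized
least squares with a fixed effect of geologic era and exponentially decaying
temporal autocorrelation:

    r_t = mu(era_t) + eps_t,      corr(eps_i, eps_j) = exp(-|t_i - t_j| / rho)

with variance sigma^2, fitted by maximum likelihood (rho profiled; GLS means
and sigma^2 closed-form given rho).  A likelihood-ratio test against the
intercept-only model (same autocorrelation structure) asks whether era
explains the correlation series; ML rather than REML likelihoods are used so
the LRT on fixed effects is valid.  The Cambrian is excluded from the era
model — too few of its stages retain enough classes — leaving three eras
(post-Cambrian Palaeozoic, Mesozoic, Cenozoic) and hence 2 degrees of
freedom.

Cross-time regressions ask whether early functional differentiation predicts
later taxonomic diversity: class-level mode counts at a predictor stage
(e.g. the Katian, ~445 Ma) are regressed against class genus diversity at a
later response stage (e.g. the Pleistocene) or against total Phanerozoic
diversity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, optimize, stats

from .data_model import EcospaceError, OccurrenceTable, Timescale
from .extinction_dynamics import RegressionResult

__all__ = [
    "GLSFit",
    "LRTResult",
    "stage_class_correlation_series",
    "fit_gls_era_model",
    "cross_time_class_regression",
    "class_summary",
]


def class_summary(occurrences: OccurrenceTable) -> pd.DataFrame:
    """Per (stage, class): genus count and distinct-mode count.

    Rows with an empty class label are dropped — class identity is required
    here, though such genera still contribute to stage-level analyses.
    """
    df = occurrences.frame
    df = df[df["class"].astype(str) != ""]
    mode_key = list(zip(df["tiering"], df["motility"], df["feeding"]))
    df = df.assign(_mode=mode_key)
    out = (
        df.groupby(["stage", "class"], sort=False)
        .agg(n_genera=("taxon_name", "nunique"), n_modes=("_mode", "nunique"))
        .reset_index()
    )
    return out


def stage_class_correlation_series(
    occurrences: OccurrenceTable,
    timescale: Timescale | None = None,
    *,
    min_genera: int = 10,
    min_classes: int = 3,
) -> pd.DataFrame:
    """Per-stage class-level correlation between log mode and genus counts.

    Returns a DataFrame with columns ``stage, midpoint, era, r, n_classes``
    ordered oldest to youngest, containing only stages that retain at least
    ``min_classes`` classes with >= ``min_genera`` genera.  Counts are
    natural-log transformed before computing Pearson's r (after filtering
    every count is >= 1, so no offset is needed); the correlation is
    invariant to the log base.  Stages dropped by the filters, or whose
    retained counts are constant across classes (r undefined), are reported
    in a warning.
    """
    ts = timescale or occurrences.timescale
    summary = class_summary(occurrences)
    rows, dropped = [], []
    for stage_name in ts.names:
        sub = summary[summary["stage"] == stage_name]
        sub = sub[sub["n_genera"] >= min_genera]
        if len(sub) < min_classes:
            dropped.append(stage_name)
            continue
        x = np.log(sub["n_genera"].to_numpy(dtype=float))
        y = np.log(sub["n_modes"].to_numpy(dtype=float))
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            dropped.append(stage_name)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        st = ts.stage(stage_name)
        rows.append(
            {
                "stage": stage_name,
                "midpoint": st.midpoint,
                "era": st.era_group,
                "r": r,
                "n_classes": len(sub),
            }
        )
    if dropped:
        warnings.warn(
            f"{len(dropped)} stage(s) dropped from the correlation series "
            f"(too few qualifying classes or degenerate counts): {dropped[:8]}"
            + ("..." if len(dropped) > 8 else "")
        )
    return pd.DataFrame(rows, columns=["stage", "midpoint", "era", "r", "n_classes"])


# ---------------------------------------------------------------------------
# GLS with exponential temporal autocorrelation


@dataclass
class GLSFit:
    """ML fit of a mean model with exponential temporal autocorrelation."""

    coefficients: dict[str, float]
    se: dict[str, float]
    sigma2: float
    rho: float
    loglik: float
    n: int

    @property
    def era_means(self) -> dict[str, float]:
        return dict(self.coefficients)


@dataclass
class LRTResult:
    """Likelihood-ratio test of the era effect."""

    statistic: float
    df: int
    p: float


def _gls_profile(rho: float, t: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Closed-form GLS given rho: returns (loglik, beta, sigma2_ML, XtRiX)."""
    n = len(y)
    R = np.exp(-np.abs(t[:, None] - t[None, :]) / rho)
    try:
        cho = linalg.cho_factor(R, lower=True)
    except linalg.LinAlgError as exc:
        raise EcospaceError(
            f"correlation matrix singular at rho={rho:.4g} Myr"
        ) from exc
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    Ri_X = linalg.cho_solve(cho, X)
    Ri_y = linalg.cho_solve(cho, y)
    XtRiX = X.T @ Ri_X
    beta = linalg.solve(XtRiX, X.T @ Ri_y, assume_a="pos")
    resid = y - X @ beta
    sigma2 = float(resid @ linalg.cho_solve(cho, resid)) / n
    if sigma2 <= 0:
        raise EcospaceError("degenerate fit: zero residual variance")
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return loglik, beta, sigma2, XtRiX


def _fit_exp_gls(
    t: np.ndarray, X: np.ndarray, y: np.ndarray, names: list[str]
) -> GLSFit:
    """Profile-likelihood fit: log-spaced grid over rho, then bounded
    refinement; tolerance ~1e-6 on the log-likelihood scale."""
    span = float(t.max() - t.min())
    gaps = np.diff(np.sort(t))
    lo = max(float(gaps[gaps > 0].min()) / 10.0, 1e-3)
    hi = max(span * 10.0, lo * 10.0)
    grid = np.geomspace(lo, hi, 41)
    lls = np.array([_gls_profile(r, t, X, y)[0] for r in grid])
    k = int(np.argmax(lls))
    lo_b = grid[max(k - 1, 0)]
    hi_b = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda logr: -_gls_profile(np.exp(logr), t, X, y)[0],
        bounds=(np.log(lo_b), np.log(hi_b)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(np.exp(res.x))
    loglik, beta, sigma2, XtRiX = _gls_profile(rho, t, X, y)
    cov_beta = sigma2 * linalg.inv(XtRiX)
    se = np.sqrt(np.diag(cov_beta))
    return GLSFit(
        coefficients=dict(zip(names, map(float, beta))),
        se=dict(zip(names, map(float, se))),
        sigma2=sigma2,
        rho=rho,
        loglik=float(loglik),
        n=len(y),
    )


def fit_gls_era_model(
    series: pd.DataFrame,
    *,
    drop_eras: tuple[str, ...] = ("Cambrian",),
    time_col: str = "midpoint",
    value_col: str = "r",
    era_col: str = "era",
) -> tuple[GLSFit, LRTResult, GLSFit]:
    """Fit era-mean and intercept-only GLS models and their LRT.

    Returns ``(full, lrt, reduced)``.  The full model uses cell-means coding
    (one coefficient per era, so ``full.era_means`` reads directly as the
    fitted per-era correlation level); the reduced model has a single mean.
    Both share the exponential autocorrelation structure with their own ML
    rho.  ``drop_eras`` removes eras (by default the Cambrian) before
    fitting; the LRT df is the number of retained eras minus one.
    """
    df = series[~series[era_col].isin(drop_eras)].copy()
    eras = [e for e in df[era_col].unique()]
    if len(eras) < 2:
        raise EcospaceError(f"need >= 2 eras to test an era effect, got {eras}")
    counts = df[era_col].value_counts()
    if (counts < 2).any():
        raise EcospaceError(
            f"every era needs >= 2 stages; got {counts.to_dict()}"
        )
    df = df.sort_values(time_col, ascending=False)  # oldest first
    t = df[time_col].to_numpy(dtype=float)
    if len(np.unique(t)) != len(t):
        raise EcospaceError("stage midpoints must be strictly ordered (no ties)")
    y = df[value_col].to_numpy(dtype=float)

    X_full = np.column_stack([
        (df[era_col] == e).to_numpy(dtype=float) for e in eras
    ])
    full = _fit_exp_gls(t, X_full, y, names=list(eras))
    reduced = _fit_exp_gls(t, np.ones((len(y), 1)), y, names=["mean"])

    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    dof = len(eras) - 1
    lrt = LRTResult(statistic=float(stat), df=dof, p=float(stats.chi2.sf(stat, dof)))
    return full, lrt, reduced


# ---------------------------------------------------------------------------
# Cross-time predictive regressions


def cross_time_class_regression(
    occurrences: OccurrenceTable,
    predictor_stage: str,
    response: str = "phanerozoic_total",
    *,
    min_overlap: int = 3,
    log: bool = False,
) -> RegressionResult:
    """Regress later class diversity on earlier class mode counts.

    Predictor: per-class distinct-mode count in ``predictor_stage``.
    Response: per-class genus diversity at the named response stage, or the
    total distinct-genus count over all stages when ``response`` is
    ``"phanerozoic_total"``.  Only classes present in both sets enter; raw
    counts are used unless ``log`` is set (natural logs).
    """
    summary = class_summary(occurrences)
    pred = summary[summary["stage"] == predictor_stage].set_index("class")["n_modes"]
    if pred.empty:
        raise EcospaceError(f"no classes recorded in predictor stage {predictor_stage!r}")

    if response == "phanerozoic_total":
        df = occurrences.frame
        df = df[df["class"].astype(str) != ""]
        resp = df.groupby("class")["taxon_name"].nunique()
    else:
        resp = summary[summary["stage"] == response].set_index("class")["n_genera"]
        if resp.empty:
            raise EcospaceError(f"no classes recorded in response stage {response!r}")

    shared = sorted(set(pred.index) & set(resp.index))
    if len(shared) < min_overlap:
        raise EcospaceError(
            f"only {len(shared)} classes shared between predictor and response; "
            f"need >= {min_overlap}"
        )
    x = pred.loc[shared].to_numpy(dtype=float)
    y = resp.loc[shared].to_numpy(dtype=float)
    if log:
        x, y = np.log(x), np.log(y)

    if np.ptp(y) == 0.0:
        return RegressionResult(slope=0.0, intercept=float(y[0]), r2=0.0, p=1.0, n=len(shared))
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        p=float(fit.pvalues[1]),
        n=len(shared),
    )
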