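# Methods

This note records the models implemented by the package, the choices made
where the design was genuinely open, the calibration regimes used by the
test suite and `scripts/acceptance.py`, and known limitations. Nothing here
asserts an empirical result that the tests or the acceptance script do not
themselves compute.

## Data model

A genus record carries a stratigraphic range (first/last appearance stage
and age, in Ma) and exactly one mode of life — the ordered (tiering,
motility, feeding) triple with each axis coded 1–6. Stage membership is
**range-through** and interval-based: a genus is present in every stage
from its FAD interval through its LAD interval inclusive, and ages are
carried only for plotting and for selecting age windows. Timescales are
ordered oldest→youngest and must be contiguous (each stage's top age equals
the next stage's base age, tolerance 10⁻⁶ Myr). Era labels are normalised
to four analysis groups — Cambrian, post-Cambrian Palaeozoic, Mesozoic,
Cenozoic — because the Cambrian's ecospace structure is analysed separately
from the rest of the Palaeozoic; unrecognised labels (synthetic data) pass
through unchanged.

Two timescale conveniences reflect how genus compendia are analysed: the
earliest Cambrian stages can be merged to epoch-level bins (stage-level
resolution is unreliable there), and the terminal Holocene bin
(0.117–0 Ma) can be dropped so living taxa do not inflate modern diversity.
The Holocene is identified as a terminal bin with top age 0 and base age
≤ 0.5 Ma; a merged Pleistocene+Holocene bin cannot be split and is kept
with a warning.

Genera with a missing class are retained in stage-level analyses and
excluded from class-level ones, which are the only analyses that need the
class label. Readers trust interval names over ages when they disagree and
only warn, since named intervals are the unit of presence.

## Rarefaction

Classical hypergeometric rarefaction applied to modes rather than species:
sampling n of N genera without replacement,

    E[S_n] = S − Σ_i C(N − N_i, n) / C(N, n),

with the exact variance from the per-mode inclusion and pairwise
co-inclusion probabilities (the Heck–van Belle–Simberloff variance).
Binomial coefficients are evaluated through log-gamma ratios, with
C(a, n) = 0 for a < n, so assemblages of any size are handled without
overflow. Sampling is *without* replacement because a stage's genus list is
a finite population. The "standard error" reported alongside a curve is
the standard deviation of the distinct-mode count across subsamples (the
spread a reader would shade around a curve), not the standard error of the
estimated mean; the Monte-Carlo estimator reports the same quantity as an
across-replicate standard deviation. Default subsample grids use every
integer up to N for N ≤ 50 and ~40 log-spaced sizes (always including N)
otherwise.

## Time-constant null model

The null hypothesis is a single genus-to-mode multinomial for all time.
Three poolings are provided: **genus-weighted** (mode frequencies over all
genus-by-stage occurrences — the primary construction), **stage-weighted**
(mean of per-stage relative frequencies, giving each stage identical
influence so that diverse recent stages do not dominate the pool), and a
**single-reference-bin** pool. For each stage with X genera, 10,000
replicates draw X modes from the pool and record the distinct-mode count;
the envelope is the 2.5–97.5 percentile band (inclusive linear-interpolation
percentiles) with bounds rounded outward to integers, since mode counts are
integers and outward rounding keeps coverage conservative. Classification
against the envelope is inclusive: an observation equal to a bound is
"within".

Draws are **with replacement** (multinomial on pool relative frequencies):
the pool is a frequency table, per-stage draw counts can approach the pool
size, and the stage-weighted pool has non-integer weights, all of which
make without-replacement sampling ill-defined in general. For integer-weight
pools a without-replacement (multivariate hypergeometric) variant is
available behind a flag.

Per-stage random substreams are derived deterministically from (seed, stage
position), so each stage's replicate set does not depend on how many other
stages are evaluated; callers should pass stages in timescale order, which
the occurrence-table accessor does.

## Extinction windows, turnover and selectivity

Built-in windows follow the convention that diversity decline begins before
the formal boundary: Permian/Triassic pre-window 262.5–251.7 Ma with the
post-window being the first timescale bin younger than 251.7 Ma;
Cretaceous/Paleogene 69.05–63 Ma divided at the 66 Ma boundary. A bin
belongs to an age interval if its midpoint falls inside (older bound
inclusive). Recovery intervals default to the 20 Myr after the boundary,
configurable. Within-interval diversity is the count of distinct genera
present in any bin of the interval (range-through union), matching the
comparison of a pre-extinction baseline with a post-extinction but
pre-recovery interval; "gained" modes are those occupied during recovery
but absent from the first post-boundary bin.

The selectivity regression uses the **proportional change**
(N_post − N_pre)/N_pre as the standardized difference in diversity and the
raw pre-extinction count N_pre as predictor, over modes occupied in both
windows (modes absent from either side are excluded). The fit is ordinary
least squares; a constant response returns slope 0, R² 0 by convention.
Two consequences of this design are worth knowing. First, because modes
that lose every genus are excluded, small modes enter the regression only
when they happen to survive, which imparts a small *negative* bias to the
slope even under unselective extinction; calibration shows the bias
shrinking roughly inversely with standing diversity (≈ −0.008 at ~160
genera/stage, ≈ −0.0002 at ~1,200), so the calibration studies assert
magnitude separation from programmed selectivity rather than exact
zero-centring. Second, if the programmed per-mode loss probability
saturates at its cap the programmed selectivity gradient flattens, so the
calibration study uses a mild abundance skew (∝ rank^−1/2) and pulse
fraction 0.2, keeping every mode's loss probability in the responsive
range.

## Class–ecology coupling and the era GLS

Per stage and class, the genus count and distinct-mode count are computed;
classes with fewer than 10 genera in that stage are dropped (too small to
estimate a mode count), stages with fewer than 3 surviving classes are
dropped, and Pearson's r is computed on natural-log counts (all counts are
≥ 1 after filtering, so no offset is needed; r is invariant to the log
base). Stages whose retained counts are constant across classes have no
defined correlation and are dropped with a warning.

The era model is

    r_t = μ(era_t) + ε_t,  cov(ε_i, ε_j) = σ² exp(−|t_i − t_j| / ρ),

fitted by maximum likelihood: given ρ, the GLS means and σ² are closed
form; ρ is profiled on a 41-point log-spaced grid spanning one tenth of the
smallest stage gap to ten times the series span, then refined by bounded
scalar minimisation on log ρ (tolerance ~10⁻⁶ on the log-likelihood).
ML rather than REML is used for both the era model and the intercept-only
reduction so the likelihood-ratio test on the fixed effect is valid; the
LRT statistic 2(ℓ_full − ℓ_reduced) is referred to χ² with (number of
eras − 1) degrees of freedom. Cell-means coding makes the fitted
coefficients directly the per-era levels, with standard errors from
σ²(XᵀR⁻¹X)⁻¹. The Cambrian is excluded from the era model by default (too
few Cambrian stages survive the class filters to estimate a level), giving
df = 2 for the standard three-era comparison. The implementation is
cross-checked in the test suite against an independent GLS implementation
(R's nlme with an exponential correlation structure) on a common series:
log-likelihoods, era coefficients and the fitted range agree.

**Calibration and a known limitation.** The LRT's χ² reference is an
asymptotic approximation. The package's calibration studies simulate null
series (90 stages of 5 Myr, no true era effect, exponential
autocorrelation) and measure the rejection rate at nominal 5%: the test is
essentially exact for autocorrelation ranges up to about one stage spacing
(ρ ≤ 5 Myr) and degrades as ρ grows — the acceptance script reports the
measured rates at ρ = 5, 10 and 30 Myr. The inflation at large ρ arises
because a strongly autocorrelated series carries only a handful of
independent fluctuations, which three contiguous era blocks can partially
absorb as spurious level differences; ML's downward-biased ρ̂ compounds
this. The default type-I calibration therefore runs at ρ = 5 Myr, and era
effects detected in strongly autocorrelated series should be read with
this liberality in mind (it is immaterial for effects as large as the
three-era differences the model is designed for). Era-mean recovery is
asserted on replicate averages (unbiasedness within two standard errors)
with the per-replicate 2-SE coverage and the median ρ̂/ρ ratio reported
alongside.

Cross-time regressions (predictor-stage class mode counts against
response-stage or total-Phanerozoic class diversity) use raw counts by
default with a natural-log option, since there is no principled reason to
force the transform; classes must be present in both sets, with at least
three shared classes.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume and
nothing more: per-stage origination (fixed count or schedule), a fixed
per-genus per-stage extinction probability, one mode and one class per
genus, and stage-interval FAD/LAD with ages from a uniform-duration
synthetic timescale whose eras are contiguous blocks. Scenario rules:
time-constant draws modes from a fixed multinomial (default abundance
∝ 1/rank, a log-series-like rank-abundance shape); early-burst assigns by
rich-get-richer (weight = current occupancy + 1/concentration); late-filling
restricts draws to modes whose innovation stage has arrived (default linear
schedule). Pulses override the extinction probability at one stage with
p_mode = fraction × (occupancy/mean occupancy)^β, capped at 0.95. An
optional coupling knob ties each class to a round-robin subset of modes to
create class-level diversity–ecology correlations. Defaults (30 stages of
5 Myr, 10-mode pool, 12 originations/stage, extinction probability 0.3,
5 classes) describe a modest Phanerozoic-like history with equilibrium
standing diversity ≈ 40 genera per stage.

What the generator does **not** emulate — and hence what passing
calibration says nothing about: preservation and sampling failure
(ranges are true ranges), phylogenetic structure in mode assignment
(modes are drawn independently per genus), within-genus mode variation,
abundance and body size, and correlated origination/extinction across
modes. Real compendia violate all of these to some degree; the
calibrations validate the estimators under their own assumptions, not
robustness to these violations.

A Gaussian-process simulator for correlation series (means per era,
σ² exp(−Δt/ρ) covariance) generates inputs for the GLS calibrations
directly; values are not clipped to [−1, 1], so era means should stay
moderate.

## Calibration study sizes

Chosen so the full test suite and the acceptance script each run in
minutes on one CPU: rarefaction enumeration over all assemblages with
N ≤ 12 (tests) or N ≤ 10 (script); null-envelope coverage over 200
simulated datasets at 2,000 replicates each; selectivity over 40 replicates
per β ∈ {0, 1, 2}; GLS recovery over 30 replicates of 90-stage series and
type-I error over 400 (default regime) plus 2 × 200 (stronger regimes)
null fits. The coverage study keeps standing diversity at ~16 genera per
stage against the 10-mode pool: mode counts are integers, and once standing
diversity saturates the pool the distinct-mode count concentrates at the
pool ceiling, where any percentile envelope trivially covers nearly every
replicate and the coverage experiment stops being informative.

## Numerical conventions and degenerate inputs

Percentiles use numpy's linear interpolation; envelope bounds round
outward. Empty stages yield S = N = 0 and are classified "within" only if
the envelope is also degenerate at zero. Subsample size 0 returns mean 0,
variance 0. Constant regressions (zero response variance) return slope 0,
R² 0, p 1 rather than NaN. The GLS rejects series with tied midpoints, eras
with fewer than two stages, and singular correlation matrices (reporting
the ρ at failure). Genus tables are validated row-by-row with all failures
reported together (row numbers and genus names); duplicate taxon names
warn but do not fail, since subgenus elevation is assumed to have been
applied upstream.
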