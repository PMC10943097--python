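# Methods

This note documents the models, numerical choices and limitations behind
`coraldemog`. It is written for a user deciding whether the defaults fit their
data, and for a maintainer wondering why a particular convention was chosen.

## The analysis problem

Repeated photographic belt-transect surveys record, for every coral colony of
three genera at inshore and offshore subtropical reef sites, its planar area
(cm²), a bleaching flag, a partial-mortality flag and whether the colony was
only partially captured in the frame. Surveys bracket a mass bleaching year
and are grouped into periods: P1 (2010, 2012; pre-bleaching), P2 (April and
October 2016; the bleaching year and aftermath) and P3 (2018, 2019; early
recovery). The pipeline asks three questions: how colony size structure
shifted between periods; how bleaching and partial mortality scale with
colony size and taxon; and which environmental conditions co-vary with the
abundance of small (replenishing) corals.

## Synthetic data as the validation substrate

Field datasets of this kind are frequently available only on request, so the
generator is a first-class module rather than a test fixture: it emulates the
survey's structure with *planted* parameters that the downstream estimators
must recover.

**Colony sizes.** Log colony area follows a skew-normal
SN(ξ, ω, α). A lognormal (normal on the log scale) cannot represent the
nonzero log-scale skewness that real populations show (large-colony dominance
gives negative skewness), so the shape parameter α carries the third moment.
`solve_size_params` inverts three published summaries — raw-scale mean area
E[e^X] (via the skew-normal MGF, E[e^X] = 2·exp(ξ + ω²/2)·Φ(δω) with
δ = α/√(1+α²)), the log-scale CV σ_X/μ_X, and the log-scale skewness — into
(ξ, ω, α). The skewness equation is solved for δ by bisection (feasible range
|skew| < 0.99; outside it the solver raises rather than clamping), then ω by
bisection on the log of the mean-area equation; solutions are verified to
1e-6 and the zero-variance limit degenerates to a point mass. Default
targets are the published genus summaries (Pocillopora 66.42 cm², CV 0.51,
skew −0.03; Turbinaria 708.47 cm², CV 0.31, skew −0.29). Acropora's mean
area is not printed in the source summaries; the bundled configuration uses
180 cm² with CV 0.42 and skew 0.05, chosen to sit between the other genera
with the published near-symmetric shape.

**Condition flags.** Bleaching and partial mortality are Bernoulli with
logit-linear dependence on centred log-area; a `pm_bleached_boost` term
raises the partial-mortality logit for bleached colonies. Defaults plant the
published marginal rates (bleaching 0.806 / 0.653 / 0.069 for Pocillopora /
Turbinaria / Acropora; partial mortality 0.0183 unbleached with a boost
reaching 0.0552 when bleached). With a nonzero size slope the intercept is
the rate at the typical (centred) colony size, so the marginal rate matches
the intercept's inverse-logit only approximately; slope-zero configurations
plant it exactly.

**Partial capture.** Each colony is flagged with probability 0.107 (the
published fraction of colonies extending beyond the photo frame); flagged
colonies have their observed area multiplied by a uniform draw in [0.3, 1),
mimicking an underestimated planar outline. Stratum counts are fixed (not
Poisson) by default so that test sample sizes are exact; a Poisson option
exists.

**Environment.** Daily SST is a seasonal sinusoid (Southern-Hemisphere peak
pinned to mid-February) plus square anomaly pulses, plus Gaussian noise; the
SST series never has missing days. Chl-a is analogous (late-winter peak,
clipped at 0.01 mg m⁻³) with missing-value windows exactly where configured.
The generator does not emulate autocorrelated weather noise, trends, or the
spatial covariance of satellite pixels — recovery tests therefore validate
the *estimators*, not the realism of any particular ocean state.

Within transects colonies are exchangeable: the survey design does not
constrain within-transect spatial structure, so none is simulated.

## Thermal-stress metrics

Climatology: daily SST is averaged to monthly means per calendar year, then
across baseline years; MMM and mMM are the maximum and minimum of the 12
values. Leap days fall into February. The default baseline is the full
available record — a deliberate choice, since the fixed satellite-era
baseline used by operational products cannot be recomputed from a short
extract; an externally supplied MMM/mMM can be injected by constructing
`Climatology` directly, and the optional external-extract check does exactly
that.

Stress metrics use a trailing 84-day window *including* the current day:
DHW_0C sums positive exceedances of MMM (divided by 7 → °C-weeks), with a
configurable anomaly threshold (0 °C by default, which accumulates low-level
heat stress and therefore exceeds the conventional +1 °C-threshold product);
DCW_xC sums deficits below mMM + x for x = 0, 1. The first 83 days are
reported missing (burn-in) rather than as partial sums. DCW is negative
internally ("more negative = more cold stress") and reported as a magnitude
in summaries. By construction |DCW_1C| ≥ |DCW_0C| pointwise.

Annual summaries take calendar-year means of SST and gap-filled Chl-a and
within-year maxima of the rolling metrics. The per-year stress predictor is
the annual maximum (not the value on survey dates) — a documented,
configurable-by-subsetting choice; partial calendar years are excluded with
a warning. Chl-a gap filling interpolates interior gaps linearly in time and
never extrapolates at the edges.

## Size structure

All log transforms are natural log. The base does not affect KS statistics,
quintile membership or skewness — only the scale of reported log-area
quantities. Mean colony size is reported on the raw cm² scale while CV and
skewness are computed on log-area: the published CV range (0.31–0.51) and
near-zero skewness values are consistent with log-scale computation, while
the published means (66.42, 708.47 cm²) are raw-scale. This pairing is an
assumption and is stated here prominently.

Quintile boundaries sit at the 20/40/60/80th percentiles of log-area pooled
across *all* years within genus × habitat (linear-interpolation quantile
convention), and the same boundaries are applied to every year — abundance
changes are counted in fixed absolute size bins, not per-year relative bins.
Bins are left-closed/right-open; a value equal to a boundary goes to the
upper bin, so a fully degenerate pool lands in Q5 (flagged by a warning).
Skewness uses the adjusted Fisher–Pearson estimator and is reported missing
(not zero) below n = 3. The two-sample KS test pools transects — a single D
per comparison — matching how such comparisons are conventionally reported.

## Change estimation

Percent change is 100·(after − before)/before; a zero baseline yields a
missing estimate with a warning rather than an infinity. Uncertainty comes
from a stratified nonparametric bootstrap: colonies are resampled with
replacement within site × period cells (the resampling unit is the colony,
since size-class counts are colony-level statistics; whole-transect
resampling is available as a sensitivity mode), class counts and size metrics
are recomputed with the *fixed* pooled quintile scheme, and the n = 1000
replicate percent changes are summarised by the median and 66%/95%
highest-density intervals. The HPD of a sample is the shortest contiguous
window containing ⌈mass·n⌉ sorted values (leftmost window on ties). An
externally supplied replicate source — e.g. posterior draws of the same
quantities from a fitted abundance model — can be summarised through the
identical reporting path (`summarize_replicates`).

## Bayesian GLMs

Three families: Gaussian (identity link) for mean size, negative binomial
NB2 (log link; Var = μ + μ²/φ) for counts pooled across transects, and
Bernoulli (logit link) for condition flags. Counts are pooled per site and
the survey area per site is constant (three 36 m² transects), so no exposure
offset is used. Continuous predictors are standardized internally
(coefficients are reported on the standardized scale; predictions reverse
the transform); categorical predictors use treatment coding with the first
sorted level as reference.

**Priors** are weakly informative and zero-centred: Normal(0, 2.5) on
standardized-predictor coefficients, Normal(0, 5) on intercepts, half-Normal
(scale 10) on the NB dispersion φ. For the Gaussian family all scales are
multiplied by the response SD, the intercept prior is centred at the
response mean, and the residual scale has a half-Normal prior at 5× the
response SD — keeping the same priors weakly informative for responses of
any magnitude. All scales are exposed in `Priors`. A numerical floor
(1e-8 × response scale) keeps the Gaussian likelihood finite for degenerate
zero-variance responses.

**Sampling** is Metropolis–Hastings with a mixture kernel: with probability
one-half an independence proposal from a multivariate-t (df 7, mildly
inflated) centred on the posterior mode with the Laplace-approximation
covariance (mode found by BFGS, Hessian by central finite differences with
eigenvalue repair), otherwise a random-walk step with the standard
2.38/√d scaling of the same covariance. For these log-concave GLM posteriors
at moderate n the independence component yields near-iid draws (effective
sample sizes above half the retained draws), while the random-walk component
guarantees correct local exploration wherever the Laplace approximation is
poor. Chain semantics follow the brms convention: 3 chains × 4000 iterations,
warmup 200, thinning 5 → (4000 − 200)/5 = 760 retained draws per chain,
2280 total, so diagnostics are comparable across tools.

**Diagnostics.** Rank-normalized split R-hat (ArviZ) with a convergence
screen at 1.05 — the diagnostic is standard, the cut-off is this package's
choice; non-converged fits are flagged and model comparison refuses them
unless forced. Credible intervals are 95% HPD intervals. Bayes R² is
computed per draw as Var(fitted means) / (Var(fitted means) + expected
residual variance), with the family-appropriate residual term (σ² for
Gaussian, mean p(1−p) for Bernoulli, mean μ + μ²/φ for NB). Model fit uses
PSIS leave-one-out cross-validation (ArviZ) with LOOIC = −2·elpd; model
weights are pseudo-BMA, w_i ∝ exp(−ΔLOOIC_i/2), matching a
"relative likelihood" reading of information-criterion weights (stacking was
considered and left out of scope; the weight function is isolated so an
alternative can be swapped in).

**Environmental model set.** Pairwise |Pearson r| > 0.8 among the annual
predictors drops the lower-priority member of each collinear pair (the
priority order keeps DCW_1C over DCW_0C, mirroring the choice to assess cold
stress with the 1 °C-threshold metric); constant predictors are flagged as
undefined. The candidate set is every additive subset of the screened
predictors {SST_mean, Chla_mean, DHW_0C, DCW_1C} — 15 non-empty models plus
intercept-only — fitted as NB2 regressions of per-site-year small-coral
counts and ranked by LOOIC. Environmental predictors enter standardized
(assumed, as the source does not state it).

## Problem sizes and numerical tolerances

Moment matching verifies to 1e-6; rolling stress metrics agree with an
explicit 84-term sum to 1e-9. Parameter-recovery checks run at the published
survey sizes (n = 6992 / 3207 / 2996 bleaching outcomes; 13,195 colonies for
the partial-mortality model; 10⁶ draws for size-moment recovery) with full
chain settings. Statistical property suites are sized for a single CPU:
coverage of planted GLM coefficients uses 50 replicate datasets of n = 500
per family with 2 × 2500-iteration chains (chain length chosen so that HPD
endpoint noise is small relative to the 95% interval width); bootstrap
coverage uses 200 datasets of 2 × 1000 colonies with 400 replicates each.
The bundled demo uses ~4,300 colonies, 12 years of daily environment at four
sites, 1000 bootstrap replicates and 3 × 1500-iteration chains, and runs in
roughly ten seconds.

## Known limitations

- The generator plants marginal abundances and condition rates; it does not
  simulate recruitment, growth or mortality mechanistically, so temporal
  autocorrelation of real populations is absent.
- The Laplace-centred independence proposal assumes a unimodal posterior;
  strongly multimodal posteriors (not expected for these GLMs) would reduce
  to random-walk efficiency and should be caught by the R-hat screen.
- PSIS-LOO warnings (high Pareto k) are possible for tiny site-year count
  datasets; comparisons on such fits should be read qualitatively.
- NetCDF ingestion is not implemented; daily series are exchanged as long
  CSV (site, date, value). Satellite data acquisition, regridding and
  logger bias correction are out of scope.
- Partial capture is modelled as multiplicative area truncation with a
  uniform fraction; the real truncation process depends on colony geometry
  and frame placement.
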