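# coraldemog

Decadal, size-structured demography of subtropical coral populations:
a tested, reusable pipeline for colony size-frequency analysis around a mass
bleaching event, with custom thermal-stress climatologies, stratified bootstrap
change estimation, and Bayesian GLMs linking bleaching, partial mortality and
juvenile abundance to colony size, taxon, survey period and environment.

The package targets ecologists analysing repeated photographic belt-transect
surveys of coral colonies (here three genera — *Acropora*, *Pocillopora*,
*Turbinaria* — at inshore/offshore subtropical reef sites), where field data
are often restricted: a first-class synthetic-data generator emulates the
survey and satellite inputs with *planted, recoverable* parameters, so every
stage of the analysis can be validated by parameter recovery.

## What it computes

**Thermal stress from daily SST** (`env_metrics`). From a monthly-mean
climatology with hot and cold baselines (MMM = max of the 12 monthly means,
mMM = min), rolling 84-day (12-week, inclusive) accumulations in °C-weeks:

    DHW_0C(t) = Σ_{d=t-83..t} max(0, SST(d) − MMM) / 7
    DCW_xC(t) = Σ_{d=t-83..t} min(0, SST(d) − (mMM + x)) / 7,   x ∈ {0, 1}

The 0 °C anomaly threshold accumulates low-level heat stress (values exceed
the conventional satellite DHW); DCW is stored negative and reported as a
magnitude. Chlorophyll-a gaps are filled by linear interpolation (interior
gaps only), and per-site annual summaries (SST_mean, Chla_mean, max DHW_0C,
max |DCW_1C|) feed the abundance models.

**Size structure** (`size_structure`). Preprocessing applies a 0.8 cm² lower
size cut-off, maps survey years to periods (P1 pre-bleaching: 2010/2012;
P2 bleaching year: 2016; P3 recovery: 2018/2019) and takes natural-log areas.
Quintile size classes use log-area boundaries at the pooled 20/40/60/80th
percentiles per genus × habitat, **fixed across years** (Q1 = small,
Q2–Q4 = medium, Q5 = large). Summaries report raw-scale mean area and
log-scale CV (σ/μ), adjusted Fisher–Pearson skewness and 20th/80th
percentiles; distributions are compared with two-sample Kolmogorov–Smirnov
tests.

**Change estimation** (`change_metrics`). Percent changes
100·(after − before)/before in size-class abundance and size metrics between
periods, with a stratified nonparametric bootstrap (colonies resampled with
replacement within site × period, n = 1000 replicates) summarised by the
median and 66%/95% highest-density intervals (shortest interval containing
⌈mass·n⌉ sorted replicates).

**Bayesian GLMs** (`bayes_models`). Gaussian (mean size), log-link negative
binomial (counts) and Bernoulli-logit (bleaching, partial mortality) models
with interactions, e.g. `bleached ~ logArea * taxa` and
`partial_mortality ~ bleaching`. Posteriors are sampled by a
Metropolis–Hastings mixture kernel (Laplace-mode multivariate-t independence
proposals + random-walk moves) with brms-style chain semantics (default
3 chains × 4000 iterations, warmup 200, thin 5 → 2280 retained draws).
Diagnostics: rank-normalized R-hat (convergence screen at 1.05), PSIS-LOO /
LOOIC with pseudo-BMA model weights `w_i ∝ exp(−ΔLOOIC_i/2)`, Bayes R², and
95% HPD credible intervals. A collinearity screen (|Pearson r| > 0.8) reduces
the environmental predictor set (keeping the 1 °C-threshold cold-stress metric
over the 0 °C one) before fitting all additive subsets of
{SST_mean, Chla_mean, DHW_0C, DCW_1C} to per-site-year small-coral counts.

**Synthetic surveys** (`synth`). Colony log-areas follow a skew-normal
distribution whose parameters are moment-matched (to 1e-6) to a target
raw-scale mean area, log-scale CV and log-scale skewness; bleaching and
partial mortality follow size-dependent logistic models; 10.7% of colonies
are flagged partially captured (area shrunk by a uniform factor in [0.3, 1));
daily SST/Chl-a series combine a seasonal sinusoid, anomaly pulses, noise and
configurable Chl-a gaps.

## Worked example

Moment-match a size model to published Pocillopora summaries (mean area
66.42 cm², log-area CV 0.51, skewness −0.03) and verify a planted heat pulse:

```python
import numpy as np
from coraldemog import synth, env_metrics as em

model = synth.solve_size_params(66.42, 0.51, -0.03)
print(model.xi, model.omega, model.alpha)
# 3.659 1.668 -0.543   (skew-normal on ln area; mean of ln area = 3.024)

env = synth.EnvModel(baseline_sst=25.0, seasonal_amplitude=0.0,
                     anomaly_events=[("2011-03-01", 84, 0.7)])
sst, _ = synth.generate_daily_env(env, "2010-01-01", "2012-12-31", seed=0)
clim = em.compute_climatology(sst, baseline_years=[2010])
print(em.compute_dhw(sst, clim).max())
# 8.4   (+0.7 °C sustained for 84 days = 0.7 × 84 / 7 °C-weeks)
```

Run the bundled end-to-end demonstration (four sites, six survey visits,
~4,300 colonies, 12 years of daily environment; about 10 s on one CPU):

```bash
coraldemog demo --out-dir runs/demo
```

Among the outputs (all tidy CSV plus `manifest.json` with seeds, versions and
digests): `ks_tests.csv` shows the planted taxon contrast
(Pocillopora vs Turbinaria D = 0.58, Acropora vs Turbinaria D = 0.44 —
the two most dissimilar size structures); `changes.csv` reports, e.g., a
−12.5% median change in small offshore Pocillopora between P1 and P3 with
95% HPD (−34.2, +9.1); and `model_params.csv` recovers the planted
bleached → partial-mortality effect (`partial_mortality ~ bleached`:
coefficient median 1.38, 95% HPD 0.96–1.83, R-hat ≤ 1.01). `env_annual.csv`
places the maximum heat stress in 2016, the bleaching year, as configured.

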