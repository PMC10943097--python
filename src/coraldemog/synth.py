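"""Synthetic colony tables and daily environmental series with planted parameters.

The generator emulates the structure of a subtropical photographic belt-transect
survey: three coral genera (*Acropora*, *Pocillopora*, *Turbinaria*) observed at
inshore/offshore sites over repeated years, with colony planar areas in cm²,
bleaching and partial-mortality flags, and a fraction of colonies only partially
captured in the photo frame. Daily SST and chlorophyll-a series are built from a
seasonal sinusoid plus configurable anomaly pulses, noise and (for Chl-a)
missing-data windows.

Colony sizes are drawn from a skew-normal distribution on natural-log area; a
lognormal is symmetric on the log scale and cannot plant the nonzero skewness
values that real size-frequency distributions show, so the skew-normal's shape
parameter carries that third moment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, log_ndtr

__all__ = [
    "InfeasibleSkewnessError",
    "ConfigurationError",
    "TaxonSizeModel",
    "ConditionModel",
    "EnvModel",
    "SurveyDesign",
    "solve_size_params",
    "generate_colony_table",
    "generate_daily_env",
    "COLONY_COLUMNS",
]

# maximum |skewness| of a skew-normal is ~0.9953; stay inside it
_SKEW_FEASIBLE = 0.99

COLONY_COLUMNS = [
    "site",
    "shelf",
    "year",
    "month",
    "transect",
    "genus",
    "area_cm2",
    "bleached",
    "partial_mortality",
    "partially_captured",
]


class InfeasibleSkewnessError(ValueError):
    """Requested log-scale skewness outside the skew-normal feasible range."""


class ConfigurationError(ValueError):
    """Generator design references a stratum with no configured model."""


@dataclass(frozen=True)
class TaxonSizeModel:
    """Skew-normal model of log colony area for one genus x habitat stratum.

    ``xi``/``omega``/``alpha`` are the location, scale and shape of the
    skew-normal on ln(area in cm²); ``omega == 0`` denotes the degenerate
    point-mass limit at ``xi``.
    """

    taxon: str
    habitat: str
    xi: float
    omega: float
    alpha: float
    n_per_stratum: int = 0

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega (log-scale) must be >= 0")
        if self.n_per_stratum < 0:
            raise ValueError("n_per_stratum must be >= 0")

    @property
    def _delta(self) -> float:
        return self.alpha / math.sqrt(1.0 + self.alpha**2)

    @property
    def mean_log(self) -> float:
        return self.xi + self.omega * self._delta * math.sqrt(2.0 / math.pi)

    @property
    def sd_log(self) -> float:
        return self.omega * math.sqrt(1.0 - 2.0 * self._delta**2 / math.pi)

    @property
    def cv_log(self) -> float:
        return self.sd_log / self.mean_log

    @property
    def skew_log(self) -> float:
        return _skewnorm_skewness(self._delta)

    @property
    def mean_area(self) -> float:
        """Raw-scale mean E[exp(X)] from the skew-normal moment generating function."""
        if self.omega == 0.0:
            return math.exp(self.xi)
        return 2.0 * math.exp(
            self.xi + 0.5 * self.omega**2 + log_ndtr(self._delta * self.omega)
        )

    def sample_log_area(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.omega == 0.0:
            return np.full(n, self.xi)
        return stats.skewnorm.rvs(
            self.alpha, loc=self.xi, scale=self.omega, size=n, random_state=rng
        )


def _skewnorm_skewness(delta: float) -> float:
    muz = delta * math.sqrt(2.0 / math.pi)
    sigz2 = 1.0 - muz**2
    return 0.5 * (4.0 - math.pi) * muz**3 / sigz2**1.5


def solve_size_params(
    target_mean_area: float,
    target_cv_log: float,
    target_skew_log: float,
    *,
    taxon: str = "",
    habitat: str = "",
    n_per_stratum: int = 0,
    tol: float = 1e-6,
) -> TaxonSizeModel:
    """Moment-match a skew-normal log-area model to printed summary statistics.

    Solves for (xi, omega, alpha) such that the raw-scale mean area, the
    log-scale coefficient of variation (sd/mean of ln area) and the log-scale
    skewness equal the targets to within ``tol``.

    Raises
    ------
    InfeasibleSkewnessError
        If ``|target_skew_log| >= 0.99`` (beyond the skew-normal family).
    ValueError
        If the moment system cannot be bracketed or verified to ``tol``.
    """
    if target_mean_area <= 0.8:
        raise ValueError("target_mean_area must exceed the 0.8 cm2 size cut-off")
    if target_cv_log < 0:
        raise ValueError("target_cv_log must be >= 0")
    if abs(target_skew_log) >= _SKEW_FEASIBLE:
        raise InfeasibleSkewnessError(
            f"log-scale skewness {target_skew_log} outside the feasible range "
            f"(-{_SKEW_FEASIBLE}, {_SKEW_FEASIBLE}) of the skew-normal family"
        )

    if target_cv_log == 0.0:
        if target_skew_log != 0.0:
            raise InfeasibleSkewnessError(
                "a zero-variance (point mass) model cannot carry nonzero skewness"
            )
        return TaxonSizeModel(
            taxon, habitat, xi=math.log(target_mean_area), omega=0.0, alpha=0.0,
            n_per_stratum=n_per_stratum,
        )

    # shape: skewness is strictly increasing in delta
    if target_skew_log == 0.0:
        delta = 0.0
    else:
        delta = optimize.brentq(
            lambda d: _skewnorm_skewness(d) - target_skew_log,
            -1.0 + 1e-12, 1.0 - 1e-12, xtol=1e-14,
        )
    alpha = delta / math.sqrt(1.0 - delta**2) if abs(delta) < 1.0 else math.inf
    muz = delta * math.sqrt(2.0 / math.pi)
    sigz = math.sqrt(1.0 - muz**2)
    log_m = math.log(target_mean_area)

    def f(omega: float) -> float:
        mean_log = omega * sigz / target_cv_log
        xi = mean_log - omega * muz
        return (
            math.log(2.0) + xi + 0.5 * omega**2 + log_ndtr(delta * omega) - log_m
        )

    lo, hi = 1e-10, 1.0
    flo = f(lo)
    while f(hi) * flo > 0:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError("could not bracket a scale solving the moment system")
    omega = optimize.brentq(f, lo, hi, xtol=1e-13, rtol=1e-15)
    xi = omega * sigz / target_cv_log - omega * muz

    model = TaxonSizeModel(taxon, habitat, xi=xi, omega=omega, alpha=alpha,
                           n_per_stratum=n_per_stratum)
    checks = (
        abs(model.mean_area / target_mean_area - 1.0),
        abs(model.cv_log - target_cv_log),
        abs(model.skew_log - target_skew_log),
    )
    if max(checks) > tol:
        raise ValueError(f"moment match failed verification: residuals {checks}")
    return model


@dataclass(frozen=True)
class ConditionModel:
    """Logistic models for bleaching and partial mortality versus colony size.

    Linear predictors use centred log-area, ``log_area - logarea_center``, so
    the intercepts are interpretable as logit-probabilities at a typical colony
    size. ``pm_bleached_boost`` shifts the partial-mortality logit for bleached
    colonies, and ``partial_capture_rate`` is the probability that a colony
    extends beyond the photo frame (its planar area is then underestimated by a
    uniform factor in [0.3, 1)).
    """

    bleach_intercept: float = 0.0
    bleach_slope: float = 0.0
    pm_intercept: float = -4.0
    pm_slope: float = 0.0
    pm_bleached_boost: float = 0.0
    partial_capture_rate: float = 0.107
    logarea_center: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.partial_capture_rate <= 1.0:
            raise ValueError("partial_capture_rate must be in [0, 1]")

    def bleach_probability(self, log_area: np.ndarray) -> np.ndarray:
        x = np.asarray(log_area) - self.logarea_center
        return expit(self.bleach_intercept + self.bleach_slope * x)

    def pm_probability(self, log_area: np.ndarray, bleached: np.ndarray) -> np.ndarray:
        x = np.asarray(log_area) - self.logarea_center
        return expit(
            self.pm_intercept
            + self.pm_slope * x
            + self.pm_bleached_boost * np.asarray(bleached)
        )


@dataclass(frozen=True)
class SurveyDesign:
    """Sites (with shelf position), survey visits and transect count."""

    sites: Mapping[str, str]  # site name -> "inshore" | "offshore"
    surveys: Sequence[tuple[int, int]]  # (year, month) per visit
    transects: int = 3

    def __post_init__(self) -> None:
        bad = {s for s, h in self.sites.items() if h not in ("inshore", "offshore")}
        if bad:
            raise ConfigurationError(f"sites with unknown shelf position: {sorted(bad)}")
        if self.transects < 1:
            raise ConfigurationError("need at least one transect")


def generate_colony_table(
    size_models: Mapping[tuple[str, str], TaxonSizeModel],
    condition_models: Mapping[str, ConditionModel],
    design: SurveyDesign,
    seed: int,
    poisson_counts: bool = False,
) -> pd.DataFrame:
    """Draw a colony observation table for every site x visit x genus stratum.

    ``size_models`` is keyed by (genus, shelf position). Counts per stratum are
    fixed at ``n_per_stratum`` by default (exactly reproducible stratum sizes);
    ``poisson_counts=True`` draws them Poisson instead. Output is byte-identical
    for a fixed seed.
    """
    genera = sorted({g for g, _ in size_models})
    for genus in genera:
        if genus not in condition_models:
            raise ConfigurationError(f"no condition model for genus {genus!r}")
    for genus in genera:
        for shelf in sorted(set(design.sites.values())):
            if (genus, shelf) not in size_models:
                raise ConfigurationError(
                    f"no size model for stratum ({genus!r}, {shelf!r})"
                )

    rng = np.random.default_rng(seed)
    frames: list[pd.DataFrame] = []
    for site in sorted(design.sites):
        shelf = design.sites[site]
        for year, month in design.surveys:
            for genus in genera:
                sm = size_models[(genus, shelf)]
                cm = condition_models[genus]
                n = int(rng.poisson(sm.n_per_stratum)) if poisson_counts else sm.n_per_stratum
                if n == 0:
                    continue
                log_area = sm.sample_log_area(n, rng)
                area = np.exp(log_area)
                bleached = rng.random(n) < cm.bleach_probability(log_area)
                pm = rng.random(n) < cm.pm_probability(log_area, bleached)
                captured_part = rng.random(n) < cm.partial_capture_rate
                frac = rng.uniform(0.3, 1.0, n)
                area_obs = np.where(captured_part, area * frac, area)
                frames.append(
                    pd.DataFrame(
                        {
                            "site": site,
                            "shelf": shelf,
                            "year": year,
                            "month": month,
                            "transect": rng.integers(1, design.transects + 1, n),
                            "genus": genus,
                            "area_cm2": area_obs,
                            "bleached": bleached.astype(int),
                            "partial_mortality": pm.astype(int),
                            "partially_captured": captured_part.astype(int),
                        }
                    )
                )
    if not frames:
        return pd.DataFrame(
            {c: pd.Series(dtype=t) for c, t in zip(
                COLONY_COLUMNS,
                [str, str, int, int, int, str, float, int, int, int],
            )}
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class EnvModel:
    """Seasonal sinusoid + anomaly pulses + noise for daily SST and Chl-a.

    ``anomaly_events`` are (start date, duration in days, signed magnitude °C)
    step pulses added to SST. ``gap_spec`` lists (start date, duration in days)
    windows set to missing in the Chl-a series (satellite dropouts); the SST
    series never contains missing days. The SST seasonal peak is pinned to
    mid-February and the Chl-a peak to late austral winter, matching a Southern
    Hemisphere subtropical annual cycle.
    """

    baseline_sst: float = 21.5
    seasonal_amplitude: float = 3.0
    anomaly_events: Sequence[tuple[str, int, float]] = field(default_factory=tuple)
    chla_baseline: float = 0.6
    chla_seasonal_amplitude: float = 0.2
    gap_spec: Sequence[tuple[str, int]] = field(default_factory=tuple)
    sst_noise_sd: float = 0.0
    chla_noise_sd: float = 0.0

    _SST_PEAK_DOY = 45  # mid-February
    _CHLA_PEAK_DOY = 240  # late August


def generate_daily_env(
    env_model: EnvModel,
    start: str,
    end: str,
    seed: int,
    site: str = "site",
) -> tuple[pd.Series, pd.Series]:
    """Generate (sst, chla) daily series as pandas Series named after the site.

    The date range must span at least one full year (a monthly climatology is
    undefined otherwise); at least two years are recommended so every calendar
    month is averaged over multiple years.
    """
    dates = pd.date_range(start, end, freq="D")
    if len(dates) < 365:
        raise ValueError("date range must span at least one full year")
    if len(dates) < 2 * 365:
        warnings.warn("date range under two years: climatology will be single-year")

    rng = np.random.default_rng(seed)
    doy = dates.dayofyear.to_numpy()
    sst = env_model.baseline_sst + env_model.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - env_model._SST_PEAK_DOY) / 365.25
    )
    for ev_start, ev_days, ev_delta in env_model.anomaly_events:
        t0 = pd.Timestamp(ev_start)
        mask = (dates >= t0) & (dates < t0 + pd.Timedelta(days=int(ev_days)))
        sst = sst + np.where(mask, float(ev_delta), 0.0)
    if env_model.sst_noise_sd > 0:
        sst = sst + rng.normal(0.0, env_model.sst_noise_sd, len(dates))

    chla = env_model.chla_baseline + env_model.chla_seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - env_model._CHLA_PEAK_DOY) / 365.25
    )
    if env_model.chla_noise_sd > 0:
        chla = chla + rng.normal(0.0, env_model.chla_noise_sd, len(dates))
    chla = np.clip(chla, 0.01, None)
    chla = chla.astype(float)
    for gap_start, gap_days in env_model.gap_spec:
        t0 = pd.Timestamp(gap_start)
        mask = (dates >= t0) & (dates < t0 + pd.Timedelta(days=int(gap_days)))
        chla = np.where(mask, np.nan, chla)

    sst_s = pd.Series(sst, index=dates, name=site)
    chla_s = pd.Series(chla, index=dates, name=site)
    return sst_s, chla_s
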