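"""Colony-table preprocessing, size-frequency summaries and quintile classes.

All log transforms are natural log; base choice does not affect KS statistics,
quintile membership or skewness, only the reported scale of log-area summaries.
Mean colony size is reported on the raw cm² scale, while the coefficient of
variation and skewness are computed on log-area — the scale on which coral
size-frequency distributions are conventionally compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENERA",
    "SIZE_CUTOFF_CM2",
    "PERIOD_BY_YEAR",
    "QuintileScheme",
    "KSResult",
    "DegenerateSchemeWarning",
    "preprocess",
    "quintile_scheme",
    "build_schemes",
    "assign_size_classes",
    "summarize_sizes",
    "ks_compare",
]

GENERA = ("Acropora", "Pocillopora", "Turbinaria")

# lower size cut-off (~1 cm diameter): smaller colonies are inconsistently
# detected in photographs and are excluded
SIZE_CUTOFF_CM2 = 0.8

# survey years -> analysis periods: pre-bleaching, bleaching year + aftermath,
# recovery window
PERIOD_BY_YEAR = {2010: "P1", 2012: "P1", 2016: "P2", 2018: "P3", 2019: "P3"}

SIZE_CLASS_BY_QUINTILE = {1: "small", 2: "medium", 3: "medium", 4: "medium", 5: "large"}

_REQUIRED_COLUMNS = [
    "site", "shelf", "year", "month", "transect", "genus", "area_cm2",
    "bleached", "partial_mortality", "partially_captured",
]


class DegenerateSchemeWarning(UserWarning):
    """Quintile boundaries are tied; size classes are not a 20% partition."""


def preprocess(
    raw_table: pd.DataFrame, include_partially_captured: bool = True
) -> pd.DataFrame:
    """Validate and filter a raw colony table into the analysis table.

    Applies the 0.8 cm² lower size cut-off, maps survey years to periods,
    adds ``period`` and ``log_area`` (natural log of area) columns, and — when
    ``include_partially_captured`` is False (sensitivity mode) — drops colonies
    whose outline extended beyond the photo frame.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in raw_table.columns]
    if missing:
        raise ValueError(f"colony table missing required columns: {missing}")
    table = raw_table.copy()
    if table.empty:
        table["period"] = pd.Series(dtype=str)
        table["log_area"] = pd.Series(dtype=float)
        return table

    bad_genus = sorted(set(table["genus"]) - set(GENERA))
    if bad_genus:
        raise ValueError(f"unknown genus values: {bad_genus}")
    if (table["area_cm2"] <= 0).any():
        n_bad = int((table["area_cm2"] <= 0).sum())
        raise ValueError(f"{n_bad} rows have non-positive planar area")
    unmapped = sorted(set(table["year"]) - set(PERIOD_BY_YEAR))
    if unmapped:
        rows = table.index[table["year"].isin(unmapped)].tolist()
        raise ValueError(
            f"years {unmapped} have no period mapping (rows {rows[:10]}"
            f"{'...' if len(rows) > 10 else ''})"
        )

    table = table[table["area_cm2"] >= SIZE_CUTOFF_CM2]
    if not include_partially_captured:
        table = table[table["partially_captured"] == 0]
    table = table.copy()
    table["period"] = table["year"].map(PERIOD_BY_YEAR)
    table["log_area"] = np.log(table["area_cm2"].to_numpy(float))
    return table.reset_index(drop=True)


@dataclass(frozen=True)
class QuintileScheme:
    """Fixed log-area quintile boundaries for one genus x habitat.

    Boundaries sit at the 20/40/60/80th percentiles of log-area pooled across
    ALL years, so that year-to-year abundance comparisons count colonies in
    identical absolute size bins. Bins are left-closed/right-open (a value equal
    to a boundary goes to the upper bin); the last bin is closed above.
    Quintile 1 is "small", quintiles 2-4 "medium" and quintile 5 "large".
    """

    genus: str
    habitat: str
    boundaries: tuple[float, float, float, float]
    n_pool: int

    def __post_init__(self) -> None:
        b = self.boundaries
        if any(b[i] > b[i + 1] for i in range(3)):
            raise ValueError("quintile boundaries must be ascending")

    def quintiles(self, log_areas) -> np.ndarray:
        """Quintile index (1..5) for each log-area."""
        return np.searchsorted(np.asarray(self.boundaries), np.asarray(log_areas),
                               side="right") + 1

    def size_classes(self, log_areas) -> np.ndarray:
        q = self.quintiles(log_areas)
        return np.where(q == 1, "small", np.where(q == 5, "large", "medium"))


def quintile_scheme(table: pd.DataFrame, genus: str, habitat: str) -> QuintileScheme:
    """Compute the pooled-across-years quintile scheme for one genus x habitat."""
    pool = table[(table["genus"] == genus) & (table["shelf"] == habitat)]["log_area"]
    if len(pool) < 5:
        raise ValueError(
            f"need at least 5 colonies to form quintiles for ({genus}, {habitat}); "
            f"got {len(pool)}"
        )
    bounds = np.percentile(pool.to_numpy(float), [20, 40, 60, 80], method="linear")
    if len(np.unique(bounds)) < 4:
        warnings.warn(
            f"tied quintile boundaries for ({genus}, {habitat}): size classes "
            "will not hold 20% each",
            DegenerateSchemeWarning,
        )
    return QuintileScheme(genus, habitat, tuple(float(b) for b in bounds), len(pool))


def build_schemes(table: pd.DataFrame) -> dict[tuple[str, str], QuintileScheme]:
    """One pooled scheme per genus x habitat present in the table."""
    out = {}
    for (genus, habitat), _ in table.groupby(["genus", "shelf"]):
        out[(genus, habitat)] = quintile_scheme(table, genus, habitat)
    return out


def assign_size_classes(
    table: pd.DataFrame, schemes: dict[tuple[str, str], QuintileScheme]
) -> pd.DataFrame:
    """Add ``quintile`` and ``size_class`` columns using the fixed schemes."""
    table = table.copy()
    table["quintile"] = 0
    table["size_class"] = ""
    for (genus, habitat), scheme in schemes.items():
        mask = (table["genus"] == genus) & (table["shelf"] == habitat)
        la = table.loc[mask, "log_area"].to_numpy(float)
        table.loc[mask, "quintile"] = scheme.quintiles(la)
        table.loc[mask, "size_class"] = scheme.size_classes(la)
    return table


def _cv_log(log_areas: np.ndarray) -> float:
    mu = log_areas.mean()
    return float(log_areas.std(ddof=1) / mu) if len(log_areas) > 1 else np.nan


def summarize_sizes(
    table: pd.DataFrame, by: tuple[str, ...] = ("genus", "shelf", "period")
) -> pd.DataFrame:
    """Size-frequency summaries per stratum.

    ``mean_area`` is the raw-scale mean (cm²); ``cv`` is sd/mean of log-area;
    ``skewness`` is the adjusted Fisher–Pearson skewness of log-area (missing
    for n < 3); ``q20``/``q80`` are log-area percentiles under the
    linear-interpolation quantile convention.
    """
    rows = []
    for keys, grp in table.groupby(list(by)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        la = grp["log_area"].to_numpy(float)
        n = len(la)
        skew = float(stats.skew(la, bias=False)) if n >= 3 else np.nan
        q20, q80 = (np.percentile(la, [20, 80], method="linear")
                    if n else (np.nan, np.nan))
        rows.append(
            dict(zip(by, keys))
            | {
                "n": n,
                "mean_area": float(grp["area_cm2"].mean()),
                "cv": _cv_log(la),
                "skewness": skew,
                "q20": float(q20),
                "q80": float(q80),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov–Smirnov comparison of size-frequency distributions."""

    d: float
    p_value: float
    n1: int
    n2: int


def ks_compare(group_a, group_b) -> KSResult:
    """Two-sided two-sample KS test on log-areas (sup distance between ECDFs)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="auto")
    return KSResult(d=float(res.statistic), p_value=float(res.pvalue),
                    n1=len(a), n2=len(b))
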