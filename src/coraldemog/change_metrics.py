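"""Percentage changes between survey periods with bootstrap HPD uncertainty.

Uncertainty in size-class abundances and size-structure metrics is
characterised by a stratified nonparametric bootstrap (default 1000 replicates):
colonies are resampled with replacement within site x period cells, size-class
counts and metrics are recomputed with the FIXED pooled quintile scheme, and the
per-replicate percent changes are summarised by their median and 66%/95%
highest-density intervals. An external replicate source (e.g. posterior draws of
the same quantities) can be summarised through the same reporting path.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .size_structure import QuintileScheme

__all__ = [
    "percent_change",
    "hpd",
    "bootstrap_changes",
    "summarize_replicates",
    "DEFAULT_PERIOD_PAIRS",
]

DEFAULT_PERIOD_PAIRS = (("P1", "P2"), ("P2", "P3"), ("P1", "P3"))

_METRIC_NAMES = ("mean", "cv", "q20", "q80")


def percent_change(before: float, after: float) -> float:
    """100 * (after - before) / before; undefined (NaN, with warning) at before = 0."""
    if before == 0:
        warnings.warn("percent change undefined for a zero baseline; reporting NaN")
        return math.nan
    return 100.0 * (after - before) / before


def hpd(samples, mass: float) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted samples.

    This is the sample highest-density interval; for unimodal posteriors it
    estimates the highest-posterior-density credible interval. Ties in width are
    broken toward the leftmost interval.
    """
    x = np.sort(np.asarray(samples, float))
    n = len(x)
    if n == 0:
        raise ValueError("cannot form an HPD interval from an empty sample")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    m = min(n, math.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def _cell_arrays(table: pd.DataFrame) -> dict[tuple, dict[str, np.ndarray]]:
    cells = {}
    for key, grp in table.groupby(["site", "period"]):
        cells[key] = {
            "log_area": grp["log_area"].to_numpy(float),
            "area": grp["area_cm2"].to_numpy(float),
            "transect": grp["transect"].to_numpy(),
        }
    return cells


def _class_counts(log_area: np.ndarray, scheme: QuintileScheme) -> dict[str, int]:
    q = scheme.quintiles(log_area)
    return {
        "small": int((q == 1).sum()),
        "medium": int(((q >= 2) & (q <= 4)).sum()),
        "large": int((q == 5).sum()),
    }


def _metrics(log_area: np.ndarray, area: np.ndarray) -> dict[str, float]:
    if len(log_area) == 0:
        return {m: math.nan for m in _METRIC_NAMES}
    q20, q80 = np.percentile(log_area, [20, 80], method="linear")
    mu = log_area.mean()
    cv = log_area.std(ddof=1) / mu if len(log_area) > 1 else math.nan
    return {"mean": float(area.mean()), "cv": float(cv),
            "q20": float(q20), "q80": float(q80)}


def bootstrap_changes(
    table: pd.DataFrame,
    schemes: Mapping[tuple[str, str], QuintileScheme],
    period_pairs: Sequence[tuple[str, str]] = DEFAULT_PERIOD_PAIRS,
    n_boot: int = 1000,
    seed: int = 0,
    include_metrics: bool = True,
    resample_unit: str = "colony",
) -> pd.DataFrame:
    """Bootstrap percent changes in size-class abundance and size metrics.

    For every genus x habitat stratum and period pair, colonies are resampled
    with replacement within each site x period cell (``resample_unit="transect"``
    resamples whole transects instead, as a sensitivity mode), class counts and
    size metrics are recomputed with the fixed pooled scheme, and percent
    changes collected over ``n_boot`` replicates. Output is tidy: one row per
    stratum x quantity x period pair with median and 66%/95% HPD bounds.
    A stratum with an empty period is reported with missing estimates.
    """
    if resample_unit not in ("colony", "transect"):
        raise ValueError("resample_unit must be 'colony' or 'transect'")
    rng = np.random.default_rng(seed)
    rows = []
    quantities = ["small", "medium", "large"] + (
        list(_METRIC_NAMES) if include_metrics else []
    )
    for (genus, habitat), stratum in table.groupby(["genus", "shelf"]):
        scheme = schemes[(genus, habitat)]
        cells = _cell_arrays(stratum)
        periods_present = {p for (_, p) in cells}
        reps: dict[str, dict[str, np.ndarray]] = {
            p: {q: np.empty(n_boot) for q in quantities} for p in periods_present
        }
        for b in range(n_boot):
            pooled_la: dict[str, list[np.ndarray]] = {p: [] for p in periods_present}
            pooled_a: dict[str, list[np.ndarray]] = {p: [] for p in periods_present}
            for (site, period), arrs in cells.items():
                n = len(arrs["log_area"])
                if resample_unit == "colony":
                    idx = rng.integers(0, n, n)
                else:
                    tr = np.unique(arrs["transect"])
                    chosen = rng.choice(tr, size=len(tr), replace=True)
                    idx = np.concatenate(
                        [np.flatnonzero(arrs["transect"] == t) for t in chosen]
                    )
                pooled_la[period].append(arrs["log_area"][idx])
                pooled_a[period].append(arrs["area"][idx])
            for period in periods_present:
                la = np.concatenate(pooled_la[period])
                counts = _class_counts(la, scheme)
                for q in ("small", "medium", "large"):
                    reps[period][q][b] = counts[q]
                if include_metrics:
                    met = _metrics(la, np.concatenate(pooled_a[period]))
                    for q in _METRIC_NAMES:
                        reps[period][q][b] = met[q]
        for p_before, p_after in period_pairs:
            for quantity in quantities:
                row = {
                    "genus": genus,
                    "shelf": habitat,
                    "quantity": quantity,
                    "period_pair": f"{p_before}-{p_after}",
                    "n_boot": n_boot,
                }
                if p_before not in periods_present or p_after not in periods_present:
                    row |= {
                        "median_pct": math.nan,
                        "hpd66_lo": math.nan, "hpd66_hi": math.nan,
                        "hpd95_lo": math.nan, "hpd95_hi": math.nan,
                        "missing": True,
                    }
                    rows.append(row)
                    continue
                before = reps[p_before][quantity]
                after = reps[p_after][quantity]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    with np.errstate(divide="ignore", invalid="ignore"):
                        pct = np.where(
                            before != 0, 100.0 * (after - before) / before, np.nan
                        )
                pct = pct[np.isfinite(pct)]
                if len(pct) == 0:
                    row |= {
                        "median_pct": math.nan,
                        "hpd66_lo": math.nan, "hpd66_hi": math.nan,
                        "hpd95_lo": math.nan, "hpd95_hi": math.nan,
                        "missing": True,
                    }
                else:
                    lo66, hi66 = hpd(pct, 0.66)
                    lo95, hi95 = hpd(pct, 0.95)
                    row |= {
                        "median_pct": float(np.median(pct)),
                        "hpd66_lo": lo66, "hpd66_hi": hi66,
                        "hpd95_lo": lo95, "hpd95_hi": hi95,
                        "missing": False,
                    }
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_replicates(replicates: pd.DataFrame) -> pd.DataFrame:
    """Summarise externally supplied per-replicate percent changes.

    ``replicates`` must have columns genus, shelf, quantity, period_pair, value
    — e.g. percent changes computed from posterior draws of a fitted abundance
    model — and is reduced to the same median/HPD table that
    :func:`bootstrap_changes` emits.
    """
    required = {"genus", "shelf", "quantity", "period_pair", "value"}
    if not required.issubset(replicates.columns):
        raise ValueError(f"replicates frame must have columns {sorted(required)}")
    rows = []
    for keys, grp in replicates.groupby(["genus", "shelf", "quantity", "period_pair"]):
        vals = grp["value"].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        lo66, hi66 = hpd(vals, 0.66)
        lo95, hi95 = hpd(vals, 0.95)
        rows.append(
            dict(zip(["genus", "shelf", "quantity", "period_pair"], keys))
            | {
                "median_pct": float(np.median(vals)),
                "hpd66_lo": lo66, "hpd66_hi": hi66,
                "hpd95_lo": lo95, "hpd95_hi": hi95,
                "n_boot": len(vals),
                "missing": False,
            }
        )
    return pd.DataFrame(rows)
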