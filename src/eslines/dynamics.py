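"""Dynamics of constraint-line characteristic values across years.

OLS-on-year trend tests with the two-star significance convention
("**" p < 0.01, "*" p < 0.05), type-7 (linear-interpolation) box
statistics with 1.5*IQR fences, series extrema, and the per-service
annual summary. A transcribed reference table of 21-year characteristic
values ships as a packaged CSV fixture for regression tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSeries",
    "TrendResult",
    "BoxStats",
    "trend_test",
    "mann_kendall",
    "box_stats",
    "series_extrema",
    "es_annual_report",
    "load_table4",
    "feature_series_from_curves",
]


@dataclass
class FeatureSeries:
    """One characteristic value of one pair tracked over calendar years."""

    pair_label: str
    feature: str  # threshold_x | threshold_y | k | b
    values: dict[int, float]
    units: str = ""

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        years = np.array(sorted(self.values))
        vals = np.array([self.values[y] for y in years], dtype=float)
        keep = np.isfinite(vals)
        return years[keep], vals[keep]


@dataclass
class TrendResult:
    slope: float
    intercept: float
    p_value: float
    flag: str  # "**" p<0.01, "*" 0.01<=p<0.05, "" otherwise
    n: int


@dataclass
class BoxStats:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    iqr: float
    lower_fence: float
    upper_fence: float
    outliers: list[float]


def significance_flag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def trend_test(series: FeatureSeries) -> TrendResult:
    """OLS of value on calendar year with a two-sided slope t-test."""
    years, vals = series.arrays()
    if years.size < 3:
        raise InsufficientDataError(
            f"trend test needs >= 3 years, got {years.size} for {series.pair_label}/{series.feature}"
        )
    if np.ptp(vals) == 0:
        logger.info("constant series %s/%s: slope 0, p = 1", series.pair_label, series.feature)
        return TrendResult(0.0, float(vals[0]), 1.0, "", years.size)
    res = stats.linregress(years, vals)
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        flag=significance_flag(res.pvalue),
        n=years.size,
    )


def mann_kendall(series: FeatureSeries) -> tuple[float, float]:
    """Alternative non-parametric trend check: Mann-Kendall S and p (normal approx)."""
    _, vals = series.arrays()
    n = vals.size
    if n < 3:
        raise InsufficientDataError("Mann-Kendall needs >= 3 years")
    s = sum(
        np.sign(vals[j] - vals[i]) for i in range(n - 1) for j in range(i + 1, n)
    )
    # tie-corrected variance
    _, counts = np.unique(vals, return_counts=True)
    var = (n * (n - 1) * (2 * n + 5) - (counts * (counts - 1) * (2 * counts + 5)).sum()) / 18.0
    if var <= 0:
        return float(s), 1.0
    z = (s - np.sign(s)) / np.sqrt(var)
    return float(s), float(2.0 * stats.norm.sf(abs(z)))


def box_stats(values: np.ndarray) -> BoxStats:
    """Box-plot statistics with type-7 quartiles and 1.5*IQR fences."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 4:
        raise InsufficientDataError(f"box stats need >= 4 values, got {vals.size}")
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = sorted(float(v) for v in vals[(vals < lo) | (vals > hi)])
    return BoxStats(
        minimum=float(vals.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(vals.max()),
        iqr=float(iqr),
        lower_fence=float(lo),
        upper_fence=float(hi),
        outliers=outliers,
    )


def series_extrema(series: FeatureSeries) -> tuple[tuple[float, int], tuple[float, int]]:
    """((min value, year), (max value, year)); ties resolved to the earliest year."""
    years, vals = series.arrays()
    if years.size == 0:
        raise InsufficientDataError("empty series")
    imin = int(np.argmin(vals))  # argmin/argmax return the first (earliest) index
    imax = int(np.argmax(vals))
    if (vals == vals[imin]).sum() > 1 or (vals == vals[imax]).sum() > 1:
        logger.info("tied extrema in %s/%s: earliest year reported", series.pair_label, series.feature)
    return (float(vals[imin]), int(years[imin])), (float(vals[imax]), int(years[imax]))


def es_annual_report(es_means: pd.DataFrame) -> pd.DataFrame:
    """Per-service summary of a (year x service-mean) table.

    ``es_means`` has a ``year`` column plus one column per service; the
    result holds min/max year+value, mean, OLS slope, p-value and flag.
    """
    if len(es_means) < 3:
        raise InsufficientDataError("annual report needs >= 3 years")
    rows = []
    for col in [c for c in es_means.columns if c != "year"]:
        series = FeatureSeries(
            pair_label=col,
            feature="annual_mean",
            values=dict(zip(es_means["year"].astype(int), es_means[col].astype(float))),
        )
        (vmin, ymin), (vmax, ymax) = series_extrema(series)
        trend = trend_test(series)
        rows.append(
            {
                "service": col,
                "min_value": vmin,
                "min_year": ymin,
                "max_value": vmax,
                "max_year": ymax,
                "mean": float(np.mean(series.arrays()[1])),
                "slope": trend.slope,
                "p_value": trend.p_value,
                "flag": trend.flag,
            }
        )
    return pd.DataFrame(rows)


def load_table4() -> pd.DataFrame:
    """Packaged 21-year reference table of characteristic values.

    Long format: year, pair, feature, value. ``threshold_x`` is the
    threshold of the constraining (x-axis) service of the pair,
    ``threshold_y`` the boundary height at the vertex; the SC_FP pair
    carries k and b instead. The published source prints the second row's
    year as a duplicate of the first; it is transcribed here as 2001.
    """
    with resources.files("eslines.data").joinpath("table4_features.csv").open() as fh:
        return pd.read_csv(fh)


def table4_series(pair: str, feature: str) -> FeatureSeries:
    """One FeatureSeries out of the packaged reference table."""
    df = load_table4()
    sel = df[(df["pair"] == pair) & (df["feature"] == feature)]
    if sel.empty:
        raise KeyError(f"no fixture column for pair={pair!r}, feature={feature!r}")
    return FeatureSeries(
        pair_label=pair,
        feature=feature,
        values=dict(zip(sel["year"].astype(int), sel["value"].astype(float))),
    )


def feature_series_from_curves(curves: pd.DataFrame) -> list[FeatureSeries]:
    """Split a run_pairs output table into per-(pair, feature) series."""
    out: list[FeatureSeries] = []
    ok = curves[curves["status"] == "ok"] if "status" in curves else curves
    for pair, grp in ok.groupby("pair"):
        features = ("k", "b") if (grp["form"] == "exponential").all() else (
            "threshold_x",
            "threshold_y",
        )
        for feat in features:
            if feat not in grp or grp[feat].isna().all():
                continue
            vals = {
                int(y): float(v)
                for y, v in zip(grp["year"], grp[feat])
                if np.isfinite(v)
            }
            if vals:
                out.append(FeatureSeries(pair_label=pair, feature=feat, values=vals))
    return out
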