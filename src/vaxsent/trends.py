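"""Weekly sentiment trends, overall averages, and correlation statistics.

Posts are aggregated by ISO week (Monday start) per (country, platform):
the weekly proportion of each class is class count / total count. Overall
per-platform proportions are reported as percentages rounded half-up to
two decimals, and the cross-platform figure for a country is the
unweighted arithmetic mean of the two platform percentages — the
convention that reproduces published overall figures from their
per-platform components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, timedelta
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import UsageError, week_start_of

CLASS_NAMES = {-1: "negative", 0: "neutral", 1: "positive"}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def week_start(ts) -> date:
    """Monday of the ISO week containing ``ts``."""
    return week_start_of(pd.Timestamp(ts).date())


def weekly_proportions(labeled: pd.DataFrame) -> pd.DataFrame:
    """Weekly per-class proportions per (country, platform).

    ``labeled`` needs columns timestamp, country, platform, label (-1/0/+1;
    NaN rows are excluded and counted in the frame's ``attrs``). The output
    is tidy: country, platform, class, week_start, n, proportion — with
    zero-post weeks emitted (n=0, proportion NaN) so series span the full
    corpus range without fabricating values.
    """
    df = labeled.copy()
    n_unlabeled = int(df["label"].isna().sum())
    df = df.dropna(subset=["label"])
    out_rows = []
    if len(df):
        df["label"] = df["label"].astype(int)
        df["week_start"] = df["timestamp"].map(week_start)
        all_weeks = _week_range(df["week_start"].min(), df["week_start"].max())
        for (country, platform), grp in df.groupby(["country", "platform"], dropna=False):
            totals = grp.groupby("week_start").size()
            by_class = grp.groupby(["week_start", "label"]).size()
            for wk in all_weeks:
                n = int(totals.get(wk, 0))
                for cls in (-1, 0, 1):
                    count = int(by_class.get((wk, cls), 0))
                    out_rows.append(
                        {
                            "country": country,
                            "platform": platform,
                            "class": CLASS_NAMES[cls],
                            "week_start": wk,
                            "n": n,
                            "proportion": count / n if n > 0 else np.nan,
                        }
                    )
    out = pd.DataFrame(
        out_rows, columns=["country", "platform", "class", "week_start", "n", "proportion"]
    )
    out.attrs["n_unlabeled"] = n_unlabeled
    return out


def _week_range(first: date, last: date) -> list[date]:
    weeks = []
    wk = first
    while wk <= last:
        weeks.append(wk)
        wk += timedelta(days=7)
    return weeks


def get_series(trends: pd.DataFrame, country: str, platform: str, cls: str) -> pd.DataFrame:
    """One (country, platform, class) trend, ordered by week."""
    mask = (
        (trends["country"] == country)
        & (trends["platform"] == platform)
        & (trends["class"] == cls)
    )
    return trends[mask].sort_values("week_start").reset_index(drop=True)


def overall_proportions(labeled: pd.DataFrame, by: str = "platform") -> pd.DataFrame:
    """Whole-window per-class percentages per platform (or other grouping).

    Percentages are half-up rounded to two decimals. Empty strata are
    simply absent; callers treat a missing stratum as not-available.
    """
    df = labeled.dropna(subset=["label"]).copy()
    rows = []
    for key, grp in df.groupby(by, dropna=False):
        total = len(grp)
        counts = grp["label"].astype(int).value_counts()
        for cls in (-1, 0, 1):
            rows.append(
                {
                    by: key,
                    "class": CLASS_NAMES[cls],
                    "n": int(counts.get(cls, 0)),
                    "percent": round_half_up(100.0 * counts.get(cls, 0) / total),
                }
            )
    return pd.DataFrame(rows, columns=[by, "class", "n", "percent"])


def cross_platform_average(per_platform: dict[str, dict[str, float]]) -> dict[str, float]:
    """Unweighted mean of two platforms' class percentages, half-up 2dp.

    ``per_platform`` maps platform -> {class name -> percentage}. Exactly
    two platforms are required; the operation is symmetric in them.
    """
    if len(per_platform) != 2:
        raise UsageError(f"expected exactly 2 platforms, got {sorted(per_platform)}")
    (pa, da), (pb, db) = per_platform.items()
    if set(da) != set(db):
        raise UsageError("platforms report different class sets")
    # average in decimal so printed two-decimal inputs stay exact
    # (27.95 + 17.04)/2 must be 22.495, not the float 22.4949...
    out = {}
    for cls in da:
        mean = (Decimal(repr(float(da[cls]))) + Decimal(repr(float(db[cls])))) / 2
        out[cls] = float(mean.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return out


def pearson_r(x, y) -> float:
    """Product-moment correlation; pairs with a missing value are dropped.

    Returns NaN (with a warning) for constant series, where r is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise UsageError("series must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise UsageError(f"need >= 3 paired observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("pearson_r undefined for a constant series; returning NaN")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def trend_strength(series: pd.DataFrame) -> float:
    """Correlation of a trend's proportions with integer week index.

    The sign gives the direction of the weekly trend, the magnitude its
    strength; missing weeks are dropped pairwise.
    """
    s = series.sort_values("week_start")
    weeks = np.arange(len(s), dtype=float)
    return pearson_r(weeks, s["proportion"].to_numpy(dtype=float))
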