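"""N-gram mining per sentiment class/time window and regional aggregation.

N-grams are contiguous within-post token sequences over cleaned text;
tables back word-cloud-style summaries of discourse around points of
interest on the trend curves. Regional aggregation averages ternary label
values per sub-national region onto the continuous -1..+1 map scale
(green = +1 positive, 0 neutral, red = -1 negative).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import UsageError
from .preprocess import CleanText


@dataclass(frozen=True)
class NGramTable:
    """Frequency table of order-n grams, sorted by count desc then gram."""

    n: int
    rows: tuple[tuple[tuple[str, ...], int], ...]
    scope: str = "all"

    @property
    def total(self) -> int:
        return sum(c for _, c in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gram": [" ".join(g) for g, _ in self.rows], "count": [c for _, c in self.rows]}
        )


def ngram_counts(clean_texts: Sequence[CleanText], n: int, scope: str = "all") -> NGramTable:
    """Count contiguous n-grams within each post; no cross-post grams.

    Posts shorter than n contribute nothing, so the total count equals
    sum over posts of max(0, len(tokens) - n + 1).
    """
    if n < 1:
        raise UsageError(f"n-gram order must be >= 1, got {n}")
    counter: Counter[tuple[str, ...]] = Counter()
    for ct in clean_texts:
        toks = ct.tokens
        counter.update(tuple(toks[i : i + n]) for i in range(len(toks) - n + 1))
    rows = tuple(sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])))
    return NGramTable(n=n, rows=rows, scope=scope)


def top_terms(table: NGramTable, k: int) -> NGramTable:
    """First k rows under the table's count-desc/lexicographic order."""
    if k < 1:
        raise UsageError(f"k must be >= 1, got {k}")
    return NGramTable(n=table.n, rows=table.rows[:k], scope=table.scope)


def write_ngram_csv(table: NGramTable, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# regional sentiment


@dataclass
class RegionSentimentResult:
    """Per-region aggregates plus the low-coverage regions held out."""

    table: pd.DataFrame  # region, n, mean_polarity, class
    low_coverage: pd.DataFrame  # region, n


def region_sentiment(
    labeled: pd.DataFrame,
    min_posts: int = 10,
    tau_geo: float = 0.05,
    *,
    use_continuous: bool = False,
) -> RegionSentimentResult:
    """Mean sentiment per region on the -1..+1 scale.

    By default the mean is over ternary label values, i.e.
    (n_pos - n_neg) / n; ``use_continuous=True`` averages the continuous
    combined polarity instead. Regions with fewer than ``min_posts``
    labeled posts are reported separately rather than mapped.
    """
    if min_posts < 1:
        raise UsageError("min_posts must be >= 1")
    value_col = "combined" if use_continuous else "label"
    df = labeled.dropna(subset=[value_col, "region"])
    rows, low = [], []
    for region, grp in df.groupby("region"):
        n = len(grp)
        if n < min_posts:
            low.append({"region": region, "n": n})
            continue
        mean = float(grp[value_col].astype(float).mean())
        if mean > tau_geo:
            cls = 1
        elif mean < -tau_geo:
            cls = -1
        else:
            cls = 0
        rows.append({"region": region, "n": n, "mean_polarity": mean, "class": cls})
    table = pd.DataFrame(rows, columns=["region", "n", "mean_polarity", "class"])
    low_df = pd.DataFrame(low, columns=["region", "n"])
    return RegionSentimentResult(table.sort_values("region").reset_index(drop=True),
                                 low_df.sort_values("region").reset_index(drop=True))


def attach_geojson(
    result: RegionSentimentResult,
    geometry: dict,
    region_property: str = "region",
) -> dict:
    """Join regional sentiment onto a GeoJSON FeatureCollection.

    Features are matched on ``properties[region_property]``; matched
    features gain n_posts / mean_polarity / sentiment_class properties,
    unmatched ones are left untouched.
    """
    if geometry.get("type") != "FeatureCollection":
        raise UsageError("geometry must be a GeoJSON FeatureCollection")
    by_region = {row["region"]: row for _, row in result.table.iterrows()}
    out = {"type": "FeatureCollection", "features": []}
    for feat in geometry.get("features", []):
        feat = json.loads(json.dumps(feat))  # deep copy
        key = feat.get("properties", {}).get(region_property)
        if key in by_region:
            row = by_region[key]
            feat.setdefault("properties", {}).update(
                {
                    "n_posts": int(row["n"]),
                    "mean_polarity": float(row["mean_polarity"]),
                    "sentiment_class": int(row["class"]),
                }
            )
        out["features"].append(feat)
    return out
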