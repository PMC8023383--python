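"""Labeled synthetic post corpora with planted statistical structure.

Real vaccine-discourse posts cannot be redistributed, so every downstream
stage is exercised on generated corpora that plant the structure the
analysis is meant to recover:

* weekly class-probability curves, piecewise-linear in ISO-week index
  (positive share rising over the window with a mid-October negative
  bump, the shape such surveillance studies report);
* a platform negativity multiplier (one platform's negative share roughly
  twice the other's after renormalization);
* additive region-level offsets on the (negative, positive) probabilities;
* probabilistic inclusion of one stage-1 COVID term and one stage-2
  vaccine term, so the thematic filter has known ground truth.

Text is a bag of class-conditional valenced tokens joined by spaces, plus
optional URL and hashtag tokens — just enough surface structure to
exercise preprocessing and filtering, with no linguistic realism.
Generation is fully reproducible from the config seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .corpus import PLATFORMS, PostRecord, UsageError, default_filter_spec, week_start_of
from .ensemble import Sentiment


class ConfigError(UsageError):
    """Invalid corpus configuration, raised before any generation."""


@dataclass(frozen=True)
class TruthLabel:
    """Ground-truth sentiment for one generated post (stands in for a
    manual annotation)."""

    post_id: str
    label: Sentiment


# class order everywhere: (negative, neutral, positive)
_DEFAULT_TREND = {
    0: (0.20, 0.33, 0.47),
    12: (0.17, 0.31, 0.52),
    28: (0.15, 0.29, 0.56),
    33: (0.24, 0.26, 0.50),  # mid-October negative bump
    35: (0.17, 0.27, 0.56),
    38: (0.14, 0.24, 0.62),
}

_DEFAULT_REGIONS = {
    "Cornwall": ("GB", +0.06),
    "Kent": ("GB", +0.04),
    "London": ("GB", 0.0),
    "West Sussex": ("GB", -0.05),
    "Somerset": ("GB", -0.04),
    "California": ("US", +0.03),
    "New York": ("US", +0.02),
    "Ohio": ("US", 0.0),
    "Texas": ("US", -0.03),
    "Florida": ("US", -0.04),
}

_DEFAULT_POOLS = {
    -1: (
        ("fear", -0.6), ("scared", -0.7), ("unsafe", -0.6), ("dangerous", -0.7),
        ("hoax", -0.8), ("conspiracy", -0.8), ("worried", -0.5), ("risky", -0.5),
        ("misinformation", -0.6), ("distrust", -0.7), ("harm", -0.6), ("rushed", -0.5),
        ("delay", -0.3), ("refuse", -0.5),
    ),
    0: (
        ("news", 0.0), ("report", 0.0), ("update", 0.0), ("week", 0.0),
        ("today", 0.0), ("study", 0.0), ("data", 0.0), ("government", 0.0),
        ("people", 0.0), ("doses", 0.0), ("trial", 0.0), ("results", 0.0),
    ),
    1: (
        ("good", 0.7), ("great", 0.8), ("amazing", 0.9), ("hope", 0.6),
        ("hopeful", 0.7), ("effective", 0.6), ("safe", 0.5), ("breakthrough", 0.8),
        ("success", 0.7), ("successful", 0.7), ("relief", 0.6), ("optimistic", 0.7),
        ("progress", 0.5), ("protection", 0.4),
    ),
}

_HASHTAGS = ("#covidvaccine", "#health", "#science", "#2020")


@dataclass(frozen=True)
class CorpusConfig:
    """Generator settings; defaults emulate a two-platform GB/US corpus
    over 2020-03-01..2020-11-22."""

    n_posts: int = 1000
    start: date = date(2020, 3, 1)
    end: date = date(2020, 11, 22)
    platform_mix: Mapping[str, float] = field(
        default_factory=lambda: {"twitter": 0.5, "facebook": 0.5}
    )
    country_mix: Mapping[str, float] = field(
        default_factory=lambda: {"GB": 0.5, "US": 0.5}
    )
    trend_knots: Mapping[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TREND)
    )
    negativity_platform: str = "twitter"
    platform_negativity_multiplier: float = 2.0
    region_table: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: dict(_DEFAULT_REGIONS)
    )
    keyword_inclusion_prob: float = 0.9
    token_pools: Mapping[int, Sequence[tuple[str, float]]] = field(
        default_factory=lambda: dict(_DEFAULT_POOLS)
    )
    tokens_per_post: tuple[int, int] = (5, 12)
    url_prob: float = 0.2
    hashtag_prob: float = 0.25
    stage1_keywords: tuple[str, ...] = ()
    stage2_keywords: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stage1_keywords or not self.stage2_keywords:
            spec = default_filter_spec()
            object.__setattr__(
                self, "stage1_keywords", self.stage1_keywords or spec.stage1_terms
            )
            object.__setattr__(
                self, "stage2_keywords", self.stage2_keywords or spec.stage2_terms
            )

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if self.n_posts < 0:
            raise ConfigError("n_posts must be >= 0")
        if self.end < self.start:
            raise ConfigError("end date before start date")
        if (self.end - self.start).days > 366:
            raise ConfigError("date range must span at most one calendar year")
        for name, mix in (("platform_mix", self.platform_mix), ("country_mix", self.country_mix)):
            if not mix or abs(sum(mix.values()) - 1.0) > 1e-9 or min(mix.values()) < 0:
                raise ConfigError(f"{name} must be non-negative and sum to 1")
        for p in self.platform_mix:
            if p not in PLATFORMS:
                raise ConfigError(f"unknown platform {p!r} in platform_mix")
        if not self.trend_knots:
            raise ConfigError("trend_knots must be non-empty")
        for wk, vec in self.trend_knots.items():
            v = np.asarray(vec, dtype=float)
            if v.shape != (3,) or (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
                raise ConfigError(
                    f"trend knot at week {wk} must be a non-negative 3-vector summing to 1"
                )
        if self.platform_negativity_multiplier <= 0:
            raise ConfigError("platform_negativity_multiplier must be positive")
        if not 0.0 <= self.keyword_inclusion_prob <= 1.0:
            raise ConfigError("keyword_inclusion_prob must be in [0, 1]")
        for cls in (-1, 0, 1):
            pool = self.token_pools.get(cls)
            if not pool:
                raise ConfigError(f"token pool for class {cls} is empty")
            for tok, val in pool:
                if not -1.0 <= float(val) <= 1.0:
                    raise ConfigError(f"token valence out of [-1,1]: {tok!r}={val}")
        lo, hi = self.tokens_per_post
        if lo < 1 or hi < lo:
            raise ConfigError("tokens_per_post must be a valid (low, high) range")
        for region, (country, offset) in self.region_table.items():
            if abs(float(offset)) > 0.5:
                raise ConfigError(f"region offset for {region!r} too large: {offset}")

    # -- derived quantities ----------------------------------------------

    @property
    def n_weeks(self) -> int:
        """Number of ISO weeks (Monday start) touched by the date range."""
        return (week_start_of(self.end) - week_start_of(self.start)).days // 7 + 1

    def week_index(self, d: date) -> int:
        return (week_start_of(d) - week_start_of(self.start)).days // 7


def planted_trend(cfg: CorpusConfig, week_index: int) -> np.ndarray:
    """Class-probability vector (neg, neu, pos) at an ISO-week index.

    Piecewise-linear interpolation between the configured knots; constant
    extrapolation outside the outermost knots.
    """
    if not 0 <= week_index < cfg.n_weeks:
        raise IndexError(
            f"week_index {week_index} outside range [0, {cfg.n_weeks})"
        )
    knots = sorted(cfg.trend_knots.items())
    xs = np.array([k for k, _ in knots], dtype=float)
    ys = np.array([v for _, v in knots], dtype=float)
    vec = np.array(
        [np.interp(week_index, xs, ys[:, i]) for i in range(3)], dtype=float
    )
    return vec / vec.sum()  # simplex-preserving up to roundoff


def adjusted_probs(
    cfg: CorpusConfig,
    week_index: int,
    platform: str,
    region: str | None = None,
) -> np.ndarray:
    """Weekly probabilities after platform-negativity and region offsets.

    The multiplier scales the configured platform's negative probability
    (then renormalizes); a region offset delta moves probability mass from
    negative to positive (pos += delta, neg -= delta, clipped to [0, 1])
    before a final renormalization.
    """
    vec = planted_trend(cfg, week_index).copy()
    if platform == cfg.negativity_platform:
        vec[0] *= cfg.platform_negativity_multiplier
        vec /= vec.sum()
    if region is not None and region in cfg.region_table:
        delta = float(cfg.region_table[region][1])
        vec[2] = np.clip(vec[2] + delta, 0.0, 1.0)
        vec[0] = np.clip(vec[0] - delta, 0.0, 1.0)
        vec /= vec.sum()
    return vec


def render_text(label: int, cfg: CorpusConfig, rng: np.random.Generator) -> str:
    """One post's text: class-conditional tokens, optional keywords/URL/hashtag."""
    pool = cfg.token_pools[int(label)]
    if not pool:
        raise ConfigError(f"token pool for class {label} is empty")
    lo, hi = cfg.tokens_per_post
    k = int(rng.integers(lo, hi + 1))
    words = [pool[int(i)][0] for i in rng.integers(len(pool), size=k)]
    if rng.random() < cfg.keyword_inclusion_prob:
        kw1 = cfg.stage1_keywords[int(rng.integers(len(cfg.stage1_keywords)))]
        kw2 = cfg.stage2_keywords[int(rng.integers(len(cfg.stage2_keywords)))]
        for kw in (kw1, kw2):
            words.insert(int(rng.integers(len(words) + 1)), kw)
    if rng.random() < cfg.url_prob:
        suffix = "".join(chr(97 + int(c)) for c in rng.integers(26, size=6))
        words.append(f"https://t.co/{suffix}")
    if rng.random() < cfg.hashtag_prob:
        words.append(_HASHTAGS[int(rng.integers(len(_HASHTAGS)))])
    return " ".join(words)


def _draw_categorical(rng: np.random.Generator, items: Sequence, probs: Sequence[float]):
    u = rng.random()
    acc = 0.0
    for item, p in zip(items, probs):
        acc += p
        if u < acc:
            return item
    return items[-1]


def generate_corpus(cfg: CorpusConfig) -> tuple[list[PostRecord], list[TruthLabel]]:
    """Generate ``cfg.n_posts`` posts with paired ground-truth labels.

    Timestamps are uniform over the date range (no weekday/diurnal
    structure); the truth label is drawn from the week-, platform- and
    region-adjusted class probabilities. Byte-identical output for
    identical configs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    start_dt = datetime.combine(cfg.start, datetime.min.time(), tzinfo=timezone.utc)
    total_seconds = ((cfg.end - cfg.start).days + 1) * 86400

    platforms = sorted(cfg.platform_mix)
    platform_p = [cfg.platform_mix[p] for p in platforms]
    countries = sorted(cfg.country_mix)
    country_p = [cfg.country_mix[c] for c in countries]
    regions_by_country: dict[str, list[str]] = {}
    for region, (country, _) in sorted(cfg.region_table.items()):
        regions_by_country.setdefault(country, []).append(region)

    records: list[PostRecord] = []
    labels: list[TruthLabel] = []
    for i in range(cfg.n_posts):
        ts = start_dt + timedelta(seconds=int(rng.integers(total_seconds)))
        platform = _draw_categorical(rng, platforms, platform_p)
        country = _draw_categorical(rng, countries, country_p)
        crs = regions_by_country.get(country)
        region = crs[int(rng.integers(len(crs)))] if crs else None
        week = cfg.week_index(ts.date())
        probs = adjusted_probs(cfg, week, platform, region)
        label = int(_draw_categorical(rng, (-1, 0, 1), probs))
        text = render_text(label, cfg, rng)
        post_id = f"p{i:06d}"
        records.append(
            PostRecord(
                id=post_id, platform=platform, timestamp=ts,
                country=country, region=region, text=text,
            )
        )
        labels.append(TruthLabel(post_id=post_id, label=Sentiment(label)))
    return records, labels


# ---------------------------------------------------------------------------
# persistence


def write_truth_csv(labels: Sequence[TruthLabel], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["post_id", "label"])
        for t in labels:
            writer.writerow([t.post_id, int(t.label)])


def read_truth_csv(path: str | Path) -> dict[str, Sentiment]:
    out: dict[str, Sentiment] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["post_id"]] = Sentiment(int(row["label"]))
    return out


def corpus_config_from_yaml(path: str | Path) -> CorpusConfig:
    """Build a config from a YAML mapping; omitted keys keep defaults."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return corpus_config_from_dict(raw)


def corpus_config_from_dict(raw: Mapping) -> CorpusConfig:
    kwargs: dict = {}
    simple = (
        "n_posts", "platform_mix", "country_mix", "negativity_platform",
        "platform_negativity_multiplier", "keyword_inclusion_prob",
        "url_prob", "hashtag_prob", "seed",
    )
    for key in simple:
        if key in raw:
            kwargs[key] = raw[key]
    for key in ("start", "end"):
        if key in raw:
            v = raw[key]
            kwargs[key] = v if isinstance(v, date) else date.fromisoformat(str(v))
    if "trend_knots" in raw:
        kwargs["trend_knots"] = {
            int(k): tuple(float(x) for x in v) for k, v in raw["trend_knots"].items()
        }
    if "region_table" in raw:
        kwargs["region_table"] = {
            str(r): (str(c), float(o)) for r, (c, o) in raw["region_table"].items()
        }
    if "token_pools" in raw:
        kwargs["token_pools"] = {
            int(cls): tuple((str(t), float(v)) for t, v in pool)
            for cls, pool in raw["token_pools"].items()
        }
    if "tokens_per_post" in raw:
        kwargs["tokens_per_post"] = tuple(int(x) for x in raw["tokens_per_post"])
    for key in ("stage1_keywords", "stage2_keywords"):
        if key in raw:
            kwargs[key] = tuple(str(t) for t in raw[key])
    cfg = CorpusConfig(**kwargs)
    cfg.validate()
    return cfg
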