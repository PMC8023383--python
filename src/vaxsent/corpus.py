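"""Post records: reading, writing, and thematic/geographic filtering.

A corpus is a list of :class:`PostRecord`. On disk it is either a CSV
(header row, UTF-8, RFC-4180 quoting) or JSON-Lines (one object per line)
with fields ``id, platform, timestamp, country, region, text``. Keyword
lists are plain text, one term per line, ``#`` comments allowed.

Thematic filtering is the two-stage AND used in vaccine-discourse
surveillance: a post is kept only if it matches at least one COVID-related
(stage 1) term and at least one vaccine-related (stage 2) term.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

PLATFORMS = ("twitter", "facebook")

# country may legitimately be absent (no-location posts are tallied by
# filter_geo rather than dropped at read time)
_REQUIRED_FIELDS = ("id", "platform", "timestamp", "text")


class UsageError(ValueError):
    """Invalid argument or configuration supplied by the caller."""


def week_start_of(d: date | datetime) -> date:
    """Monday of the ISO week containing ``d``."""
    if isinstance(d, datetime):
        d = d.date()
    return d - timedelta(days=d.weekday())


@dataclass(frozen=True)
class PostRecord:
    """One social-media post.

    ``timestamp`` is timezone-resolved to UTC; ``country`` is an ISO-3166
    alpha-2 code; ``region`` is a free-text sub-national id (state or
    county) and may be None; ``text`` may be empty but not None.
    """

    id: str
    platform: str
    timestamp: datetime
    country: str | None
    text: str
    region: str | None = None

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise UsageError(f"unknown platform {self.platform!r}")
        if self.text is None:
            raise UsageError("text must not be None")
        if self.timestamp.tzinfo is None:
            object.__setattr__(
                self, "timestamp", self.timestamp.replace(tzinfo=timezone.utc)
            )
        else:
            object.__setattr__(
                self, "timestamp", self.timestamp.astimezone(timezone.utc)
            )


@dataclass
class ReadResult:
    records: list[PostRecord]
    n_skipped: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


@dataclass
class GeoFilterResult:
    records: list[PostRecord]
    n_no_location: int = 0
    n_dropped: int = 0


@dataclass(frozen=True)
class KeywordFilterSpec:
    """Two-stage keyword filter: stage-1 COVID terms AND stage-2 vaccine terms."""

    stage1_terms: tuple[str, ...]
    stage2_terms: tuple[str, ...]
    match_mode: str = "word_boundary"  # or "substring"
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        for name, terms in (("stage1", self.stage1_terms), ("stage2", self.stage2_terms)):
            if not terms or any(not t for t in terms):
                raise UsageError(f"{name}_terms must be a non-empty list of non-empty strings")
        if self.match_mode not in ("word_boundary", "substring"):
            raise UsageError(f"unknown match_mode {self.match_mode!r}")


def _parse_timestamp(value) -> datetime:
    ts = pd.Timestamp(value)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.tz_convert("UTC").to_pydatetime()


def _record_from_mapping(row: dict) -> PostRecord:
    missing = [f for f in _REQUIRED_FIELDS if row.get(f) in (None, "")]
    # empty text is legal; None is not
    if "text" in missing and row.get("text") == "":
        missing.remove("text")
    if missing:
        raise ValueError(f"missing required fields: {missing}")
    region = row.get("region")
    if region in ("", None):
        region = None
    country = row.get("country")
    if country in ("", None):
        country = None
    return PostRecord(
        id=str(row["id"]),
        platform=str(row["platform"]),
        timestamp=_parse_timestamp(row["timestamp"]),
        country=country,
        region=region,
        text=str(row["text"]),
    )


def read_posts(path: str | Path, format: str | None = None) -> ReadResult:
    """Read a corpus from CSV or JSON-Lines.

    Rows missing required fields (or unparseable lines) are skipped and
    counted; the skip count is logged and returned on the result.
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix in (".jsonl", ".ndjson", ".json") else "csv"
    if format not in ("csv", "jsonl"):
        raise UsageError(f"unknown corpus format {format!r}")

    records: list[PostRecord] = []
    skipped = 0
    with open(path, encoding="utf-8", newline="") as fh:
        if format == "csv":
            rows: Iterable[dict] = csv.DictReader(fh)
        else:
            rows = _iter_jsonl(fh)
        for row in rows:
            if row is None:
                skipped += 1
                continue
            try:
                records.append(_record_from_mapping(row))
            except (ValueError, UsageError) as exc:
                skipped += 1
                logger.debug("skipping row: %s", exc)
    if skipped:
        logger.warning("read_posts: skipped %d malformed row(s) in %s", skipped, path)
    return ReadResult(records, skipped)


def _iter_jsonl(fh):
    for line in fh:
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError:
            yield None
            continue
        yield obj if isinstance(obj, dict) else None


def write_posts(records: Sequence[PostRecord], path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix in (".jsonl", ".ndjson", ".json") else "csv"
    if format not in ("csv", "jsonl"):
        raise UsageError(f"unknown corpus format {format!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if format == "csv":
            writer = csv.DictWriter(
                fh, fieldnames=["id", "platform", "timestamp", "country", "region", "text"]
            )
            writer.writeheader()
            for r in records:
                writer.writerow(_record_to_mapping(r))
        else:
            for r in records:
                fh.write(json.dumps(_record_to_mapping(r), ensure_ascii=False) + "\n")


def _record_to_mapping(r: PostRecord) -> dict:
    return {
        "id": r.id,
        "platform": r.platform,
        "timestamp": r.timestamp.isoformat().replace("+00:00", "Z"),
        "country": r.country if r.country is not None else "",
        "region": r.region if r.region is not None else "",
        "text": r.text,
    }


def posts_to_frame(records: Sequence[PostRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of a corpus (one row per post)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "platform": [r.platform for r in records],
            "timestamp": pd.to_datetime([r.timestamp for r in records], utc=True),
            "country": [r.country for r in records],
            "region": [r.region for r in records],
            "text": [r.text for r in records],
        }
    )


def load_keywords(path: str | Path) -> list[str]:
    """One term per line; blank lines and '#' comments ignored."""
    terms = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            terms.append(line)
    return terms


def _bundled(name: str) -> Path:
    return resources.files("vaxsent.data") / name


def default_filter_spec() -> KeywordFilterSpec:
    """Bundled COVID (stage 1) and vaccine (stage 2) term lists."""
    return KeywordFilterSpec(
        stage1_terms=tuple(load_keywords(_bundled("covid_terms.txt"))),
        stage2_terms=tuple(load_keywords(_bundled("vaccine_terms.txt"))),
    )


def _compile_terms(terms: Sequence[str], match_mode: str, case_sensitive: bool) -> re.Pattern:
    flags = 0 if case_sensitive else re.IGNORECASE
    if match_mode == "word_boundary":
        # (?<!\w)/(?!\w) rather than \b so hyphenated terms like "covid-19"
        # anchor on their alphanumeric ends.
        parts = [rf"(?<!\w){re.escape(t)}(?!\w)" for t in terms]
    else:
        parts = [re.escape(t) for t in terms]
    return re.compile("|".join(parts), flags)


def thematic_match(text: str, spec: KeywordFilterSpec) -> bool:
    """True iff text matches >=1 stage-1 term AND >=1 stage-2 term."""
    p1 = _compile_terms(spec.stage1_terms, spec.match_mode, spec.case_sensitive)
    p2 = _compile_terms(spec.stage2_terms, spec.match_mode, spec.case_sensitive)
    return bool(p1.search(text)) and bool(p2.search(text))


def filter_thematic(records: Sequence[PostRecord], spec: KeywordFilterSpec) -> list[PostRecord]:
    """Keep posts passing the two-stage AND keyword filter; order preserved."""
    p1 = _compile_terms(spec.stage1_terms, spec.match_mode, spec.case_sensitive)
    p2 = _compile_terms(spec.stage2_terms, spec.match_mode, spec.case_sensitive)
    return [r for r in records if p1.search(r.text) and p2.search(r.text)]


def filter_geo(records: Sequence[PostRecord], countries: Iterable[str]) -> GeoFilterResult:
    """Keep posts whose country is in ``countries``; order preserved.

    Posts with no country are dropped and counted separately in
    ``n_no_location``.
    """
    countries = set(countries)
    if not countries:
        raise UsageError("countries must be non-empty")
    kept: list[PostRecord] = []
    no_loc = dropped = 0
    for r in records:
        if not r.country:
            no_loc += 1
        elif r.country in countries:
            kept.append(r)
        else:
            dropped += 1
    return GeoFilterResult(kept, n_no_location=no_loc, n_dropped=dropped)


def dedupe_exact(records: Sequence[PostRecord]) -> list[PostRecord]:
    """Optionally drop exact-text duplicates, keeping first occurrence."""
    seen: set[str] = set()
    out = []
    for r in records:
        if r.text not in seen:
            seen.add(r.text)
            out.append(r)
    return out
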