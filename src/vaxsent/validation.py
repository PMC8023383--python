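"""Annotation sampling and accuracy assessment.

Mirrors the manual-validation step of sentiment surveillance studies: a
random 10% sample of classified posts is exported for human annotation,
re-imported, and compared with model output through a 3x3 confusion matrix
(rows = true class, columns = predicted class, both ordered negative,
neutral, positive) with per-class one-vs-rest sensitivity/specificity.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import PostRecord, UsageError
from .ensemble import LABELS, Sentiment

_CLASS_NAMES = {-1: "negative", 0: "neutral", 1: "positive"}
_INDEX = {-1: 0, 0: 1, 1: 2}


def sample_for_annotation(
    records: Sequence[PostRecord],
    fraction: float = 0.10,
    seed: int = 0,
    *,
    stratify_by_platform: bool = False,
) -> list[PostRecord]:
    """Simple random sample without replacement of size floor(fraction*n).

    Reproducible from ``seed``. With ``stratify_by_platform`` the floor is
    applied within each platform stratum (pooled sampling is the default).
    """
    if not 0 < fraction <= 1:
        raise UsageError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    if stratify_by_platform:
        out: list[PostRecord] = []
        for platform in sorted({r.platform for r in records}):
            stratum = [r for r in records if r.platform == platform]
            k = math.floor(fraction * len(stratum))
            idx = rng.permutation(len(stratum))[:k]
            out.extend(stratum[i] for i in idx)
        return out
    k = math.floor(fraction * len(records))
    idx = rng.permutation(len(records))[:k]
    return [records[i] for i in idx]


@dataclass
class ConfusionMatrix:
    """3x3 counts, rows true class, columns predicted; order (neg, neu, pos)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (3, 3) or (counts < 0).any():
            raise UsageError("counts must be a 3x3 non-negative integer matrix")
        self.counts = counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def zero_rows(self) -> list[int]:
        """Label values (-1/0/+1) of true classes with no items."""
        sums = self.counts.sum(axis=1)
        return [int(l) for l, s in zip(LABELS, sums) if s == 0]

    @property
    def normalized(self) -> np.ndarray:
        """Row-normalized view; rows with zero count stay all-zero."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / np.maximum(sums, 1), 0.0)
        return out

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        names = [_CLASS_NAMES[int(l)] for l in LABELS]
        data = self.normalized if normalized else self.counts
        return pd.DataFrame(data, index=pd.Index(names, name="true"), columns=names)


def confusion_matrix(truth: Sequence[int], pred: Sequence[int]) -> ConfusionMatrix:
    """Tally true-vs-predicted label pairs."""
    if len(truth) != len(pred):
        raise UsageError(f"length mismatch: {len(truth)} truth vs {len(pred)} predictions")
    counts = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(truth, pred):
        counts[_INDEX[int(t)], _INDEX[int(p)]] += 1
    return ConfusionMatrix(counts)


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest sensitivity/specificity per class plus overall accuracy.

    Undefined ratios (zero denominators) are NaN, not 0.
    """

    sensitivity: dict[int, float]
    specificity: dict[int, float]
    accuracy: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in (-1, 0, 1):
            rows.append(
                {
                    "class": _CLASS_NAMES[label],
                    "sensitivity": self.sensitivity[label],
                    "specificity": self.specificity[label],
                }
            )
        return pd.DataFrame(rows)


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Per-class sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)."""
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise UsageError("cannot compute metrics of an all-zero confusion matrix")
    sens: dict[int, float] = {}
    spec: dict[int, float] = {}
    for label, i in _INDEX.items():
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens[label] = float(tp / (tp + fn)) if tp + fn > 0 else float("nan")
        spec[label] = float(tn / (tn + fp)) if tn + fp > 0 else float("nan")
    return ClassMetrics(sens, spec, float(np.trace(counts) / total))


# ---------------------------------------------------------------------------
# annotation round trip


def export_annotation_sheet(sample: Sequence[PostRecord], path: str | Path) -> None:
    """Write the sample as CSV with an empty ``annotation`` column to fill
    with -1/0/1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "platform", "timestamp", "country", "region", "text", "annotation"])
        for r in sample:
            writer.writerow(
                [r.id, r.platform, r.timestamp.isoformat(), r.country or "",
                 r.region or "", r.text, ""]
            )


def import_annotations(path: str | Path) -> dict[str, Sentiment]:
    """Read back a filled annotation sheet; blank annotations are skipped."""
    out: dict[str, Sentiment] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            raw = (row.get("annotation") or "").strip()
            if raw == "":
                continue
            value = int(raw)
            if value not in (-1, 0, 1):
                raise UsageError(f"annotation for {row['id']!r} must be -1, 0 or 1, got {raw}")
            out[row["id"]] = Sentiment(value)
    return out


def metrics_report(cm: ConfusionMatrix) -> str:
    """Human-readable validation summary."""
    m = class_metrics(cm)
    lines = ["Validation report", "=" * 17, "", "Confusion matrix (rows = true):",
             cm.to_frame().to_string(), "", "Row-normalized:",
             cm.to_frame(normalized=True).round(3).to_string(), "",
             m.to_frame().round(3).to_string(index=False),
             "", f"Overall accuracy: {m.accuracy:.3f} (n = {cm.total})"]
    if cm.zero_rows:
        names = ", ".join(_CLASS_NAMES[l] for l in cm.zero_rows)
        lines.append(f"Warning: no annotated items in class(es): {names}")
    return "\n".join(lines)
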