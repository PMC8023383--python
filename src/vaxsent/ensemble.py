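"""Hierarchical hybrid sentiment ensemble.

Two lexicon scorers produce continuous polarities in [-1, 1]; a weighted
average (default 0.45/0.55) is thresholded into a ternary label with a
symmetric neutral band; the lexicon label is then fused with a classifier
backend's label through an explicit 9-entry rule table. The default rule
reflects the empirical division of labor reported for this class of model:
lexicon methods are more reliable on positive posts, the trained
classifier on neutral and negative ones — so the lexicon label wins when
it is positive and the classifier wins otherwise.

Backends are contracts, not implementations:

* a lexicon backend is any callable mapping text input to a float in
  [-1, 1] (the bundled :class:`LexiconScorer` averages per-token valences
  from a CSV valence table);
* a classifier backend is any callable mapping text to a
  :class:`ClassifierOutput` (tests and the default pipeline use the
  deterministic keyword-triggered :class:`KeywordClassifier`; adapters to
  VADER, TextBlob, and pretrained transformers import those packages
  lazily and are never required).
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .corpus import PostRecord, UsageError
from .preprocess import CleanText

logger = logging.getLogger(__name__)


class Sentiment(enum.IntEnum):
    """Ternary sentiment label; values match the -1/0/+1 map scale."""

    NEGATIVE = -1
    NEUTRAL = 0
    POSITIVE = 1


LABELS = (Sentiment.NEGATIVE, Sentiment.NEUTRAL, Sentiment.POSITIVE)


class BackendError(RuntimeError):
    """A sentiment backend violated its contract or failed on a post."""


@dataclass(frozen=True)
class ClassifierOutput:
    label: Sentiment
    probabilities: tuple[float, float, float] | None = None  # (neg, neu, pos)

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", Sentiment(self.label))
        p = self.probabilities
        if p is not None:
            p = tuple(float(x) for x in p)
            if len(p) != 3 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-6:
                raise BackendError(f"invalid probability vector {p}")
            if LABELS[int(np.argmax(p))] != self.label:
                raise BackendError("probability argmax inconsistent with label")
            object.__setattr__(self, "probabilities", p)


def default_rule_table() -> dict[tuple[Sentiment, Sentiment], Sentiment]:
    """Lexicon label wins iff positive; classifier wins otherwise."""
    table = {}
    for lex in LABELS:
        for clf in LABELS:
            table[(lex, clf)] = lex if lex == Sentiment.POSITIVE else clf
    return table


def _validate_rule_table(table: Mapping) -> dict[tuple[Sentiment, Sentiment], Sentiment]:
    out = {}
    for lex in LABELS:
        for clf in LABELS:
            key = (lex, clf)
            if key not in table and (int(lex), int(clf)) not in table:
                raise UsageError(f"rule table missing entry for {key}")
            out[key] = Sentiment(table.get(key, table.get((int(lex), int(clf)))))
    return out


@dataclass(frozen=True)
class EnsembleConfig:
    """Weights, neutral band, and fusion rules of the hybrid ensemble."""

    lexicon_weights: tuple[float, float] = (0.45, 0.55)
    neutral_band: float = 0.05
    rule_table: Mapping = field(default_factory=default_rule_table)

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.lexicon_weights)
        if len(w) != 2 or any(x < 0 for x in w):
            raise UsageError("lexicon_weights must be two non-negative reals")
        if abs(sum(w) - 1.0) > 1e-9:
            raise UsageError(f"lexicon_weights must sum to 1, got {sum(w)}")
        if self.neutral_band < 0:
            raise UsageError("neutral_band must be >= 0")
        object.__setattr__(self, "lexicon_weights", w)
        object.__setattr__(self, "rule_table", _validate_rule_table(self.rule_table))


class LexiconScorer:
    """Bundled valence-table scorer: mean valence of in-lexicon tokens.

    Returns 0.0 when no token is in the lexicon. Operates on cleaned
    tokens (``wants_raw_text`` is False); adapters to scorers that use
    capitalization/punctuation cues may set it True to receive raw text.
    """

    wants_raw_text = False

    def __init__(self, valences: Mapping[str, float], name: str = "lexicon"):
        for tok, v in valences.items():
            if not -1.0 <= float(v) <= 1.0:
                raise UsageError(f"valence out of [-1,1] for {tok!r}: {v}")
        self.valences = {str(t): float(v) for t, v in valences.items()}
        self.name = name

    def __call__(self, tokens: Sequence[str]) -> float:
        vals = [self.valences[t] for t in tokens if t in self.valences]
        return float(np.mean(vals)) if vals else 0.0


def load_lexicon(path: str | Path) -> dict[str, float]:
    """CSV valence table with header ``token,valence``."""
    out: dict[str, float] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["token"]] = float(row["valence"])
    return out


def bundled_scorers() -> tuple[LexiconScorer, LexiconScorer]:
    data = resources.files("vaxsent.data")
    return (
        LexiconScorer(load_lexicon(data / "lexicon_a.csv"), name="lexicon_a"),
        LexiconScorer(load_lexicon(data / "lexicon_b.csv"), name="lexicon_b"),
    )


def lexicon_polarity(backend, record: PostRecord, cleaned: CleanText) -> float:
    """Score one post with a lexicon backend, enforcing the [-1,1] contract."""
    if getattr(backend, "wants_raw_text", False):
        value = backend(record.text)
    else:
        value = backend(cleaned.tokens)
    value = float(value)
    if not -1.0 <= value <= 1.0:
        raise BackendError(f"lexicon backend returned out-of-range polarity {value}")
    return value


def combine_lexicons(a: float, b: float, weights: tuple[float, float] = (0.45, 0.55)) -> float:
    """Convex combination w_A*a + w_B*b of two polarity scores."""
    if abs(weights[0] + weights[1] - 1.0) > 1e-9 or min(weights) < 0:
        raise UsageError(f"weights must be non-negative and sum to 1, got {weights}")
    return weights[0] * a + weights[1] * b


def polarity_to_label(score: float, neutral_band: float = 0.05) -> Sentiment:
    """Ternarize a continuous polarity; |score| <= band is neutral."""
    if neutral_band < 0:
        raise UsageError("neutral_band must be >= 0")
    if score > neutral_band:
        return Sentiment.POSITIVE
    if score < -neutral_band:
        return Sentiment.NEGATIVE
    return Sentiment.NEUTRAL


def merge_rule(lex: Sentiment, clf: Sentiment, table: Mapping | None = None) -> Sentiment:
    """Fuse the lexicon and classifier labels through the rule table."""
    if table is None:
        table = default_rule_table()
    key = (Sentiment(lex), Sentiment(clf))
    if key not in table:
        raise UsageError(f"rule table missing entry for {key}")
    return Sentiment(table[key])


@dataclass(frozen=True)
class Backends:
    """The three registered backends of the ensemble."""

    lexicon_a: Callable
    lexicon_b: Callable
    classifier: Callable[[str], ClassifierOutput]


def default_backends(classifier: Callable[[str], ClassifierOutput] | None = None) -> Backends:
    a, b = bundled_scorers()
    return Backends(a, b, classifier if classifier is not None else KeywordClassifier())


@dataclass(frozen=True)
class PostClassification:
    """Final label plus all intermediates, for audit output."""

    post_id: str
    lex_a: float | None
    lex_b: float | None
    combined: float | None
    lex_label: Sentiment | None
    clf_label: Sentiment | None
    final: Sentiment | None
    error: str | None = None


def classify_post(
    record: PostRecord,
    cleaned: CleanText,
    backends: Backends,
    cfg: EnsembleConfig | None = None,
) -> PostClassification:
    """Run the full hierarchy on one post.

    Backend failures do not raise; the post is returned with
    ``final=None`` and an error message so corpus-level runs continue.
    """
    if cfg is None:
        cfg = EnsembleConfig()
    try:
        a = lexicon_polarity(backends.lexicon_a, record, cleaned)
        b = lexicon_polarity(backends.lexicon_b, record, cleaned)
        combined = combine_lexicons(a, b, cfg.lexicon_weights)
        lex_label = polarity_to_label(combined, cfg.neutral_band)
        clf_out = backends.classifier(record.text)
        if not isinstance(clf_out, ClassifierOutput):
            clf_out = ClassifierOutput(Sentiment(clf_out))
        final = merge_rule(lex_label, clf_out.label, cfg.rule_table)
    except Exception as exc:  # contract violations and backend crashes alike
        logger.warning("backend failure on post %s: %s", record.id, exc)
        return PostClassification(record.id, None, None, None, None, None, None, error=str(exc))
    return PostClassification(record.id, a, b, combined, lex_label, clf_out.label, final)


def classify_corpus(
    records: Sequence[PostRecord],
    cleaned: Sequence[CleanText],
    backends: Backends,
    cfg: EnsembleConfig | None = None,
):
    """Classify every post; returns (audit DataFrame, n_errors).

    The audit frame has one row per post: id, lex_a, lex_b, combined,
    lex_label, clf_label, final (final is NaN on backend failure).
    """
    import pandas as pd

    rows = [classify_post(r, c, backends, cfg) for r, c in zip(records, cleaned, strict=True)]
    frame = pd.DataFrame(
        {
            "id": [r.post_id for r in rows],
            "lex_a": [r.lex_a for r in rows],
            "lex_b": [r.lex_b for r in rows],
            "combined": [r.combined for r in rows],
            "lex_label": [None if r.lex_label is None else int(r.lex_label) for r in rows],
            "clf_label": [None if r.clf_label is None else int(r.clf_label) for r in rows],
            "final": [None if r.final is None else int(r.final) for r in rows],
            "error": [r.error for r in rows],
        }
    )
    n_errors = int(frame["error"].notna().sum())
    if n_errors:
        logger.warning("classify_corpus: %d post(s) failed in a backend", n_errors)
    return frame, n_errors


# ---------------------------------------------------------------------------
# classifier backends


class KeywordClassifier:
    """Deterministic keyword-triggered classifier.

    Counts occurrences of configured positive/negative trigger words in
    the raw text (case-insensitive) and returns the majority sign,
    neutral on ties or no triggers. Deterministic by construction.
    """

    _POS = ("good", "great", "amazing", "hope", "hopeful", "safe", "effective",
            "breakthrough", "success", "successful", "relief", "optimistic")
    _NEG = ("bad", "fear", "scared", "unsafe", "dangerous", "hoax", "conspiracy",
            "risky", "worried", "misinformation", "distrust", "harm", "rushed")

    def __init__(self, positive: Sequence[str] | None = None, negative: Sequence[str] | None = None):
        self.positive = tuple(positive) if positive is not None else self._POS
        self.negative = tuple(negative) if negative is not None else self._NEG

    def __call__(self, text: str) -> ClassifierOutput:
        words = text.lower().split()
        pos = sum(w in self.positive for w in words)
        neg = sum(w in self.negative for w in words)
        if pos > neg:
            return ClassifierOutput(Sentiment.POSITIVE)
        if neg > pos:
            return ClassifierOutput(Sentiment.NEGATIVE)
        return ClassifierOutput(Sentiment.NEUTRAL)


class OracleClassifier:
    """Echoes a known truth label per post, optionally with planted noise.

    Used to validate the validation machinery itself: with per-class
    error rates planted, estimated sensitivities must converge to
    1 - error_rate. ``truth`` maps post text or id to a label; here we key
    by text since classifier backends receive text only.
    """

    def __init__(
        self,
        truth_by_text: Mapping[str, int],
        error_rates: Mapping[int, float] | None = None,
        seed: int = 0,
    ):
        self.truth = dict(truth_by_text)
        self.error_rates = {int(k): float(v) for k, v in (error_rates or {}).items()}
        self.rng = np.random.default_rng(seed)

    def __call__(self, text: str) -> ClassifierOutput:
        label = Sentiment(self.truth[text])
        rate = self.error_rates.get(int(label), 0.0)
        if rate and self.rng.random() < rate:
            others = [l for l in LABELS if l != label]
            label = others[self.rng.integers(len(others))]
        return ClassifierOutput(label)


# optional adapters to published scorers; never required by tests


def vader_scorer():
    """Adapter to the VADER compound score (requires vaderSentiment)."""
    from vaderSentiment.vaderSentiment import SentimentIntensityAnalyzer

    analyzer = SentimentIntensityAnalyzer()

    def score(text: str) -> float:
        return float(analyzer.polarity_scores(text)["compound"])

    score.wants_raw_text = True  # VADER uses punctuation/capitalization cues
    return score


def textblob_scorer():
    """Adapter to the TextBlob polarity score (requires textblob)."""
    from textblob import TextBlob

    def score(text: str) -> float:
        return float(TextBlob(text).sentiment.polarity)

    score.wants_raw_text = True
    return score


def transformer_classifier(model_name: str = "nlptown/bert-base-multilingual-uncased-sentiment"):
    """Adapter to a pretrained transformer pipeline (requires transformers).

    Collapses the model's star/label output onto the ternary scale. Never
    exercised in the test suite (no weight download); provided so the
    classifier slot can be filled with a real model where available.
    """
    from transformers import pipeline as hf_pipeline

    clf = hf_pipeline("sentiment-analysis", model=model_name)

    def classify(text: str) -> ClassifierOutput:
        out = clf(text[:512])[0]
        label = out["label"].lower()
        if "1" in label or "2" in label or "neg" in label:
            return ClassifierOutput(Sentiment.NEGATIVE)
        if "4" in label or "5" in label or "pos" in label:
            return ClassifierOutput(Sentiment.POSITIVE)
        return ClassifierOutput(Sentiment.NEUTRAL)

    return classify
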