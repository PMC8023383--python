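"""Text normalization for sentiment scoring and n-gram mining.

The cleaning pipeline runs in a fixed order: strip URLs, drop hashtag and
@-mention tokens, lowercase, split on whitespace/punctuation (apostrophes
kept inside words), drop stop words, drop empties. Hashtags are removed as
whole tokens by default; ``keep_hashtag_word=True`` retains the bare word
instead. Mentions are always removed — they are handles, not content.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)
# a word: alphanumeric runs, apostrophes allowed inside (don't, it's)
_TOKEN_RE = re.compile(r"[^\W_]+(?:'[^\W_]+)*")


@dataclass(frozen=True)
class CleanText:
    """Normalized token view of one post."""

    post_id: str | None
    tokens: tuple[str, ...]

    @property
    def joined(self) -> str:
        return " ".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load a stop-word list (one lowercase word per line); bundled default."""
    if path is None:
        path = resources.files("vaxsent.data") / "stopwords.txt"
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip().lower()
        if line:
            words.add(line)
    return frozenset(words)


def clean_text(
    raw: str,
    stopwords: Iterable[str] | None = None,
    *,
    post_id: str | None = None,
    keep_hashtag_word: bool = False,
) -> CleanText:
    """Normalize one post's text to lowercase content tokens.

    Empty input, or input whose tokens are all removed, yields an empty
    token list rather than an error.
    """
    stop = frozenset(stopwords) if stopwords is not None else _DEFAULT_STOPWORDS
    text = _URL_RE.sub(" ", raw)
    kept_chunks = []
    for chunk in text.split():
        if chunk.startswith("@"):
            continue
        if chunk.startswith("#"):
            if keep_hashtag_word:
                kept_chunks.append(chunk.lstrip("#"))
            continue
        kept_chunks.append(chunk)
    tokens = []
    for word in _TOKEN_RE.findall(" ".join(kept_chunks).lower()):
        word = word.strip("'")
        if word and word not in stop:
            tokens.append(word)
    return CleanText(post_id=post_id, tokens=tuple(tokens))


def clean_corpus(records: Sequence, stopwords: Iterable[str] | None = None, **kw) -> list[CleanText]:
    """Apply :func:`clean_text` to every record, carrying post ids."""
    return [clean_text(r.text, stopwords, post_id=r.id, **kw) for r in records]


_DEFAULT_STOPWORDS = load_stopwords()
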