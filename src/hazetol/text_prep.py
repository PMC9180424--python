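"""Microblog text cleaning, tokenization, and stop-word filtering.

Cleaning removes the three noise classes that dominate scraped microblogs —
URLs, @mention / #hashtag# markup, and emoji — then collapses whitespace.
Tokenization is pluggable: the default segmenter splits on whitespace and
punctuation, and a dictionary-based segmenter (e.g. for Chinese) can be
injected without changing any downstream contract.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

Tokenizer = Callable[[str], list[str]]

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
# paired #topic# (Weibo style, may contain spaces), bare #tag, stray '#'
_HASHTAG_RE = re.compile(r"#[^#\n]{0,60}#|#\S+|#")
_MENTION_RE = re.compile(r"@\S+")
# Emoji: pictographs, emoticons, transport, symbols, dingbats, variation
# selectors and joiners.  Codepoint blocks, so no lexicon is needed.
_EMOJI_RE = re.compile(
    "["
    "\U0001F300-\U0001F5FF"
    "\U0001F600-\U0001F64F"
    "\U0001F680-\U0001F6FF"
    "\U0001F700-\U0001FAFF"
    "☀-➿"
    "︎️‍"
    "]+"
)
_WS_RE = re.compile(r"\s+")


def clean_text(raw: str) -> str:
    """Strip URLs, hashtag/mention markup and emoji; collapse whitespace.

    Idempotent; the input string is never modified.
    """
    s = _URL_RE.sub(" ", raw)
    s = _HASHTAG_RE.sub(" ", s)
    s = _MENTION_RE.sub(" ", s)
    s = _EMOJI_RE.sub(" ", s)
    return _WS_RE.sub(" ", s).strip()


_TOKEN_RE = re.compile(r"[\w一-鿿]+")


def default_tokenizer(cleaned: str) -> list[str]:
    """Split on whitespace/punctuation; lowercases ASCII."""
    return [t.lower() for t in _TOKEN_RE.findall(cleaned)]


def tokenize(cleaned: str, segmenter: Tokenizer | None = None) -> list[str]:
    """Tokenize cleaned text with the given segmenter (default: regex split)."""
    segmenter = segmenter or default_tokenizer
    return list(segmenter(cleaned))


@dataclass(frozen=True)
class StopWordList:
    """A named stop-word set; one token per line on disk (UTF-8)."""

    words: frozenset[str]
    source_name: str = "inline"

    @classmethod
    def from_file(cls, path: str | Path) -> "StopWordList":
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"stop-word list not found: {p}")
        words = frozenset(
            w.strip() for w in p.read_text(encoding="utf-8").splitlines() if w.strip()
        )
        return cls(words=words, source_name=str(p))

    @classmethod
    def default(cls) -> "StopWordList":
        return cls.from_file(Path(__file__).parent / "data" / "stopwords_en.txt")


def filter_stopwords(tokens: Sequence[str], stops: StopWordList | Iterable[str]) -> list[str]:
    """Order-preserving removal of stop-word tokens."""
    words = stops.words if isinstance(stops, StopWordList) else set(stops)
    return [t for t in tokens if t not in words]
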