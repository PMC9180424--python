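"""Core record type for microblog posts and its JSON-lines serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path
from typing import Iterable, Iterator, Optional


@dataclass
class MicroblogRecord:
    """One microblog post.

    At least one of ``text`` / ``tokens`` must be present.  ``label`` is the
    hand-annotated polarity used for training ("positive"/"negative", or
    None); ``score`` is the model posterior of the positive class in [0, 1].
    """

    id: str
    region: str
    timestamp: datetime
    text: Optional[str] = None
    tokens: Optional[list[str]] = None
    label: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.text is None and self.tokens is None:
            raise ValueError(f"record {self.id!r}: need text or tokens")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"record {self.id!r}: score {self.score} outside [0, 1]")
        if self.label not in (None, "positive", "negative"):
            raise ValueError(f"record {self.id!r}: bad label {self.label!r}")

    def to_json(self) -> str:
        d = asdict(self)
        d["timestamp"] = self.timestamp.isoformat()
        return json.dumps({k: v for k, v in d.items() if v is not None},
                          ensure_ascii=False, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "MicroblogRecord":
        d = json.loads(line)
        d["timestamp"] = datetime.fromisoformat(d["timestamp"])
        return cls(**d)


def write_jsonl(records: Iterable[MicroblogRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_jsonl(path: str | Path) -> Iterator[MicroblogRecord]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield MicroblogRecord.from_json(line)


def winter_season(ts: datetime) -> Optional[int]:
    """Label a timestamp with its winter season (year of the December).

    December of year Y together with January/February of year Y+1 form the
    winter labelled Y; other months return None.
    """
    if ts.month == 12:
        return ts.year
    if ts.month <= 2:
        return ts.year - 1
    return None
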