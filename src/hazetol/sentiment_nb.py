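"""Multinomial naive-Bayes sentiment scoring with the 0.5 polarity rule.

The scorer returns the posterior probability of the positive class,

    P(pos | d) = P(pos) prod_w P(w|pos)^{n_w}  /  sum_c P(c) prod_w P(w|c)^{n_w},

computed in the log domain with additive (Laplace) smoothing,
P(w|c) = (n_{w,c} + alpha) / (N_c + alpha * V).  A post is labelled positive
only when its score strictly exceeds 0.5; a score of exactly 0.5 counts as
negative.  Tokens outside the training vocabulary fall back on the smoothed
floor alpha / (N_c + alpha * V).
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from hazetol.records import MicroblogRecord, winter_season

POSITIVE = "positive"
NEGATIVE = "negative"
CLASSES = (POSITIVE, NEGATIVE)


@dataclass
class NBModel:
    """Trained multinomial naive-Bayes model (log-domain storage)."""

    log_prior: dict[str, float]
    log_cond: dict[str, dict[str, float]]  # class -> token -> log P(token|class)
    log_unseen: dict[str, float]           # class -> log mass of an unseen token
    vocab: frozenset[str]
    alpha: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "log_prior": self.log_prior,
                "log_cond": self.log_cond,
                "log_unseen": self.log_unseen,
                "vocab": sorted(self.vocab),
                "alpha": self.alpha,
            },
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, s: str) -> "NBModel":
        d = json.loads(s)
        return cls(
            log_prior=d["log_prior"],
            log_cond=d["log_cond"],
            log_unseen=d["log_unseen"],
            vocab=frozenset(d["vocab"]),
            alpha=d["alpha"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "NBModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


@dataclass(frozen=True)
class SentimentResult:
    score: float              # posterior of the positive class, in [0, 1]
    polarity: str             # positive iff score > 0.5

    def __post_init__(self) -> None:
        assert 0.0 <= self.score <= 1.0


def train(corpus: Iterable[MicroblogRecord], alpha: float = 1.0) -> NBModel:
    """Fit the multinomial model with additive smoothing ``alpha``.

    Requires at least one document of each polarity and alpha > 0 (alpha = 0
    would leave zero-probability tokens that annihilate posteriors).
    """
    if alpha <= 0:
        raise ValueError(f"smoothing alpha must be > 0, got {alpha}")
    counts: dict[str, Counter] = {c: Counter() for c in CLASSES}
    n_docs: dict[str, int] = {c: 0 for c in CLASSES}
    for rec in corpus:
        if rec.label not in CLASSES:
            raise ValueError(f"record {rec.id!r}: unlabeled or bad label {rec.label!r}")
        if rec.tokens is None:
            raise ValueError(f"record {rec.id!r}: training requires tokens")
        counts[rec.label].update(rec.tokens)
        n_docs[rec.label] += 1
    missing = [c for c in CLASSES if n_docs[c] == 0]
    if missing:
        raise ValueError(f"training corpus has no documents of class {missing}")

    vocab = frozenset(counts[POSITIVE]) | frozenset(counts[NEGATIVE])
    total_docs = sum(n_docs.values())
    log_prior = {c: math.log(n_docs[c] / total_docs) for c in CLASSES}
    log_cond: dict[str, dict[str, float]] = {}
    log_unseen: dict[str, float] = {}
    for c in CLASSES:
        n_c = sum(counts[c].values())
        denom = n_c + alpha * len(vocab)
        log_cond[c] = {w: math.log((counts[c][w] + alpha) / denom) for w in vocab}
        log_unseen[c] = math.log(alpha / denom)
    return NBModel(log_prior, log_cond, log_unseen, vocab, alpha)


def score(model: NBModel, tokens: Sequence[str]) -> SentimentResult:
    """Posterior of the positive class for one token sequence.

    Empty input returns the prior.  Complementarity holds by construction:
    P(pos|d) + P(neg|d) = 1.
    """
    log_post = {}
    for c in CLASSES:
        lp = model.log_prior[c]
        cond = model.log_cond[c]
        unseen = model.log_unseen[c]
        for t in tokens:
            lp += cond.get(t, unseen)
        log_post[c] = lp
    m = max(log_post.values())
    num = math.exp(log_post[POSITIVE] - m)
    den = num + math.exp(log_post[NEGATIVE] - m)
    s = num / den
    return SentimentResult(score=s, polarity=POSITIVE if s > 0.5 else NEGATIVE)


@dataclass
class SeasonAggregate:
    """Per (region, season) sentiment aggregates used by the tolerance index.

    ``ae_pos`` / ``ae_neg`` are None (explicitly flagged undefined) when the
    corresponding polarity group is empty.
    """

    region: str
    season: int
    we_pos: int
    we_neg: int
    ae_pos: float | None
    ae_neg: float | None


def score_corpus(
    model: NBModel, corpus: Iterable[MicroblogRecord]
) -> tuple[list[MicroblogRecord], list[SeasonAggregate]]:
    """Score every record in place and aggregate by (region, winter season).

    Returns the scored records and per-group counts (WEp, WEN) and mean
    scores (AEp, AEN) over the positive/negative polarity groups.  Posts
    falling outside a winter season are scored but excluded from aggregates.
    """
    scored: list[MicroblogRecord] = []
    groups: dict[tuple[str, int], dict[str, list[float]]] = {}
    for rec in corpus:
        if rec.tokens is None:
            raise ValueError(f"record {rec.id!r}: score_corpus requires tokens")
        res = score(model, rec.tokens)
        rec.score = res.score
        scored.append(rec)
        season = winter_season(rec.timestamp)
        if season is None:
            continue
        g = groups.setdefault((rec.region, season), {POSITIVE: [], NEGATIVE: []})
        g[res.polarity].append(res.score)

    aggregates = [
        SeasonAggregate(
            region=region,
            season=season,
            we_pos=len(g[POSITIVE]),
            we_neg=len(g[NEGATIVE]),
            ae_pos=(sum(g[POSITIVE]) / len(g[POSITIVE])) if g[POSITIVE] else None,
            ae_neg=(sum(g[NEGATIVE]) / len(g[NEGATIVE])) if g[NEGATIVE] else None,
        )
        for (region, season), g in sorted(groups.items())
    ]
    return scored, aggregates


def aggregates_frame(aggregates: Iterable[SeasonAggregate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": a.region,
                "season": a.season,
                "we_pos": a.we_pos,
                "we_neg": a.we_neg,
                "ae_pos": a.ae_pos,
                "ae_neg": a.ae_neg,
            }
            for a in aggregates
        ]
    )
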