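"""TF-IDF keywords, co-word topic index, haze-perception index, and the
social-media indicators (C14-C18) of the evaluation panel.

TF-IDF dialect: tf = count / document length, idf = ln(N / df) with no
offsets, so a term present in every document scores 0.  The topic index is a
co-word (document-level co-occurrence) network statistic: the total weight
of co-occurrence edges incident to a set of haze seed terms, divided by the
number of documents — invariant to duplicating the corpus and to token order
within a document.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from hazetol.records import MicroblogRecord, winter_season


@dataclass(frozen=True)
class KeywordScore:
    token: str
    tf: float
    idf: float
    tfidf: float


def tfidf_keywords(
    docs: Sequence[Sequence[str]], top_k: int = 10
) -> list[list[KeywordScore]]:
    """Rank each document's terms by tf-idf.

    tf = term count / document length; idf = ln(N/df).  Ranking is
    descending by tf-idf with lexicographic tie-break.  Raises on a corpus
    with no non-empty document.
    """
    if not any(len(d) for d in docs):
        raise ValueError("tfidf_keywords: all documents are empty")
    n_docs = len(docs)
    df: Counter = Counter()
    for d in docs:
        df.update(set(d))
    idf = {t: math.log(n_docs / c) for t, c in df.items()}
    out: list[list[KeywordScore]] = []
    for d in docs:
        if not d:
            out.append([])
            continue
        counts = Counter(d)
        scores = [
            KeywordScore(t, c / len(d), idf[t], (c / len(d)) * idf[t])
            for t, c in counts.items()
        ]
        scores.sort(key=lambda k: (-k.tfidf, k.token))
        out.append(scores[:top_k])
    return out


def coword_network(docs: Iterable[Sequence[str]]) -> nx.Graph:
    """Document-level co-occurrence graph: edge weight = number of documents
    in which both (distinct) tokens appear, counted at most once per doc."""
    g = nx.Graph()
    for d in docs:
        for a, b in combinations(sorted(set(d)), 2):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return g


def topic_index(docs: Sequence[Sequence[str]], seed_terms: Iterable[str]) -> float:
    """Intensity of discussion around ``seed_terms``.

    Sum of co-word edge weights incident to any seed term, divided by the
    number of documents.  Returns 0 (with a warning) for an empty corpus.
    """
    seeds = set(seed_terms)
    if not seeds:
        raise ValueError("topic_index: seed_terms must be non-empty")
    docs = list(docs)
    if not docs:
        warnings.warn("topic_index: no documents; returning 0", stacklevel=2)
        return 0.0
    g = coword_network(docs)
    total = 0
    seen = set()
    for s in seeds & set(g.nodes):
        for u, v, w in g.edges(s, data="weight"):
            key = frozenset((u, v))
            if key not in seen:
                seen.add(key)
                total += w
    return total / len(docs)


def minmax(values: Sequence[float]) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant vector maps to all ones."""
    x = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        return np.ones_like(x)
    return (x - lo) / (hi - lo)


def perception_index(
    n_haze_posts: Sequence[int],
    n_total_posts: Sequence[int],
    topic_idx: Sequence[float],
    weights: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
) -> np.ndarray:
    """Haze-perception index per region: weighted sum of the min-max scaled
    haze-post share, haze-post count, and topic index.

    The three weights must be non-negative and sum to 1 (default equal).
    The index is relative to the dataset: the region at the maximum of every
    component scores 1, the region at every minimum scores 0.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("perception_index: need 3 non-negative weights summing to 1")
    total = np.asarray(n_total_posts, dtype=float)
    if (total <= 0).any():
        raise ValueError("perception_index: zero total posts for some region")
    haze = np.asarray(n_haze_posts, dtype=float)
    share = minmax(haze / total)
    count = minmax(haze)
    topic = minmax(np.asarray(topic_idx, dtype=float))
    return w[0] * share + w[1] * count + w[2] * topic


@dataclass
class SocialMediaIndicators:
    """Table-5 social-media block for one (region, season).

    Correlations are Pearson r on daily aggregates within the winter season;
    they are None (flagged missing, never defaulted) when fewer than 3
    paired days exist or a series is constant.
    """

    region: str
    season: int
    n_posts: int                    # C14
    corr_number: float | None       # C15: r(daily post count, daily mean PM2.5)
    mean_sentiment: float           # C16
    corr_sentiment: float | None    # C17: r(daily mean score, daily mean PM2.5)
    topic_index: float              # C18


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None
    r = stats.pearsonr(x, y).statistic
    return float(r)


def compute_indicators(
    scored_corpus: Iterable[MicroblogRecord],
    pm25: pd.DataFrame,
    seed_terms: Iterable[str] = ("haze", "smog", "pm25"),
) -> list[SocialMediaIndicators]:
    """C14-C18 per (region, winter season) from a scored corpus and a daily
    PM2.5 table with columns (region, date, concentration)."""
    rows = []
    for rec in scored_corpus:
        season = winter_season(rec.timestamp)
        if season is None:
            continue
        if rec.score is None:
            raise ValueError(f"record {rec.id!r}: not scored")
        rows.append(
            {
                "region": rec.region,
                "season": season,
                "date": rec.timestamp.date(),
                "score": rec.score,
                "tokens": rec.tokens if rec.tokens is not None else [],
            }
        )
    if not rows:
        return []
    corpus_df = pd.DataFrame(rows)

    pm = pm25.copy()
    pm["date"] = pd.to_datetime(pm["date"]).dt.date

    out: list[SocialMediaIndicators] = []
    for (region, season), grp in sorted(corpus_df.groupby(["region", "season"])):
        daily = grp.groupby("date").agg(n=("score", "size"), mean_score=("score", "mean"))
        pm_region = pm[pm["region"] == region].set_index("date")["concentration"]
        paired = daily.join(pm_region.rename("pm25"), how="inner").dropna()
        out.append(
            SocialMediaIndicators(
                region=region,
                season=int(season),
                n_posts=int(len(grp)),
                corr_number=_safe_pearson(
                    paired["n"].to_numpy(float), paired["pm25"].to_numpy(float)
                ),
                mean_sentiment=float(grp["score"].mean()),
                corr_sentiment=_safe_pearson(
                    paired["mean_score"].to_numpy(float), paired["pm25"].to_numpy(float)
                ),
                topic_index=topic_index(list(grp["tokens"]), seed_terms),
            )
        )
    return out


def indicators_frame(indicators: Iterable[SocialMediaIndicators]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": i.region,
                "season": i.season,
                "C14": i.n_posts,
                "C15": i.corr_number,
                "C16": i.mean_sentiment,
                "C17": i.corr_sentiment,
                "C18": i.topic_index,
            }
            for i in indicators
        ]
    )
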