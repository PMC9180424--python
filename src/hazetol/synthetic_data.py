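"""Synthetic study-condition generator.

Emulates the statistical structure the downstream analysis assumes, so that
every stage is testable without scraping or downloads:

* daily winter PM2.5 per region, lognormal around configured region means
  (defaults follow the printed winter means of the seven study regions);
* a microblog corpus whose daily volume rises with same-day PM2.5 (Poisson
  with a log link on standardized PM2.5) and whose latent sentiment class is
  Bernoulli with a logit-linear dependence on PM2.5 — the configured slope
  applies to the POSITIVE class, so a negative slope couples sentiment
  negatively to pollution;
* class-conditional multinomial token distributions (matching the naive-
  Bayes model family, so classifier recovery is well-posed) and a labeled
  training corpus;
* an 18-indicator region-year panel in the evaluation-system schema, whose
  social-media block (C14-C18) is computed from the generated corpus via
  the sentiment and keyword modules;
* per-unit Markov class-state sequences for trajectory coding.

All randomness flows from ``SimConfig.seed`` through named substreams, so an
identical config reproduces a byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from hazetol import keywords_topics, sentiment_nb
from hazetol.records import MicroblogRecord

#: Winter-mean PM2.5 levels (ug/m3) used as the seven default region levels.
DEFAULT_REGION_MEANS = (90.0, 88.0, 75.0, 80.0, 86.0, 60.0, 67.0)

HAZE_TERMS = ("haze", "smog", "mask", "pollution", "pm25")
POSITIVE_TERMS = ("blue", "sky", "clear", "happy", "sunshine")


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the emulated study conditions."""

    n_regions: int = 7
    years: tuple[int, ...] = (2013, 2014, 2015, 2016, 2017, 2018, 2019)
    season_days: int = 90
    pm25_region_means: tuple[float, ...] = DEFAULT_REGION_MEANS
    pm25_sigma: float = 0.3                # lognormal scale (log-space sd)
    posts_per_day_base: float = 2.5        # Poisson rate at average PM2.5
    count_pm25_slope: float = 0.4          # log-link slope of volume on z(PM2.5)
    sentiment_pm25_slope: float = -0.8     # logit slope of P(positive) on z(PM2.5)
    base_positive_share: float = 0.55      # P(positive) at average PM2.5
    vocab_size: int = 200
    mean_tokens_per_post: float = 8.0
    n_train_docs: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions <= 0 or self.season_days <= 0 or self.vocab_size <= 0:
            raise ValueError("counts must be > 0")
        if len(self.years) == 0:
            raise ValueError("years must be non-empty")
        if len(self.pm25_region_means) != self.n_regions:
            raise ValueError(
                f"{len(self.pm25_region_means)} region means for {self.n_regions} regions"
            )
        if any(m <= 0 for m in self.pm25_region_means):
            raise ValueError("PM2.5 region means must be > 0")
        if self.pm25_sigma < 0:
            raise ValueError("pm25_sigma must be >= 0")
        if not (0.0 < self.base_positive_share < 1.0):
            raise ValueError("base_positive_share must lie strictly in (0, 1)")
        if self.n_train_docs < 0 or self.posts_per_day_base < 0:
            raise ValueError("rates/counts must be non-negative")

    @property
    def regions(self) -> list[str]:
        return [f"region_{i + 1:02d}" for i in range(self.n_regions)]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stream])


def build_vocab(config: SimConfig) -> list[str]:
    generic = [f"tok_{i:04d}" for i in range(max(0, config.vocab_size - 10))]
    return list(HAZE_TERMS) + list(POSITIVE_TERMS) + generic


def class_token_distributions(config: SimConfig) -> dict[str, np.ndarray]:
    """Class-conditional multinomial token probabilities.

    A Zipf-like base is tilted: the negative class up-weights haze terms
    (complaints name the smog), the positive class up-weights the
    clear-weather terms.  Both classes still cover the full vocabulary.
    """
    vocab = build_vocab(config)
    base = 1.0 / (np.arange(len(vocab)) + 2.0)
    boosts = {"positive": np.ones(len(vocab)), "negative": np.ones(len(vocab))}
    for i, tok in enumerate(vocab):
        if tok in HAZE_TERMS:
            boosts["negative"][i] = 8.0
            boosts["positive"][i] = 0.8
        elif tok in POSITIVE_TERMS:
            boosts["positive"][i] = 8.0
            boosts["negative"][i] = 0.5
    return {c: (base * b) / (base * b).sum() for c, b in boosts.items()}


def generate_pm25(config: SimConfig) -> pd.DataFrame:
    """Daily winter PM2.5 per region: columns (region, date, season,
    concentration).  Winter of year Y starts 1 December Y and runs
    ``season_days`` days.  Values are lognormal with arithmetic mean equal
    to the configured region mean; sigma = 0 degenerates to the mean."""
    rng = _rng(config, 1)
    rows = []
    for year in config.years:
        start = date(year, 12, 1)
        dates = [start + timedelta(days=d) for d in range(config.season_days)]
        for region, mean in zip(config.regions, config.pm25_region_means):
            if config.pm25_sigma == 0:
                vals = np.full(config.season_days, mean)
            else:
                mu = np.log(mean) - config.pm25_sigma**2 / 2.0
                vals = rng.lognormal(mu, config.pm25_sigma, size=config.season_days)
            for d, v in zip(dates, vals):
                rows.append(
                    {"region": region, "date": d, "season": year,
                     "concentration": float(v)}
                )
    return pd.DataFrame(rows)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_corpus(
    config: SimConfig, pm25: pd.DataFrame
) -> tuple[list[MicroblogRecord], list[MicroblogRecord]]:
    """Posts coupled to PM2.5, plus a labeled training corpus.

    Daily volume per region-day is Poisson(base * exp(slope_n * z)) and the
    latent class is positive with probability
    sigmoid(logit(p0) + slope_s * z), z the standardized log concentration
    over the whole table.  Generated records carry their latent class as
    ``label`` (ground truth for validation); training documents are drawn
    50/50 from the two class-conditional token distributions.
    """
    if pm25.empty:
        raise ValueError("generate_corpus: empty PM2.5 table")
    rng = _rng(config, 2)
    vocab = np.array(build_vocab(config))
    dists = class_token_distributions(config)

    logc = np.log(pm25["concentration"].to_numpy(float))
    z = (logc - logc.mean()) / (logc.std() if logc.std() > 0 else 1.0)
    rate = config.posts_per_day_base * np.exp(config.count_pm25_slope * z)
    n_posts = rng.poisson(rate)
    p_pos = _sigmoid(
        np.log(config.base_positive_share / (1 - config.base_positive_share))
        + config.sentiment_pm25_slope * z
    )

    total = int(n_posts.sum())
    post_region = np.repeat(pm25["region"].to_numpy(), n_posts)
    post_date = np.repeat(pm25["date"].to_numpy(), n_posts)
    post_p = np.repeat(p_pos, n_posts)
    is_pos = rng.random(total) < post_p
    lengths = 1 + rng.poisson(config.mean_tokens_per_post - 1, size=total)
    tokens = _draw_tokens(rng, vocab, dists, is_pos, lengths)

    corpus = [
        MicroblogRecord(
            id=f"post_{i:07d}",
            region=str(post_region[i]),
            timestamp=datetime.combine(post_date[i], datetime.min.time())
            + timedelta(hours=12),
            tokens=tokens[i],
            label="positive" if is_pos[i] else "negative",
        )
        for i in range(total)
    ]

    rng_t = _rng(config, 3)
    t0 = datetime(min(config.years), 12, 1, 12)
    n_train = config.n_train_docs
    t_is_pos = rng_t.random(n_train) < 0.5
    t_lengths = 1 + rng_t.poisson(config.mean_tokens_per_post - 1, size=n_train)
    t_tokens = _draw_tokens(rng_t, vocab, dists, t_is_pos, t_lengths)
    train = [
        MicroblogRecord(
            id=f"train_{i:06d}",
            region=config.regions[i % config.n_regions],
            timestamp=t0,
            tokens=t_tokens[i],
            label="positive" if t_is_pos[i] else "negative",
        )
        for i in range(n_train)
    ]
    return corpus, train


def _draw_tokens(
    rng: np.random.Generator,
    vocab: np.ndarray,
    dists: dict[str, np.ndarray],
    is_pos: np.ndarray,
    lengths: np.ndarray,
) -> list[list[str]]:
    """Draw every post's tokens in two bulk multinomial passes (one per
    class); much faster than per-post sampling and just as reproducible."""
    n = len(lengths)
    tokens: list[list[str]] = [[] for _ in range(n)]
    for cls, mask in (("positive", is_pos), ("negative", ~is_pos)):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        lens = lengths[idx]
        flat = rng.choice(len(vocab), size=int(lens.sum()), p=dists[cls])
        words = vocab[flat]
        for i, chunk in zip(idx, np.split(words, np.cumsum(lens)[:-1])):
            tokens[i] = [str(w) for w in chunk]
    return tokens


#: Panel schema: the 18 indicator columns of the evaluation system.
INDICATOR_COLUMNS = [f"C{i}" for i in range(1, 19)]

#: Rule layers and their indicator columns (row order of the bundled
#: within-group judgment matrices).
INDICATOR_GROUPS = {
    "ecological environment": ["C2", "C1", "C3", "C4", "C5"],
    "social economy": ["C6", "C7", "C8", "C9", "C10", "C11", "C12", "C13"],
    "social media": ["C14", "C15", "C16", "C17", "C18"],
}

#: Default standardization directions.  Pressure-type indicators (pollution
#: level and days, crowding, heavy-industry share) count as costs; the rest
#: as benefits.  A convention: the direction map is a required analysis
#: input, not a fact of the evaluation system.
DEFAULT_DIRECTIONS = {
    "C1": "cost", "C2": "benefit", "C3": "benefit", "C4": "benefit", "C5": "cost",
    "C6": "cost", "C7": "benefit", "C8": "cost", "C9": "benefit", "C10": "benefit",
    "C11": "benefit", "C12": "benefit", "C13": "benefit",
    "C14": "benefit", "C15": "benefit", "C16": "benefit", "C17": "benefit",
    "C18": "benefit",
}


def generate_panel(
    config: SimConfig,
    corpus: Sequence[MicroblogRecord],
    pm25: pd.DataFrame,
    train_corpus: Sequence[MicroblogRecord] | None = None,
) -> pd.DataFrame:
    """Region-year panel with the 18-indicator schema.

    C1-C5 derive from the PM2.5 table plus synthetic winter weather; C6-C13
    are socio-economic draws around persistent region levels; C14-C18 are
    computed from the corpus through the sentiment and keyword modules (a
    naive-Bayes model trained on ``train_corpus`` scores the posts).
    """
    if pm25.empty:
        raise ValueError("generate_panel: empty PM2.5 table")
    rng = _rng(config, 4)
    regions = config.regions

    # persistent region levels for the socio-economic block
    base = {
        r: {
            "C6": rng.uniform(200, 1400),     # population density, person/km2
            "C7": rng.uniform(30_000, 120_000),  # per-capita GDP, CNY
            "C8": rng.uniform(30, 55),        # secondary-industry share, %
            "C9": rng.uniform(5, 25),         # built-up area share, %
            "C10": rng.uniform(1_000, 10_000),   # road area, 1e4 m2
            "C11": rng.uniform(8, 18),        # per-capita green space, m2
            "C12": rng.uniform(8, 14),        # education level (schooling years)
            "C13": rng.uniform(98, 106),      # gender ratio (female = 100)
        }
        for r in regions
    }

    scored = list(corpus)
    if train_corpus:
        model = sentiment_nb.train(train_corpus)
        scored, _ = sentiment_nb.score_corpus(model, scored)
    indicators = keywords_topics.compute_indicators(scored, pm25, seed_terms=HAZE_TERMS)
    ind_map = {(i.region, i.season): i for i in indicators}

    rows = []
    for year in config.years:
        for r in regions:
            sl = pm25[(pm25["region"] == r) & (pm25["season"] == year)]
            if sl.empty:
                raise ValueError(f"generate_panel: missing PM2.5 for {r}/{year}")
            conc = sl["concentration"].to_numpy(float)
            ind = ind_map.get((r, year))
            row = {
                "region": r,
                "year": year,
                "C1": float(conc.mean()),
                "C2": float(rng.normal(-4.0, 2.0)),
                "C3": float(rng.uniform(30, 70)),
                "C4": float(rng.lognormal(0.8, 0.3)),
                "C5": int((conc > 75).sum()),
            }
            for k, v in base[r].items():
                row[k] = float(v * rng.lognormal(0.0, 0.05))
            row.update(
                {
                    "C14": ind.n_posts if ind else 0,
                    "C15": _defined(ind.corr_number) if ind else np.nan,
                    "C16": ind.mean_sentiment if ind else np.nan,
                    "C17": _defined(ind.corr_sentiment) if ind else np.nan,
                    "C18": ind.topic_index if ind else 0.0,
                }
            )
            rows.append(row)
    return pd.DataFrame(rows, columns=["region", "year"] + INDICATOR_COLUMNS)


def _defined(x: float | None) -> float:
    return np.nan if x is None else x


def generate_class_raster(
    config: SimConfig, n_units: int = 100, persistence: float = 0.6,
    n_classes: int = 5,
) -> pd.DataFrame:
    """Per-unit Markov class-state sequences, one state per year.

    Each unit starts uniform over 1..n_classes and stays in its state with
    probability ``persistence``, otherwise jumps uniformly to one of the
    other states (persistence = 1/n_classes gives the uniform transition;
    persistence = 1 freezes every sequence).  Columns: unit_id, year, state.
    """
    if not (0.0 <= persistence <= 1.0):
        raise ValueError("persistence must lie in [0, 1]")
    rng = _rng(config, 5)
    rows = []
    for u in range(n_units):
        state = int(rng.integers(1, n_classes + 1))
        for year in config.years:
            rows.append({"unit_id": f"unit_{u:04d}", "year": year, "state": state})
            if rng.random() >= persistence:
                others = [s for s in range(1, n_classes + 1) if s != state]
                state = int(others[rng.integers(len(others))])
    return pd.DataFrame(rows)


@dataclass
class SyntheticBundle:
    config: SimConfig
    corpus: list[MicroblogRecord]
    train_corpus: list[MicroblogRecord]
    pm25: pd.DataFrame
    panel: pd.DataFrame
    class_raster: pd.DataFrame


def generate_bundle(config: SimConfig | None = None) -> SyntheticBundle:
    """Generate every input of the analysis from one seed."""
    config = config or SimConfig()
    pm25 = generate_pm25(config)
    corpus, train = generate_corpus(config, pm25)
    panel = generate_panel(config, corpus, pm25, train_corpus=train)
    raster = generate_class_raster(config)
    return SyntheticBundle(
        config=config, corpus=corpus, train_corpus=train,
        pm25=pm25, panel=panel, class_raster=raster,
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a bundle: corpora as JSON-lines, tables as headed CSV."""
    from hazetol.records import write_jsonl

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": out / "corpus.jsonl",
        "train_corpus": out / "train_corpus.jsonl",
        "pm25": out / "pm25.csv",
        "panel": out / "panel.csv",
        "class_raster": out / "class_raster.csv",
    }
    write_jsonl(bundle.corpus, paths["corpus"])
    write_jsonl(bundle.train_corpus, paths["train_corpus"])
    bundle.pm25.to_csv(paths["pm25"], index=False)
    bundle.panel.to_csv(paths["panel"], index=False)
    bundle.class_raster.to_csv(paths["class_raster"], index=False)
    return paths
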