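"""End-to-end orchestration: simulate -> prep -> sentiment -> indicators ->
weights -> tolerance -> trajectory, with a reproducibility manifest.

The provincial branch ends in the composite score table (weights stage);
the prefecture branch ends in the tolerance table and its trajectories.
All randomness flows from the single configured seed, so re-running an
identical config reproduces identical output hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from hazetol import (
    keywords_topics,
    mcda_weights,
    sentiment_nb,
    synthetic_data,
    text_prep,
    tolerance_index,
    trajectory,
)
from hazetol.records import read_jsonl, write_jsonl

log = logging.getLogger("hazetol.pipeline")

STAGES = ("simulate", "prep", "sentiment", "indicators", "weights",
          "tolerance", "trajectory")

#: Stage dependency DAG (stage -> stages whose outputs it consumes).
DEPENDENCIES: dict[str, tuple[str, ...]] = {
    "simulate": (),
    "prep": ("simulate",),
    "sentiment": ("prep", "simulate"),
    "indicators": ("sentiment", "simulate"),
    "weights": ("simulate", "indicators"),
    "tolerance": ("sentiment", "simulate"),
    "trajectory": ("tolerance",),
}


@dataclass
class RunConfig:
    out_dir: str | Path = "hazetol_run"
    stages: tuple[str, ...] = STAGES
    sim: synthetic_data.SimConfig = field(default_factory=synthetic_data.SimConfig)
    stopword_path: str | None = None       # None -> bundled default list
    alpha: float = 1.0                     # naive-Bayes smoothing
    directions: Mapping[str, str] = field(
        default_factory=lambda: dict(synthetic_data.DEFAULT_DIRECTIONS)
    )
    n_classes: int = 5                     # tolerance reclassification bins
    seed: int | None = None                # overrides sim.seed when set

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.seed is not None:
            self.sim = synthetic_data.SimConfig(
                **{**asdict(self.sim), "seed": self.seed,
                   "years": tuple(self.sim.years),
                   "pm25_region_means": tuple(self.sim.pm25_region_means)}
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim_raw = raw.pop("sim", {})
        if "years" in sim_raw:
            sim_raw["years"] = tuple(sim_raw["years"])
        if "pm25_region_means" in sim_raw:
            sim_raw["pm25_region_means"] = tuple(sim_raw["pm25_region_means"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(sim=synthetic_data.SimConfig(**sim_raw), **raw)


@dataclass
class RunManifest:
    seed: int
    stages_run: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)     # path -> sha256
    params: dict[str, dict] = field(default_factory=dict)
    wall_time_s: dict[str, float] = field(default_factory=dict)
    complete: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_stage_plan(stages: tuple[str, ...]) -> None:
    enabled = set(stages)
    for s in enabled:
        missing = set(DEPENDENCIES[s]) - enabled
        if missing:
            raise ValueError(
                f"stage {s!r} requires disabled stage(s) {sorted(missing)}: "
                "enable them or supply their outputs"
            )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order.

    On stage failure the run aborts with the stage name and cause; outputs
    of completed stages are retained and the manifest (written regardless)
    marks the run incomplete.
    """
    validate_stage_plan(config.stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.sim.seed)
    enabled = [s for s in STAGES if s in config.stages]

    def register(stage: str, *paths: Path) -> None:
        for p in paths:
            manifest.outputs[str(p.relative_to(out))] = _sha256(p)

    try:
        for stage in enabled:
            t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            paths = _STAGE_FNS[stage](config, out)
            register(stage, *paths)
            manifest.stages_run.append(stage)
            manifest.wall_time_s[stage] = round(time.perf_counter() - t0, 3)
        manifest.complete = True
    except Exception as exc:  # noqa: BLE001 - annotate with stage and re-raise
        (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
        raise StageError(stage, exc) from exc
    manifest.params = {
        "sim": asdict(config.sim),
        "alpha": {"alpha": config.alpha},
        "n_classes": {"n_classes": config.n_classes},
    }
    (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return manifest


# --- individual stages ------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path) -> list[Path]:
    bundle = synthetic_data.generate_bundle(config.sim)
    return list(synthetic_data.write_bundle(bundle, out).values())


def _stage_prep(config: RunConfig, out: Path) -> list[Path]:
    stops = (
        text_prep.StopWordList.from_file(config.stopword_path)
        if config.stopword_path
        else text_prep.StopWordList.default()
    )
    prepped = []
    for rec in read_jsonl(out / "corpus.jsonl"):
        if rec.tokens is None:
            rec.tokens = text_prep.tokenize(text_prep.clean_text(rec.text or ""))
        rec.tokens = text_prep.filter_stopwords(rec.tokens, stops)
        prepped.append(rec)
    p = out / "corpus_prepped.jsonl"
    write_jsonl(prepped, p)
    return [p]


def _stage_sentiment(config: RunConfig, out: Path) -> list[Path]:
    train = list(read_jsonl(out / "train_corpus.jsonl"))
    corpus = list(read_jsonl(out / "corpus_prepped.jsonl"))
    model = sentiment_nb.train(train, alpha=config.alpha)
    scored, aggregates = sentiment_nb.score_corpus(model, corpus)
    p_model, p_scored, p_agg = (
        out / "nb_model.json", out / "corpus_scored.jsonl", out / "aggregates.csv",
    )
    model.save(p_model)
    write_jsonl(scored, p_scored)
    sentiment_nb.aggregates_frame(aggregates).to_csv(p_agg, index=False)
    return [p_model, p_scored, p_agg]


def _stage_indicators(config: RunConfig, out: Path) -> list[Path]:
    scored = list(read_jsonl(out / "corpus_scored.jsonl"))
    pm25 = pd.read_csv(out / "pm25.csv", parse_dates=["date"])
    inds = keywords_topics.compute_indicators(
        scored, pm25, seed_terms=synthetic_data.HAZE_TERMS
    )
    p = out / "indicators.csv"
    keywords_topics.indicators_frame(inds).to_csv(p, index=False)
    return [p]


def _stage_weights(config: RunConfig, out: Path) -> list[Path]:
    panel = pd.read_csv(out / "panel.csv")
    idx = panel[["region", "year"]]
    values = panel[synthetic_data.INDICATOR_COLUMNS]
    std = mcda_weights.standardize(values, config.directions)
    ws = mcda_weights.build_weight_set(
        mcda_weights.load_bundled_matrices(), std, synthetic_data.INDICATOR_GROUPS
    )
    for name, rep in ws.consistency.items():
        log.info("consistency %-22s CR=%.4f (%s)", name, rep.CR,
                 "ok" if rep.consistent else "REJECT")
    comp = mcda_weights.composite_score(ws.combined, std)
    comp = pd.concat([idx, comp], axis=1)
    p_w, p_c, p_z = out / "weights.csv", out / "consistency.csv", out / "composite.csv"
    ws.frame().to_csv(p_w, index_label="indicator")
    pd.DataFrame(
        [
            {"matrix": k, "lambda_max": r.lambda_max, "CI": r.CI, "RI": r.RI,
             "CR": r.CR, "consistent": r.consistent}
            for k, r in ws.consistency.items()
        ]
    ).to_csv(p_c, index=False)
    comp.to_csv(p_z, index=False)
    return [p_w, p_c, p_z]


def _stage_tolerance(config: RunConfig, out: Path) -> list[Path]:
    agg_df = pd.read_csv(out / "aggregates.csv")
    aggregates = [
        sentiment_nb.SeasonAggregate(
            region=str(r.region), season=int(r.season),
            we_pos=int(r.we_pos), we_neg=int(r.we_neg),
            ae_pos=None if pd.isna(r.ae_pos) else float(r.ae_pos),
            ae_neg=None if pd.isna(r.ae_neg) else float(r.ae_neg),
        )
        for r in agg_df.itertuples()
    ]
    pm25 = pd.read_csv(out / "pm25.csv")
    means = (
        pm25.groupby(["region", "season"])["concentration"].mean().reset_index()
    )
    tol = tolerance_index.tolerance_panel(aggregates, means, n_classes=config.n_classes)
    p = out / "tolerance.csv"
    tol.to_csv(p, index=False)
    return [p]


def _stage_trajectory(config: RunConfig, out: Path) -> list[Path]:
    tol = pd.read_csv(out / "tolerance.csv")
    sequences = {
        region: [
            None if pd.isna(c) else int(c)
            for _, c in grp.sort_values("period")["class"].items()
        ]
        for region, grp in tol.groupby("region")
    }
    table, summary = trajectory.trajectory_table(sequences)
    p_t, p_s = out / "trajectory.csv", out / "trajectory_summary.json"
    table.to_csv(p_t, index=False)
    p_s.write_text(json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8")
    return [p_t, p_s]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "prep": _stage_prep,
    "sentiment": _stage_sentiment,
    "indicators": _stage_indicators,
    "weights": _stage_weights,
    "tolerance": _stage_tolerance,
    "trajectory": _stage_trajectory,
}
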