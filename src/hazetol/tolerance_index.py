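"""Prefecture-level haze psychological-tolerance index.

For one region and season,

    T = (WEp * AEp) / (WEN * (1 - AEN) * C_PM2.5)

where WEp/WEN count positive/negative posts, AEp/AEN are the mean positive
and negative sentiment scores, and C_PM2.5 is the seasonal mean PM2.5
concentration (ug/m3).  Larger T means the population tolerates the haze
better: many, strongly positive posts against few, mildly negative ones per
unit of pollution.  T is undefined — a flagged missing value, never an
epsilon-patched number — when either polarity group is empty or AEN = 1.

Defined T values over a panel of region-seasons are reclassified into five
equal-interval classes (1 = low ... 5 = high tolerance) over the pooled
range, so class codes are comparable across seasons and feed the trajectory
coding directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from hazetol.sentiment_nb import SeasonAggregate


@dataclass(frozen=True)
class ToleranceInputs:
    we_pos: int
    we_neg: int
    ae_pos: float | None
    ae_neg: float | None
    c_pm25: float

    def __post_init__(self) -> None:
        if self.we_pos < 0 or self.we_neg < 0:
            raise ValueError("post counts must be non-negative")
        if self.c_pm25 <= 0:
            raise ValueError(f"PM2.5 concentration must be > 0, got {self.c_pm25}")
        for name, val in (("ae_pos", self.ae_pos), ("ae_neg", self.ae_neg)):
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name}={val} outside [0, 1]")


@dataclass(frozen=True)
class ToleranceResult:
    region: str
    period: int
    T: float | None          # None = undefined (empty polarity group or AEN=1)
    inputs: ToleranceInputs


def tolerance(inputs: ToleranceInputs, region: str = "", period: int = 0) -> ToleranceResult:
    """Evaluate the tolerance ratio; undefined inputs yield a flagged None."""
    t: float | None
    if (
        inputs.we_pos == 0
        or inputs.we_neg == 0
        or inputs.ae_pos is None
        or inputs.ae_neg is None
        or inputs.ae_neg >= 1.0
    ):
        t = None
    else:
        t = (inputs.we_pos * inputs.ae_pos) / (
            inputs.we_neg * (1.0 - inputs.ae_neg) * inputs.c_pm25
        )
    return ToleranceResult(region=region, period=period, T=t, inputs=inputs)


def classify_equal_interval(values: pd.Series, n_classes: int = 5) -> pd.Series:
    """Equal-interval classes 1..n over the pooled range of defined values.

    Intervals are right-open except the last (closed), so the maximum falls
    in class n.  A degenerate range (single distinct value, e.g. one row)
    puts everything in the top class.  NaNs stay NaN.
    """
    x = values.astype(float)
    defined = x.dropna()
    out = pd.Series(np.nan, index=values.index, dtype=float)
    if defined.empty:
        return out
    lo, hi = defined.min(), defined.max()
    if hi == lo:
        out[defined.index] = n_classes
        return out
    edges = np.linspace(lo, hi, n_classes + 1)
    cls = np.digitize(defined.to_numpy(), edges[1:-1], right=False) + 1
    out[defined.index] = cls
    return out


def tolerance_panel(
    aggregates: Iterable[SeasonAggregate],
    pm25_means: Mapping[tuple[str, int], float] | pd.DataFrame,
    n_classes: int = 5,
) -> pd.DataFrame:
    """Tolerance table over region-seasons with 5-class reclassification.

    ``pm25_means`` maps (region, season) to the seasonal mean concentration,
    or is a frame with columns (region, season, concentration).  Regions
    present in the corpus but missing from PM2.5 are reported with missing
    T (never silently dropped).  Class codes are equal-interval over all
    defined T values in the panel.
    """
    if isinstance(pm25_means, pd.DataFrame):
        pm25_means = {
            (str(r.region), int(r.season)): float(r.concentration)
            for r in pm25_means.itertuples()
        }
    rows = []
    for agg in aggregates:
        key = (agg.region, agg.season)
        c = pm25_means.get(key)
        if c is None:
            rows.append(
                {
                    "region": agg.region, "period": agg.season,
                    "we_pos": agg.we_pos, "we_neg": agg.we_neg,
                    "ae_pos": agg.ae_pos, "ae_neg": agg.ae_neg,
                    "c_pm25": np.nan, "T": np.nan, "missing_pm25": True,
                }
            )
            continue
        res = tolerance(
            ToleranceInputs(agg.we_pos, agg.we_neg, agg.ae_pos, agg.ae_neg, c),
            region=agg.region,
            period=agg.season,
        )
        rows.append(
            {
                "region": agg.region, "period": agg.season,
                "we_pos": agg.we_pos, "we_neg": agg.we_neg,
                "ae_pos": agg.ae_pos, "ae_neg": agg.ae_neg,
                "c_pm25": c, "T": res.T if res.T is not None else np.nan,
                "missing_pm25": False,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["class"] = pd.Series(dtype=float)
        return df
    df["class"] = classify_equal_interval(df["T"], n_classes=n_classes)
    return df
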