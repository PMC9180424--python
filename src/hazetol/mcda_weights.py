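"""AHP-entropy multi-criteria weighting and the composite tolerance score.

Subjective weights come from the principal eigenvector of a positive
reciprocal pairwise-comparison (judgment) matrix on the Saaty 1-9 scale,
with the consistency test

    CI = (lambda_max - n) / (n - 1),   CR = CI / RI(n),

where RI(n) is the tabulated average random consistency index and CR < 0.1
deems the judgments acceptable.  Objective weights come from the entropy
method on a range-standardized indicator panel; combined weights are the
normalized geometric mean of the two.  The composite score of an evaluation
object is the weighted sum z = sum_j w_j x_j of its standardized indicator
values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

#: Average random consistency index for matrix orders 1-9.
RI_TABLE: dict[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45,
}

CR_THRESHOLD = 0.1

_DATA = Path(__file__).parent / "data"

#: Pairwise-comparison fixtures shipped with the package: the first-level
#: matrix over the three rule layers and the three within-group matrices
#: (ecological, socio-economic, social-media).
BUNDLED_MATRICES = {
    "primary": _DATA / "table6.csv",
    "ecological environment": _DATA / "table7.csv",
    "social economy": _DATA / "table8.csv",
    "social media": _DATA / "table9.csv",
}


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class JudgmentMatrix:
    """Square positive reciprocal pairwise-comparison matrix with labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    @property
    def order(self) -> int:
        return len(self.labels)

    def __post_init__(self) -> None:
        a = self.values
        n = self.order
        if a.shape != (n, n):
            raise ValidationError(f"matrix is {a.shape}, expected ({n}, {n})")
        if (a <= 0).any():
            bad = [tuple(ix) for ix in np.argwhere(a <= 0)]
            raise ValidationError(f"non-positive entries at {bad}")
        if not np.allclose(np.diag(a), 1.0, atol=1e-9):
            raise ValidationError("diagonal entries must be 1")
        recip = np.abs(a * a.T - 1.0)
        bad = np.argwhere(recip > 1e-3)
        bad = [tuple(ix) for ix in bad if ix[0] < ix[1]]
        if bad:
            cells = ", ".join(
                f"a[{i},{j}]={a[i, j]:g} vs a[{j},{i}]={a[j, i]:g}" for i, j in bad
            )
            raise ValidationError(f"reciprocity violated: {cells}")


def read_judgment_matrix(path: str | Path) -> JudgmentMatrix:
    """Read and validate a CSV judgment matrix (label header row and column)."""
    df = pd.read_csv(path, index_col=0)
    labels = tuple(str(c).strip() for c in df.columns)
    row_labels = tuple(str(r).strip() for r in df.index)
    if labels != row_labels:
        raise ValidationError(
            f"{path}: row labels {row_labels} differ from column labels {labels}"
        )
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric cell ({exc})") from exc
    return JudgmentMatrix(labels=labels, values=values)


def load_bundled_matrices() -> dict[str, JudgmentMatrix]:
    return {name: read_judgment_matrix(p) for name, p in BUNDLED_MATRICES.items()}


def ri_lookup(n: int) -> float:
    """Average random consistency index RI for a matrix of order ``n`` (1-9)."""
    if n not in RI_TABLE:
        raise ValueError(f"RI table covers orders 1-9; got {n}")
    return RI_TABLE[n]


@dataclass(frozen=True)
class ConsistencyReport:
    lambda_max: float
    CI: float
    RI: float
    CR: float
    consistent: bool


def ahp_weights(
    matrix: JudgmentMatrix,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, ConsistencyReport]:
    """Principal-eigenvector weights and consistency report.

    Power iteration on the positive matrix (Perron-Frobenius guarantees a
    unique positive dominant eigenvector); lambda_max is the converged
    Rayleigh quotient.  CR is defined as 0 when RI(n) = 0 (n <= 2, where any
    reciprocal matrix is consistent).
    """
    a = matrix.values
    n = matrix.order
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        v = a @ w
        lam = float(v.sum())  # since sum(w) = 1, this is the eigenvalue estimate
        v = v / v.sum()
        if np.max(np.abs(v - w)) < tol * max(1.0, np.max(np.abs(v))):
            w = v
            lam = float((a @ w).sum())
            break
        w = v
    else:
        raise ArithmeticError(f"power iteration did not converge in {max_iter} steps")
    ci = (lam - n) / (n - 1) if n > 1 else 0.0
    ci = max(ci, 0.0)
    ri = ri_lookup(n)
    cr = ci / ri if ri > 0 else 0.0
    return w, ConsistencyReport(lambda_max=lam, CI=ci, RI=ri, CR=cr,
                                consistent=cr < CR_THRESHOLD)


def compose_hierarchy(
    first_level: Mapping[str, float],
    groups: Mapping[str, Mapping[str, float]],
) -> dict[str, float]:
    """Absolute indicator weights: rule-layer weight x within-group weight.

    ``first_level`` maps rule-layer name -> weight; ``groups`` maps the same
    names to within-group weight dicts.  Every vector must sum to 1; the
    output sums to 1 by construction.
    """
    if set(first_level) != set(groups):
        raise ValueError(
            f"rule layers {sorted(first_level)} do not match groups {sorted(groups)}"
        )
    for name, vec in [("first_level", first_level), *groups.items()]:
        s = sum(vec.values()) if isinstance(vec, Mapping) else 0.0
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"weights of {name!r} sum to {s}, expected 1")
    out: dict[str, float] = {}
    for layer, lw in first_level.items():
        for label, gw in groups[layer].items():
            if label in out:
                raise ValueError(f"duplicate indicator label {label!r}")
            out[label] = lw * gw
    return out


Direction = Literal["benefit", "cost"]


def standardize(
    panel: pd.DataFrame,
    directions: Mapping[str, Direction],
    zero_floor: float = 0.01,
) -> pd.DataFrame:
    """Range (min-max) standardization with per-indicator direction.

    benefit: (x - min) / (max - min); cost: (max - x) / (max - min).
    Exact zeros in the standardized output are replaced by ``zero_floor``
    (keeps every entry strictly positive for the entropy shares); constant
    columns standardize to 1 for every object, so they carry no entropy
    information and receive zero entropy weight.
    """
    missing = set(panel.columns) - set(directions)
    if missing:
        raise ValueError(f"no direction configured for indicators {sorted(missing)}")
    out = {}
    for col in panel.columns:
        x = pd.to_numeric(panel[col], errors="raise").to_numpy(dtype=float)
        if np.isnan(x).any():
            rows = list(panel.index[np.isnan(x)])
            raise ValueError(f"non-numeric/missing cells in column {col!r}, rows {rows}")
        lo, hi = x.min(), x.max()
        if hi == lo:
            y = np.ones_like(x)
        elif directions[col] == "benefit":
            y = (x - lo) / (hi - lo)
        elif directions[col] == "cost":
            y = (hi - x) / (hi - lo)
        else:
            raise ValueError(f"direction for {col!r} must be 'benefit' or 'cost'")
        y[y == 0.0] = zero_floor
        out[col] = y
    return pd.DataFrame(out, index=panel.index)


@dataclass
class EntropyTable:
    Y: pd.DataFrame           # standardized values (strictly positive)
    P: pd.DataFrame           # column-normalized shares, each column sums to 1
    entropy: pd.Series        # e_j in [0, 1]
    weights: pd.Series        # entropy weights S_j, sum to 1


def entropy_weights(Y: pd.DataFrame) -> EntropyTable:
    """Entropy weights over a strictly positive standardized panel.

    P_ij = Y_ij / sum_i Y_ij;  e_j = -(1/ln m) sum_i P_ij ln P_ij with m the
    number of evaluation objects;  S_j = (1 - e_j) / sum_j (1 - e_j).
    """
    y = Y.to_numpy(dtype=float)
    if (y <= 0).any():
        raise ValueError("entropy_weights requires strictly positive Y")
    m = y.shape[0]
    if m < 2:
        raise ValueError("entropy_weights requires at least 2 evaluation objects")
    p = y / y.sum(axis=0, keepdims=True)
    e = -(p * np.log(p)).sum(axis=0) / np.log(m)
    info = 1.0 - e
    # clip tiny negative round-off from columns at maximum entropy
    info = np.where(np.abs(info) < 1e-12, 0.0, info)
    if info.sum() <= 0:
        raise ValueError("degenerate panel: every indicator has maximum entropy")
    s = info / info.sum()
    return EntropyTable(
        Y=Y,
        P=pd.DataFrame(p, index=Y.index, columns=Y.columns),
        entropy=pd.Series(e, index=Y.columns, name="entropy"),
        weights=pd.Series(s, index=Y.columns, name="entropy_weight"),
    )


def combine_weights(w_subjective: pd.Series, w_objective: pd.Series) -> pd.Series:
    """Normalized geometric mean of subjective (AHP) and objective (entropy)
    weights: w_j = sqrt(w1_j w2_j) / sum_k sqrt(w1_k w2_k)."""
    if len(w_subjective) != len(w_objective):
        raise ValueError("weight vectors differ in length")
    if set(w_subjective.index) != set(w_objective.index):
        raise ValueError("weight vectors are over different indicators")
    w2 = w_objective.reindex(w_subjective.index)
    g = np.sqrt(w_subjective.to_numpy(float) * w2.to_numpy(float))
    return pd.Series(g / g.sum(), index=w_subjective.index, name="combined_weight")


@dataclass
class WeightSet:
    """Subjective (AHP), objective (entropy) and combined weights over the
    indicator layer, plus the AHP hierarchy pieces and consistency reports."""

    subjective: pd.Series
    objective: pd.Series
    combined: pd.Series
    first_level: dict[str, float]
    group_weights: dict[str, dict[str, float]]
    consistency: dict[str, ConsistencyReport]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ahp": self.subjective,
                "entropy": self.objective,
                "combined": self.combined,
            }
        )


def build_weight_set(
    matrices: Mapping[str, JudgmentMatrix],
    standardized_panel: pd.DataFrame,
    indicator_groups: Mapping[str, Sequence[str]],
    primary_key: str = "primary",
) -> WeightSet:
    """Full AHP-entropy weighting over an indicator panel.

    ``matrices`` holds the first-level matrix under ``primary_key`` (labels =
    rule-layer names) and one within-group matrix per rule layer.
    ``indicator_groups`` maps each rule layer to the panel column names its
    matrix rows correspond to, in row order.
    """
    reports: dict[str, ConsistencyReport] = {}
    prim = matrices[primary_key]
    w_first, rep = ahp_weights(prim)
    reports[primary_key] = rep
    first_level = dict(zip(prim.labels, w_first))

    groups: dict[str, dict[str, float]] = {}
    for layer in prim.labels:
        gm = matrices[layer]
        cols = list(indicator_groups[layer])
        if len(cols) != gm.order:
            raise ValueError(
                f"group {layer!r}: matrix order {gm.order} != {len(cols)} indicators"
            )
        gw, rep = ahp_weights(gm)
        reports[layer] = rep
        groups[layer] = dict(zip(cols, gw))

    absolute = compose_hierarchy(first_level, groups)
    subjective = pd.Series(absolute).reindex(standardized_panel.columns)
    if subjective.isna().any():
        missing = list(subjective.index[subjective.isna()])
        raise ValueError(f"panel columns without AHP weight: {missing}")

    ent = entropy_weights(standardized_panel)
    combined = combine_weights(subjective, ent.weights)
    return WeightSet(
        subjective=subjective,
        objective=ent.weights.reindex(subjective.index),
        combined=combined,
        first_level=first_level,
        group_weights=groups,
        consistency=reports,
    )


def composite_score(weights: pd.Series, standardized_panel: pd.DataFrame) -> pd.DataFrame:
    """Composite score z_i = sum_j w_j x_ij per evaluation object.

    Returns a frame with per-indicator contributions and the total ``z``;
    z lies in [0, 1] whenever all standardized values do and weights sum
    to 1.
    """
    missing = set(standardized_panel.columns) ^ set(weights.index)
    if missing:
        raise ValueError(f"weights and panel indicators differ: {sorted(missing)}")
    w = weights.reindex(standardized_panel.columns)
    contrib = standardized_panel.mul(w, axis=1)
    out = contrib.copy()
    out["z"] = contrib.sum(axis=1)
    return out
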