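"""Spatio-temporal trajectory coding and change-type classification.

A unit observed in q > 1 time phases with class states P_1..P_q (integers
1-9; the tolerance analysis uses 1-5) gets the base-10 positional code

    C = P_1 * 10^(q-1) + P_2 * 10^(q-2) + ... + P_q,

so the decimal digits of C read off the state sequence.  The shape of the
sequence is summarized into five change types by taking successive
differences, dropping zeros (plateaus), and collapsing equal-sign runs:

    empty pattern      -> no_change
    (-, +)             -> decline_rise
    (-, +, -)          -> decline_rise_decline
    (+, -, +)          -> rise_decline_rise
    anything else      -> complex   (including purely monotone sequences)

The classification depends only on the ordering of states, so any strictly
increasing relabeling preserves the type.
"""

from __future__ import annotations

from collections import Counter
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd


class ChangeType(str, Enum):
    NO_CHANGE = "no_change"
    DECLINE_RISE = "decline_rise"
    DECLINE_RISE_DECLINE = "decline_rise_decline"
    RISE_DECLINE_RISE = "rise_decline_rise"
    COMPLEX = "complex"


def _check_states(states: Sequence[int]) -> None:
    if len(states) < 2:
        raise ValueError(f"need q > 1 time phases, got {len(states)}")
    for s in states:
        if not isinstance(s, (int,)) or isinstance(s, bool) or not (1 <= s <= 9):
            raise ValueError(f"states must be integers in 1..9, got {s!r}")


def encode(states: Sequence[int]) -> int:
    """Positional base-10 trajectory code of a state sequence."""
    _check_states(states)
    code = 0
    for s in states:
        code = code * 10 + s
    return code


def encode_str(states: Sequence[int]) -> str:
    """Digit-string form of the code (overflow-proof for very long series)."""
    _check_states(states)
    return "".join(str(s) for s in states)


def decode(code: int | str, q: int) -> tuple[int, ...]:
    """Invert :func:`encode`: split a q-digit code into its states.

    The code must have exactly q decimal digits, none of them zero (states
    start at 1, so a zero digit cannot arise from a valid sequence).
    """
    s = str(int(code))
    if len(s) != q:
        raise ValueError(f"code {code} has {len(s)} digits, expected q={q}")
    if "0" in s:
        raise ValueError(f"code {code} contains a zero digit; states start at 1")
    return tuple(int(ch) for ch in s)


def classify_change_type(states: Sequence[int | float | None]) -> ChangeType | None:
    """Five-way shape classification of a class-state sequence.

    Missing states (None/NaN) make the whole type missing (returns None).
    """
    seq = list(states)
    if len(seq) < 2:
        raise ValueError("need q > 1 time phases")
    clean: list[float] = []
    for s in seq:
        if s is None or (isinstance(s, float) and s != s):
            return None
        clean.append(float(s))
    signs = []
    for a, b in zip(clean, clean[1:]):
        d = b - a
        if d == 0:
            continue
        sg = 1 if d > 0 else -1
        if not signs or signs[-1] != sg:
            signs.append(sg)
    pattern = tuple(signs)
    if pattern == ():
        return ChangeType.NO_CHANGE
    if pattern == (-1, 1):
        return ChangeType.DECLINE_RISE
    if pattern == (-1, 1, -1):
        return ChangeType.DECLINE_RISE_DECLINE
    if pattern == (1, -1, 1):
        return ChangeType.RISE_DECLINE_RISE
    return ChangeType.COMPLEX


def trajectory_table(
    sequences: Mapping[str, Sequence[int | None]],
) -> tuple[pd.DataFrame, dict]:
    """Per-unit codes and change types, plus a frequency summary.

    All units must share the same number of phases q.  Units with any
    missing state get no code and a missing change type; they are excluded
    from the summary counts but listed under ``summary['units_missing']``.
    The summary reports both the number of distinct codes and the number of
    distinct collapsed sign patterns (via the type counts).
    """
    lengths = {len(v) for v in sequences.values()}
    if len(lengths) > 1:
        raise ValueError(f"ragged sequences: lengths {sorted(lengths)}")
    rows = []
    missing_units = []
    for unit, states in sequences.items():
        has_missing = any(
            s is None or (isinstance(s, float) and s != s) for s in states
        )
        if has_missing:
            missing_units.append(unit)
            rows.append({"unit": unit, "code": None, "change_type": None})
            continue
        ints = [int(s) for s in states]
        rows.append(
            {
                "unit": unit,
                "code": encode_str(ints),
                "change_type": classify_change_type(ints).value,
            }
        )
    df = pd.DataFrame(rows)
    complete = df.dropna(subset=["code"])
    type_counts = Counter(complete["change_type"])
    summary = {
        "n_units": len(df),
        "n_complete": len(complete),
        "units_missing": missing_units,
        "n_distinct_codes": complete["code"].nunique(),
        "type_counts": {t.value: type_counts.get(t.value, 0) for t in ChangeType},
    }
    return df, summary
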