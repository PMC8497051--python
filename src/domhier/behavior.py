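"""Behavioral stress-outcome measures.

Four measures from chronic-stress paradigms in mice:

* **Social-interaction (SI) ratio** — time in the interaction zone with a
  social target present divided by time with the target absent. Stressed
  animals that avoid the target score below 1 and are classified
  susceptible; a ratio of 1 or above is resilient.
* **Active-coping score** — (escapes + fighting back - passive events)
  per attack bout received during defeat; +1 means every attack met an
  active response, -1 means all-passive responding.
* **Wound score** — 0-12 point sum over four body regions (lower back by
  wound area, upper back / tail / abdomen by discrete wound count), each
  region contributing 0-3 points.
* **Vigilance** — seconds spent oriented toward the aggressor while
  outside the interaction zone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SUSCEPTIBLE = "susceptible"
RESILIENT = "resilient"


@dataclass(frozen=True)
class SocialInteractionMeasure:
    time_present: float
    time_absent: float
    si_ratio: float
    outcome: str


@dataclass(frozen=True)
class VigilanceMeasure:
    vigilance_s: float


class UndefinedScoreError(ValueError):
    """A score's denominator is zero; no value is imputed."""


def si_ratio(time_present: float, time_absent: float) -> SocialInteractionMeasure:
    """Social-interaction ratio and susceptibility classification.

    Susceptibility is strictly below 1 (equal times sit exactly on the
    boundary and classify resilient). Zero target-absent time leaves the
    ratio undefined and raises rather than capping.
    """
    if time_present < 0 or time_absent < 0:
        raise ValueError("interaction-zone times must be non-negative")
    if time_absent == 0:
        raise UndefinedScoreError(
            "SI ratio undefined: no time recorded with target absent"
        )
    ratio = time_present / time_absent
    outcome = SUSCEPTIBLE if ratio < 1 else RESILIENT
    return SocialInteractionMeasure(
        time_present=time_present, time_absent=time_absent,
        si_ratio=ratio, outcome=outcome,
    )


def coping_score(
    n_escape: int, n_fight: int, n_passive: int, n_attacks: int
) -> float:
    """Active-coping score: (escape + fight - passive) / attacks.

    The full active-minus-passive tally is normalized by the number of
    attack bouts received, so an all-passive animal scores -1 and an
    animal answering every attack actively scores +1 (exceeding those
    bounds is possible if multiple responses follow one bout).
    """
    for name, v in (
        ("n_escape", n_escape), ("n_fight", n_fight),
        ("n_passive", n_passive), ("n_attacks", n_attacks),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if n_attacks == 0:
        raise UndefinedScoreError("coping score undefined: no attacks received")
    return (n_escape + n_fight - n_passive) / n_attacks


def _area_points(area_cm2: float) -> int:
    # bins lower-inclusive / upper-exclusive; below 0.01 cm^2 scores 0
    if area_cm2 < 0:
        raise ValueError("wound area must be non-negative")
    if area_cm2 < 0.01:
        return 0
    if area_cm2 < 1:
        return 1
    if area_cm2 < 2:
        return 2
    return 3


def _count_points(count: int) -> int:
    if count < 0:
        raise ValueError("wound count must be non-negative")
    if count == 0:
        return 0
    if count < 5:
        return 1
    if count < 10:
        return 2
    return 3


def wound_score(
    lower_back_area: float,
    upper_back_wounds: int,
    tail_wounds: int,
    abdominal_wounds: int,
) -> int:
    """Wound score: 0-3 points per region summed over four regions (max 12).

    The lower back is binned by wound area (0.01-1 cm2 = 1, 1-2 cm2 = 2,
    2+ cm2 = 3); the other regions by discrete wound count (1-5 = 1,
    5-10 = 2, 10+ = 3). Shared bin boundaries are lower-inclusive /
    upper-exclusive, so counts bin as [1,5), [5,10), [10, inf).
    """
    return (
        _area_points(lower_back_area)
        + _count_points(upper_back_wounds)
        + _count_points(tail_wounds)
        + _count_points(abdominal_wounds)
    )


def vigilance_time(
    events: Iterable[Sequence],
    trial_duration_s: float | None = None,
) -> VigilanceMeasure:
    """Total vigilance from scored intervals.

    ``events`` holds ``(start_s, stop_s, oriented_to_aggressor,
    in_interaction_zone)`` tuples; intervals must be non-overlapping and,
    when a trial duration is given, inside ``[0, duration]``. Only time
    both oriented toward the aggressor and *outside* the interaction zone
    counts.
    """
    events = sorted(events, key=lambda e: e[0])
    total = 0.0
    prev_stop = None
    for start, stop, oriented, in_zone in events:
        if stop <= start:
            raise ValueError(f"interval ({start}, {stop}) has non-positive duration")
        if start < 0 or (trial_duration_s is not None and stop > trial_duration_s):
            raise ValueError(f"interval ({start}, {stop}) outside the trial")
        if prev_stop is not None and start < prev_stop:
            raise ValueError(f"interval starting at {start} overlaps the previous one")
        prev_stop = stop
        if oriented and not in_zone:
            total += stop - start
    return VigilanceMeasure(vigilance_s=total)


def score_behavior_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add derived score columns to a behavior table.

    Adds ``si_ratio`` + ``outcome`` where both interaction-zone times are
    present, ``coping_score`` where the coping counts are present, and
    ``wound_score`` where the wound observations are present. Rows with
    missing inputs get NaN, not errors — a table mixes assays.
    """
    df = df.copy()
    if {"time_target_present", "time_target_absent"} <= set(df.columns):
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = df["time_target_present"] / df["time_target_absent"]
        ratio[df["time_target_absent"] <= 0] = np.nan
        df["si_ratio"] = ratio
        df["outcome"] = np.where(
            ratio.isna(), None, np.where(ratio < 1, SUSCEPTIBLE, RESILIENT)
        )
    coping_cols = {"n_escape", "n_fight", "n_passive", "n_attacks"}
    if coping_cols <= set(df.columns):
        with np.errstate(invalid="ignore", divide="ignore"):
            cs = (df["n_escape"] + df["n_fight"] - df["n_passive"]) / df["n_attacks"]
        cs[df["n_attacks"] <= 0] = np.nan
        df["coping_score"] = cs
    wound_cols = {"lower_back_area", "upper_back_wounds", "tail_wounds", "abdominal_wounds"}
    if wound_cols <= set(df.columns):
        scores = []
        for row in df.itertuples():
            vals = (row.lower_back_area, row.upper_back_wounds,
                    row.tail_wounds, row.abdominal_wounds)
            if any(pd.isna(v) for v in vals):
                scores.append(np.nan)
            else:
                scores.append(wound_score(vals[0], int(vals[1]), int(vals[2]), int(vals[3])))
        df["wound_score"] = scores
    return df
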