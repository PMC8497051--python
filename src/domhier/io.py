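"""Contest-ledger, behavior-table, and run-configuration I/O.

The primitive record is one tube-test contest: on a given study day, two
cagemates met in the tube and one of them retreated (the loser). A ledger
is long-format delimited text, one contest per row, with the header
``day,cage,animal_a,animal_b,winner``. Ties are unrepresentable: the
assay always yields a winner, and a retried trial is logged once as its
final outcome.

Validation is strict and names the offending row: the winner must be one
of the two contestants, an animal cannot meet itself, an unordered pair
may appear at most once per cage-day (round-robin sessions), and an
animal tag belongs to exactly one cage for the life of a housing epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from domhier.hierarchy import WinMatrix

LEDGER_COLUMNS = ("day", "cage", "animal_a", "animal_b", "winner")

#: Behavior-table columns. Only cage/animal are required; measures are
#: optional and may be empty, but any animal entering group statistics
#: needs stress_condition.
BEHAVIOR_REQUIRED = ("cage", "animal")
BEHAVIOR_TIME_COLUMNS = (
    "time_target_present",
    "time_target_absent",
    "distance_target_absent",
    "vigilance_s",
    "warm_corner_s",
)
BEHAVIOR_COUNT_COLUMNS = (
    "n_escape",
    "n_fight",
    "n_passive",
    "n_attacks",
    "upper_back_wounds",
    "tail_wounds",
    "abdominal_wounds",
)
STRESS_CONDITIONS = ("CTRL", "STRESS")


class LedgerValidationError(ValueError):
    """Base class for contest-ledger validation failures."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class MissingColumnError(LedgerValidationError):
    pass


class WinnerNotContestantError(LedgerValidationError):
    pass


class SelfContestError(LedgerValidationError):
    pass


class DuplicatePairError(LedgerValidationError):
    pass


class CrossCageError(LedgerValidationError):
    pass


@dataclass(frozen=True)
class ContestRecord:
    """One tube-test contest: the loser retreated, the winner held the tube."""

    day: int
    cage: str
    animal_a: str
    animal_b: str
    winner: str


class ContestLedger:
    """Validated, ordered collection of contest records.

    Wraps a DataFrame with the ledger columns; row order is preserved
    from the source. Animal tags are treated as study-unique, so an
    animal appearing under two cages is a validation error (cage
    membership is fixed within a housing epoch).
    """

    def __init__(self, df: pd.DataFrame):
        self.df = self._validate(df)

    # -- construction ------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[ContestRecord]) -> "ContestLedger":
        df = pd.DataFrame(
            [(r.day, r.cage, r.animal_a, r.animal_b, r.winner) for r in records],
            columns=list(LEDGER_COLUMNS),
        )
        return cls(df)

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        for col in LEDGER_COLUMNS:
            if col not in df.columns:
                raise MissingColumnError(f"ledger is missing column {col!r}")
        df = df.loc[:, list(LEDGER_COLUMNS)].copy()
        df["day"] = pd.to_numeric(df["day"], errors="raise").astype(int)
        if (df["day"] < 1).any():
            bad = int(df.index[df["day"] < 1][0])
            raise LedgerValidationError("study days are 1-based", row=bad)
        for col in ("cage", "animal_a", "animal_b", "winner"):
            df[col] = df[col].astype(str)
        df = df.reset_index(drop=True)

        cage_of: dict[str, str] = {}
        seen: set[tuple[str, int, frozenset]] = set()
        for row in df.itertuples():
            i = row.Index
            if row.animal_a == row.animal_b:
                raise SelfContestError(
                    f"animal {row.animal_a!r} contests itself", row=i
                )
            if row.winner not in (row.animal_a, row.animal_b):
                raise WinnerNotContestantError(
                    f"winner {row.winner!r} is not a contestant "
                    f"({row.animal_a!r} vs {row.animal_b!r})",
                    row=i,
                )
            for tag in (row.animal_a, row.animal_b):
                prev = cage_of.setdefault(tag, row.cage)
                if prev != row.cage:
                    raise CrossCageError(
                        f"animal {tag!r} appears in cage {row.cage!r} "
                        f"but belongs to cage {prev!r}",
                        row=i,
                    )
            key = (row.cage, row.day, frozenset((row.animal_a, row.animal_b)))
            if key in seen:
                raise DuplicatePairError(
                    f"pair ({row.animal_a!r}, {row.animal_b!r}) already "
                    f"contested in cage {row.cage!r} on day {row.day}",
                    row=i,
                )
            seen.add(key)
        return df

    # -- views -------------------------------------------------------

    @property
    def sessions(self) -> list[int]:
        """Sorted distinct study days across the whole ledger."""
        return sorted(self.df["day"].unique().tolist())

    @property
    def cages(self) -> list[str]:
        return sorted(self.df["cage"].unique().tolist())

    def sessions_for(self, cage: str) -> list[int]:
        sub = self.df[self.df["cage"] == cage]
        if sub.empty:
            raise KeyError(f"cage {cage!r} not in ledger")
        return sorted(sub["day"].unique().tolist())

    def animals(self, cage: str) -> list[str]:
        sub = self.df[self.df["cage"] == cage]
        if sub.empty:
            raise KeyError(f"cage {cage!r} not in ledger")
        return sorted(set(sub["animal_a"]) | set(sub["animal_b"]))

    def group_size(self, cage: str) -> int:
        return len(self.animals(cage))

    def subset(self, cage: str | None = None, days: Sequence[int] | None = None) -> pd.DataFrame:
        out = self.df
        if cage is not None:
            out = out[out["cage"] == cage]
        if days is not None:
            out = out[out["day"].isin(list(days))]
        return out

    @property
    def records(self) -> list[ContestRecord]:
        return [
            ContestRecord(r.day, r.cage, r.animal_a, r.animal_b, r.winner)
            for r in self.df.itertuples()
        ]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContestLedger):
            return NotImplemented
        return self.df.equals(other.df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def load_contests(path: str | Path) -> ContestLedger:
    """Read and validate a contest ledger CSV (header required, UTF-8)."""
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    return ContestLedger(df)


def write_contests(ledger: ContestLedger, path: str | Path) -> None:
    """Write a ledger back to CSV; a round trip reproduces identical records."""
    ledger.to_csv(path)


def build_win_matrix(
    ledger: ContestLedger, cage: str, window: Sequence[int]
) -> WinMatrix:
    """Aggregate pairwise win counts for one cage over a set of session days.

    ``wins[i, j]`` counts contests in the window where animal ``i`` beat
    ``j``; animals are ordered by sorted tag for determinism.
    """
    window = sorted(set(int(d) for d in window))
    if not window:
        raise ValueError("window must contain at least one session day")
    sessions = set(ledger.sessions_for(cage))  # raises KeyError if cage absent
    missing = [d for d in window if d not in sessions]
    if missing:
        raise ValueError(f"cage {cage!r} has no contests on day(s) {missing}")
    animals = ledger.animals(cage)
    index = {a: i for i, a in enumerate(animals)}
    wins = np.zeros((len(animals), len(animals)), dtype=float)
    for row in ledger.subset(cage=cage, days=window).itertuples():
        loser = row.animal_b if row.winner == row.animal_a else row.animal_a
        wins[index[row.winner], index[loser]] += 1
    return WinMatrix(animals=animals, wins=wins, cage=cage, window=tuple(window))


# -- behavior tables -------------------------------------------------


def load_behavior(path: str | Path) -> pd.DataFrame:
    """Read a behavior-measurement table CSV keyed by cage+animal.

    Optional measures may be blank; times and counts must be non-negative
    where present, and ``stress_condition`` (CTRL/STRESS) must be valid
    where present.
    """
    df = pd.read_csv(path, encoding="utf-8")
    return validate_behavior(df)


def validate_behavior(df: pd.DataFrame) -> pd.DataFrame:
    for col in BEHAVIOR_REQUIRED:
        if col not in df.columns:
            raise MissingColumnError(f"behavior table is missing column {col!r}")
    df = df.copy()
    df["cage"] = df["cage"].astype(str)
    df["animal"] = df["animal"].astype(str)
    dup = df.duplicated(subset=["cage", "animal"])
    if dup.any():
        raise LedgerValidationError(
            "duplicate cage+animal key in behavior table", row=int(df.index[dup][0])
        )
    for col in BEHAVIOR_TIME_COLUMNS + BEHAVIOR_COUNT_COLUMNS + ("lower_back_area",):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="raise")
            if (vals.dropna() < 0).any():
                bad = int(df.index[vals < 0][0])
                raise LedgerValidationError(f"negative value in {col!r}", row=bad)
            df[col] = vals
    if "stress_condition" in df.columns:
        bad_mask = ~df["stress_condition"].isin(STRESS_CONDITIONS) & df[
            "stress_condition"
        ].notna()
        if bad_mask.any():
            raise LedgerValidationError(
                f"stress_condition must be one of {STRESS_CONDITIONS}",
                row=int(df.index[bad_mask][0]),
            )
    return df


# -- run configuration ------------------------------------------------


class RunConfig(BaseModel):
    """Analysis configuration.

    Windows are counts of tube-test sessions, anchored to a named event
    day (typically stress start): rank uses the 4 sessions preceding it
    (spanning 8 days at the every-other-day cadence), steepness uses 7
    sessions (2 weeks), stability the final 4. Rank-class cutoffs carve
    the attainable tetrad DS range [-6, 6] into quartiles at +3/-3.
    """

    model_config = ConfigDict(extra="forbid")

    ds_window_sessions: int = Field(default=4, ge=1)
    steepness_window_sessions: int = Field(default=7, ge=1)
    stability_window_sessions: int = Field(default=4, ge=1)
    dom_cutoff: float = 3.0
    sub_cutoff: float = -3.0
    mobility_threshold: int = Field(default=2, ge=1)
    outlier_sd: float = Field(default=2.0, gt=0)
    stability_criterion: str = "outcomes"
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check_cutoffs(self) -> "RunConfig":
        if self.dom_cutoff <= self.sub_cutoff:
            raise ValueError("dom_cutoff must exceed sub_cutoff")
        if self.stability_criterion not in ("outcomes", "ranks"):
            raise ValueError("stability_criterion must be 'outcomes' or 'ranks'")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig JSON document; unknown keys are rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return RunConfig(**payload)
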