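"""Rank inference from pairwise contest outcomes.

All hierarchy descriptors live here: David's Scores over a session window,
normalized scores and quartile rank classes, per-day standings with the
tournament-linearity flag, stability of the final sessions, hierarchy
steepness, day-to-day rank mobility, and rank-trajectory summaries.

David's Score for animal *i* in a group of *N* uses the win proportions
``P_ij = wins_ij / (wins_ij + wins_ji)``:

    w_i  = sum_j P_ij            (win proportions)
    w2_i = sum_j P_ij * w_j      (wins weighted by opponent strength)
    l_i  = sum_j P_ji            (loss proportions)
    l2_i = sum_j P_ji * l_j      (losses weighted by opponent weakness)
    DS_i = w_i + w2_i - l_i - l2_i

Raw proportions are used (no dyadic chance correction), so for a tetrad
with every pair contested DS spans exactly [-6, 6], attained by an animal
that wins (or loses) every contest in a unanimous linear hierarchy. The
normalized score ``NormDS_i = DS_i / N + (N - 1) / 2`` lies in
``[0, N - 1]`` and is the quantity regressed on ordinal rank to obtain
hierarchy steepness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from domhier.io import ContestLedger, RunConfig

DOM = "DOM"
INT = "INT"
SUB = "SUB"
LOW = "LOW"
HIGH = "HIGH"
UNDEFINED = "UNDEFINED"

DEFAULT_DOM_CUTOFF = 3.0
DEFAULT_SUB_CUTOFF = -3.0


class IncompleteDyadError(ValueError):
    """A pair of animals has no contests in the requested window."""


class IncompleteRoundRobinError(ValueError):
    """A session is missing contests for one or more pairs."""


class TooFewSessionsError(ValueError):
    """Fewer sessions available than the analysis window requires."""


@dataclass
class WinMatrix:
    """Pairwise win counts aggregated over a session window.

    Attributes
    ----------
    animals
        Ordered animal tags; matrix axes follow this order.
    wins
        ``wins[i, j]`` = contests in the window where ``i`` beat ``j``.
    cage, window
        Provenance of the aggregation (optional).
    """

    animals: list[str]
    wins: np.ndarray
    cage: str | None = None
    window: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.wins = np.asarray(self.wins, dtype=float)
        n_animals = len(self.animals)
        if self.wins.shape != (n_animals, n_animals):
            raise ValueError(
                f"wins matrix shape {self.wins.shape} does not match "
                f"{n_animals} animals"
            )
        if (self.wins < 0).any():
            raise ValueError("win counts must be non-negative")
        if np.diag(self.wins).any():
            raise ValueError("diagonal of the wins matrix must be zero")

    @property
    def n(self) -> np.ndarray:
        """Contest counts per ordered pair: ``n[i, j] = wins[i, j] + wins[j, i]``."""
        return self.wins + self.wins.T

    @property
    def P(self) -> np.ndarray:
        """Win proportions; NaN where a pair was never contested."""
        n = self.n
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, self.wins / np.where(n > 0, n, 1), np.nan)
        np.fill_diagonal(p, np.nan)
        return p

    @property
    def size(self) -> int:
        return len(self.animals)


@dataclass
class DailyStanding:
    """Win tally and rank order for one complete round-robin session."""

    day: int
    animals: list[str]
    win_count: dict[str, int]
    linear: bool
    #: 1 = most wins; None for every animal on non-linear (tied) days.
    rank_position: dict[str, int | None] = field(default_factory=dict)


@dataclass
class StabilityReport:
    cage: str
    stable: bool
    window: tuple[int, ...]
    criterion: str = "outcomes"


@dataclass
class SteepnessResult:
    cage: str
    slope_magnitude: float
    window: tuple[int, ...]


@dataclass
class MobilityReport:
    animal: str
    n_rank_changes: int
    mobility_class: str  # LOW / HIGH / UNDEFINED
    n_linear_days: int = 0


def davids_scores(wm: WinMatrix) -> pd.DataFrame:
    """Compute David's Scores for every animal in a win matrix.

    Requires every pair to have at least one contest (guaranteed for
    round-robin windows); a silent imputation of un-contested pairs would
    bias the opponent-weighted terms, so the gap is an error instead.

    Returns a DataFrame indexed by animal (input order preserved) with
    columns ``w, w2, l, l2, ds, norm_ds``.
    """
    n_mat = wm.n
    n_animals = wm.size
    off_diag = ~np.eye(n_animals, dtype=bool)
    missing = (n_mat == 0) & off_diag
    if missing.any():
        i, j = np.argwhere(missing)[0]
        raise IncompleteDyadError(
            f"pair ({wm.animals[i]}, {wm.animals[j]}) has no contests in the window"
        )
    p = wm.P.copy()
    np.fill_diagonal(p, 0.0)
    w = p.sum(axis=1)
    w2 = p @ w
    l = p.sum(axis=0)
    l2 = p.T @ l
    ds = w + w2 - l - l2
    norm_ds = ds / n_animals + (n_animals - 1) / 2.0
    return pd.DataFrame(
        {"w": w, "w2": w2, "l": l, "l2": l2, "ds": ds, "norm_ds": norm_ds},
        index=pd.Index(wm.animals, name="animal"),
    )


def classify_rank(
    ds: float,
    dom_cutoff: float = DEFAULT_DOM_CUTOFF,
    sub_cutoff: float = DEFAULT_SUB_CUTOFF,
) -> str:
    """Quartile rank class from a David's Score.

    The attainable tetrad DS range [-6, 6] is divided into quarters:
    dominant above ``dom_cutoff`` (strictly), subordinate below
    ``sub_cutoff`` (strictly), intermediate otherwise — so the boundary
    values themselves are intermediate.
    """
    if dom_cutoff <= sub_cutoff:
        raise ValueError("dom_cutoff must exceed sub_cutoff")
    if ds > dom_cutoff:
        return DOM
    if ds < sub_cutoff:
        return SUB
    return INT


def classify_ranks(
    ds: Sequence[float] | pd.Series,
    dom_cutoff: float = DEFAULT_DOM_CUTOFF,
    sub_cutoff: float = DEFAULT_SUB_CUTOFF,
) -> pd.Series:
    """Vectorized :func:`classify_rank`."""
    ds = pd.Series(ds)
    out = pd.Series(INT, index=ds.index, dtype=object)
    out[ds > dom_cutoff] = DOM
    out[ds < sub_cutoff] = SUB
    return out


def _day_outcomes(day_df: pd.DataFrame) -> dict[frozenset, str]:
    """Winner per unordered pair for one cage-day."""
    return {
        frozenset((row.animal_a, row.animal_b)): row.winner
        for row in day_df.itertuples()
    }


def _require_complete(day_df: pd.DataFrame, animals: Sequence[str], cage: str, day: int) -> None:
    expected = {frozenset(p) for p in _all_pairs(animals)}
    got = {frozenset((r.animal_a, r.animal_b)) for r in day_df.itertuples()}
    if got != expected:
        missing = expected - got
        raise IncompleteRoundRobinError(
            f"cage {cage!r} day {day}: incomplete round robin "
            f"({len(missing)} missing pair(s))"
        )


def _all_pairs(animals: Sequence[str]) -> Iterable[tuple[str, str]]:
    for i, a in enumerate(animals):
        for b in animals[i + 1 :]:
            yield a, b


def daily_standings(ledger: "ContestLedger", cage: str, day: int) -> DailyStanding:
    """Win counts, linearity flag, and (when linear) rank order for one session.

    A day is linear (fully transitive) exactly when the win counts are a
    permutation of {0, ..., N-1}; on non-linear days rank positions are
    left undefined rather than tie-broken.
    """
    animals = ledger.animals(cage)
    day_df = ledger.subset(cage=cage, days=[day])
    if day_df.empty:
        raise IncompleteRoundRobinError(f"cage {cage!r} has no contests on day {day}")
    _require_complete(day_df, animals, cage, day)
    counts = {a: 0 for a in animals}
    for row in day_df.itertuples():
        counts[row.winner] += 1
    linear = sorted(counts.values()) == list(range(len(animals)))
    if linear:
        order = sorted(animals, key=lambda a: -counts[a])
        positions: dict[str, int | None] = {a: i + 1 for i, a in enumerate(order)}
    else:
        positions = {a: None for a in animals}
    return DailyStanding(
        day=day, animals=list(animals), win_count=counts, linear=linear,
        rank_position=positions,
    )


def all_standings(
    ledger: "ContestLedger", cage: str, days: Sequence[int] | None = None
) -> list[DailyStanding]:
    """Daily standings for every (or the given) session of a cage."""
    if days is None:
        days = ledger.sessions_for(cage)
    return [daily_standings(ledger, cage, d) for d in days]


def is_transitive(standing_or_wins: DailyStanding | np.ndarray) -> bool:
    """Whether a single complete round-robin day is fully transitive.

    Uses the score-sequence criterion: a complete single-day tournament
    contains no directed 3-cycle exactly when its win counts are a
    permutation of {0, ..., N-1}.

    Accepts a :class:`DailyStanding` or a 0/1 single-day wins matrix.
    """
    if isinstance(standing_or_wins, DailyStanding):
        counts = sorted(standing_or_wins.win_count.values())
        return counts == list(range(len(counts)))
    wins = np.asarray(standing_or_wins)
    n = wins.shape[0]
    if wins.shape != (n, n):
        raise ValueError("wins matrix must be square")
    off = ~np.eye(n, dtype=bool)
    if not np.array_equal((wins + wins.T)[off], np.ones(n * n - n)):
        raise IncompleteRoundRobinError(
            "single-day wins matrix must have exactly one contest per pair"
        )
    return sorted(wins.sum(axis=1)) == list(range(n))


def stability(
    ledger: "ContestLedger",
    cage: str,
    window_sessions: int = 4,
    criterion: str = "outcomes",
) -> StabilityReport:
    """Whether the final sessions of a cage repeat identically.

    A cage is stable when its last ``window_sessions`` consecutive sessions
    produced identical results. Under the default ``criterion="outcomes"``
    the full pairwise outcome set (winner of every pair) must repeat, which
    is well defined even on non-linear days. ``criterion="ranks"`` instead
    requires every window day to be linear with an identical rank ordering.
    """
    if window_sessions < 1:
        raise ValueError("window_sessions must be >= 1")
    if criterion not in ("outcomes", "ranks"):
        raise ValueError(f"unknown stability criterion {criterion!r}")
    sessions = ledger.sessions_for(cage)
    if len(sessions) < window_sessions:
        raise TooFewSessionsError(
            f"cage {cage!r} has {len(sessions)} sessions; "
            f"stability window needs {window_sessions}"
        )
    window = tuple(sessions[-window_sessions:])
    animals = ledger.animals(cage)
    if criterion == "outcomes":
        outcome_sets = []
        for day in window:
            day_df = ledger.subset(cage=cage, days=[day])
            _require_complete(day_df, animals, cage, day)
            outcome_sets.append(_day_outcomes(day_df))
        stable = all(o == outcome_sets[0] for o in outcome_sets[1:])
    else:
        standings = [daily_standings(ledger, cage, d) for d in window]
        stable = all(s.linear for s in standings) and all(
            s.rank_position == standings[0].rank_position for s in standings[1:]
        )
    return StabilityReport(cage=cage, stable=stable, window=window, criterion=criterion)


def steepness(
    ledger: "ContestLedger",
    cage: str,
    window: Sequence[int] | None = None,
    window_sessions: int = 7,
) -> SteepnessResult:
    """Hierarchy steepness over a session window.

    David's Scores are computed over the window, normalized scores are
    ordered descending, and the magnitude of the ordinary least-squares
    slope against ordinal position 1..N is reported. 1 means a perfectly
    despotic linear hierarchy, 0 a flat one.
    """
    sessions = ledger.sessions_for(cage)
    if window is None:
        if len(sessions) < window_sessions:
            raise TooFewSessionsError(
                f"cage {cage!r} has {len(sessions)} sessions; "
                f"steepness window needs {window_sessions}"
            )
        window = sessions[-window_sessions:]
    window = tuple(sorted(window))
    from domhier.io import build_win_matrix

    wm = build_win_matrix(ledger, cage, window)
    norm = np.sort(davids_scores(wm)["norm_ds"].to_numpy())[::-1]
    positions = np.arange(1, len(norm) + 1, dtype=float)
    slope = np.polyfit(positions, norm, 1)[0]
    # |slope| <= 1 analytically (norm_ds is bounded in [0, N-1]); clamp
    # the few-ulp excess polyfit can introduce at the despotic extreme
    magnitude = min(float(abs(slope)), 1.0)
    return SteepnessResult(cage=cage, slope_magnitude=magnitude, window=window)


def mobility(
    standings: Sequence[DailyStanding],
    animal: str,
    threshold: int = 2,
) -> MobilityReport:
    """Rank mobility of one animal across a sequence of daily standings.

    Non-linear days carry no rank order and are skipped entirely; a rank
    change is counted for each consecutive pair of *linear* days on which
    the animal's position differs. LOW means fewer changes than
    ``threshold`` (default: one or fewer), HIGH means at least
    ``threshold``. With fewer than two linear days mobility is undefined
    and flagged as such, never silently LOW.
    """
    positions = [
        s.rank_position[animal]
        for s in sorted(standings, key=lambda s: s.day)
        if s.linear
    ]
    if len(positions) < 2:
        return MobilityReport(
            animal=animal, n_rank_changes=0, mobility_class=UNDEFINED,
            n_linear_days=len(positions),
        )
    changes = sum(1 for a, b in zip(positions, positions[1:]) if a != b)
    cls = HIGH if changes >= threshold else LOW
    return MobilityReport(
        animal=animal, n_rank_changes=changes, mobility_class=cls,
        n_linear_days=len(positions),
    )


def _ordinal_ranks(df: pd.DataFrame) -> pd.Series:
    """Within-cage ordinal rank by descending DS (1 = highest)."""
    return df.groupby("cage")["ds"].rank(ascending=False, method="min").astype(int)


def rank_change_fraction(pre: pd.DataFrame, post: pd.DataFrame) -> float:
    """Fraction of animals whose within-cage DS ordinal differs between windows.

    Both frames need columns ``cage, animal, ds`` and must cover the same
    animals.
    """
    pre = pre.set_index(["cage", "animal"]) if "animal" in pre.columns else pre
    post = post.set_index(["cage", "animal"]) if "animal" in post.columns else post
    if set(pre.index) != set(post.index):
        raise ValueError("pre and post windows cover different animal sets")
    pre = pre.sort_index().reset_index()
    post = post.sort_index().reset_index()
    changed = (_ordinal_ranks(pre) != _ordinal_ranks(post)).sum()
    return float(changed) / len(pre)


def avg_wins_by_rank_trajectory(
    ledger: "ContestLedger",
    assignments: pd.DataFrame,
    days: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Mean daily win count per rank class across all sessions.

    ``assignments`` holds the reference-window classes (columns
    ``cage, animal, rank_class``); each session day contributes the mean
    win count within each class, with the per-class n. This is the
    trajectory view showing e.g. whether reference-window dominants keep
    winning over time.
    """
    key = assignments.set_index(["cage", "animal"])["rank_class"]
    rows = []
    for cage in ledger.cages:
        cage_days = ledger.sessions_for(cage) if days is None else days
        for day in cage_days:
            standing = daily_standings(ledger, cage, day)
            for animal, wins in standing.win_count.items():
                rows.append(
                    {"day": day, "rank_class": key.loc[(cage, animal)], "wins": wins}
                )
    long = pd.DataFrame(rows)
    out = (
        long.groupby(["day", "rank_class"])["wins"]
        .agg(mean_wins="mean", n="size")
        .reset_index()
    )
    return out
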