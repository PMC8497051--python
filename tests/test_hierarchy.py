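"""Rank-inference metrics against independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domhier.hierarchy import (
    DOM,
    INT,
    SUB,
    DailyStanding,
    IncompleteDyadError,
    IncompleteRoundRobinError,
    TooFewSessionsError,
    WinMatrix,
    avg_wins_by_rank_trajectory,
    classify_rank,
    classify_ranks,
    daily_standings,
    davids_scores,
    is_transitive,
    mobility,
    rank_change_fraction,
    stability,
    steepness,
)
from domhier.io import ContestLedger, ContestRecord, build_win_matrix

from conftest import (
    TETRAD,
    all_tetrad_tournaments,
    make_round_robin_records,
    unanimous_outcomes,
)

# ---------------------------------------------------------------- oracles


def ds_oracle(P):
    """Brute-force David's Score: the four sums written as plain loops."""
    n = len(P)
    w = [sum(P[i][j] for j in range(n) if j != i) for i in range(n)]
    l = [sum(P[j][i] for j in range(n) if j != i) for i in range(n)]
    w2 = [sum(P[i][j] * w[j] for j in range(n) if j != i) for i in range(n)]
    l2 = [sum(P[j][i] * l[j] for j in range(n) if j != i) for i in range(n)]
    return [w[i] + w2[i] - l[i] - l2[i] for i in range(n)]


def has_three_cycle(wins01: np.ndarray) -> bool:
    """Exhaustive directed 3-cycle search on a 0/1 tournament matrix."""
    n = wins01.shape[0]
    for i, j, k in itertools.permutations(range(n), 3):
        if wins01[i, j] and wins01[j, k] and wins01[k, i]:
            return True
    return False


def tournament_to_ledger(outcomes, days=(1,), cage="C1") -> ContestLedger:
    return ContestLedger.from_records(
        make_round_robin_records(outcomes, days=days, cage=cage)
    )


def outcomes_to_wins(outcomes) -> np.ndarray:
    idx = {a: i for i, a in enumerate(TETRAD)}
    wins = np.zeros((4, 4))
    for (a, b), winner in outcomes.items():
        loser = b if winner == a else a
        wins[idx[winner], idx[loser]] = 1
    return wins


random_win_matrices = st.lists(
    st.integers(min_value=0, max_value=5), min_size=12, max_size=12
)


def wins_from_flat(flat, n=4):
    """Build a complete win matrix from 2 * C(4,2) counts, ensuring n>0."""
    wins = np.zeros((n, n))
    pairs = list(itertools.combinations(range(n), 2))
    it = iter(flat)
    for i, j in pairs:
        a, b = next(it), next(it)
        if a + b == 0:
            a = 1
        wins[i, j], wins[j, i] = a, b
    return wins


# ---------------------------------------------------------------- David's Score


class TestDavidsScores:
    def test_unanimous_linear_tetrad(self, unanimous_ledger):
        ds = davids_scores(build_win_matrix(unanimous_ledger, "C1", [1, 3, 5, 7]))
        assert ds.loc[list("ABCD"), "ds"].tolist() == [6.0, 2.0, -2.0, -6.0]
        assert ds.loc[list("ABCD"), "w"].tolist() == [3.0, 2.0, 1.0, 0.0]
        assert ds.loc[list("ABCD"), "w2"].tolist() == [3.0, 1.0, 0.0, 0.0]
        assert ds.loc[list("ABCD"), "norm_ds"].tolist() == [3.0, 2.0, 1.0, 0.0]

    def test_even_matrix_is_flat(self, even_ledger):
        ds = davids_scores(build_win_matrix(even_ledger, "C1", [1, 3, 5, 7]))
        assert np.allclose(ds["ds"], 0.0)

    @settings(max_examples=100, deadline=None)
    @given(random_win_matrices)
    def test_matches_bruteforce_oracle_and_conserves(self, flat):
        wm = WinMatrix(animals=list("wxyz"), wins=wins_from_flat(flat))
        ds = davids_scores(wm)
        p = wm.P.copy()
        np.fill_diagonal(p, 0.0)
        assert np.allclose(ds["ds"].to_numpy(), ds_oracle(p.tolist()))
        assert abs(ds["ds"].sum()) < 1e-9
        assert ds["norm_ds"].between(-1e-9, 3 + 1e-9).all()

    def test_missing_pair_raises_naming_the_pair(self):
        wins = np.zeros((4, 4))
        wins[0, 1] = wins[0, 2] = wins[0, 3] = wins[1, 2] = wins[1, 3] = 1
        # pair (y, z) never contested
        wm = WinMatrix(animals=list("wxyz"), wins=wins)
        with pytest.raises(IncompleteDyadError, match=r"\(y, z\)"):
            davids_scores(wm)

    def test_extremes_over_all_tetrad_tournaments(self):
        # over all 64 daily tournaments replicated to 4 identical sessions,
        # DS spans exactly [-6, 6], attained only by unanimous win/loss rows
        lo, hi = 0.0, 0.0
        for outcomes in all_tetrad_tournaments():
            wins = outcomes_to_wins(outcomes) * 4
            ds = davids_scores(WinMatrix(animals=TETRAD, wins=wins))["ds"]
            if ds.max() > hi:
                hi = ds.max()
            if ds.min() < lo:
                lo = ds.min()
            for animal, value in ds.items():
                i = TETRAD.index(animal)
                if value == 6.0:
                    assert wins[i].sum() == 12  # won every contest
                if value == -6.0:
                    assert wins[:, i].sum() == 12
        assert (lo, hi) == (-6.0, 6.0)

    def test_top_animal_monotone_in_own_proportions(self):
        # strengthening the top row of P never decreases the top DS
        rng = np.random.default_rng(0)
        for _ in range(50):
            wins = wins_from_flat(rng.integers(0, 5, size=12))
            wm = WinMatrix(animals=TETRAD, wins=wins)
            ds0 = davids_scores(wm)["ds"].iloc[0]
            stronger = wins.copy()
            stronger[0, 1:] += 3  # more wins for animal 0, same opponents
            ds1 = davids_scores(WinMatrix(animals=TETRAD, wins=stronger))["ds"].iloc[0]
            assert ds1 >= ds0 - 1e-12


class TestClassifyRank:
    @pytest.mark.parametrize(
        "ds, expected",
        [(6, DOM), (3.01, DOM), (3, INT), (0, INT), (-3, INT), (-3.01, SUB), (-6, SUB)],
    )
    def test_boundaries_are_strict(self, ds, expected):
        assert classify_rank(ds) == expected

    @given(st.floats(min_value=-6, max_value=6, allow_nan=False))
    def test_every_score_maps_to_exactly_one_class(self, ds):
        assert classify_rank(ds) in (DOM, INT, SUB)

    def test_vectorized_matches_scalar(self):
        values = [-6, -3, -1, 0, 3, 5]
        assert classify_ranks(values).tolist() == [classify_rank(v) for v in values]


# ---------------------------------------------------------------- daily standings


class TestDailyStandings:
    def test_linear_day(self):
        ledger = tournament_to_ledger(unanimous_outcomes())
        standing = daily_standings(ledger, "C1", 1)
        assert [standing.win_count[a] for a in TETRAD] == [3, 2, 1, 0]
        assert standing.linear
        assert [standing.rank_position[a] for a in TETRAD] == [1, 2, 3, 4]

    def test_cyclic_day_is_not_linear(self):
        outcomes = unanimous_outcomes()
        outcomes[("A", "C")] = "C"  # A>B, B>C, C>A with D losing all
        ledger = tournament_to_ledger(outcomes)
        standing = daily_standings(ledger, "C1", 1)
        assert sorted(standing.win_count.values()) == [0, 2, 2, 2]
        assert not standing.linear
        assert all(v is None for v in standing.rank_position.values())

    def test_incomplete_day_rejected(self):
        records = make_round_robin_records(unanimous_outcomes(), days=(1,))[:-1]
        ledger = ContestLedger.from_records(records)
        with pytest.raises(IncompleteRoundRobinError):
            daily_standings(ledger, "C1", 1)

    def test_exactly_24_of_64_tournaments_are_linear(self):
        n_linear = sum(
            daily_standings(tournament_to_ledger(o), "C1", 1).linear
            for o in all_tetrad_tournaments()
        )
        assert n_linear == 24  # = 4! orderings


class TestIsTransitive:
    def test_agrees_with_cycle_search_on_all_tetrads(self):
        for outcomes in all_tetrad_tournaments():
            wins = outcomes_to_wins(outcomes)
            assert is_transitive(wins) == (not has_three_cycle(wins))

    def test_agrees_with_cycle_search_on_random_larger_tournaments(self):
        rng = np.random.default_rng(42)
        for n in (5, 6):
            for _ in range(200):
                wins = np.zeros((n, n))
                for i, j in itertools.combinations(range(n), 2):
                    if rng.random() < 0.5:
                        wins[i, j] = 1
                    else:
                        wins[j, i] = 1
                assert is_transitive(wins) == (not has_three_cycle(wins))

    def test_dyad_is_always_transitive(self):
        assert is_transitive(np.array([[0, 1], [0, 0]]))
        assert is_transitive(np.array([[0, 0], [1, 0]]))

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(IncompleteRoundRobinError):
            is_transitive(np.zeros((3, 3)))


# ---------------------------------------------------------------- stability


class TestStability:
    def test_four_identical_sessions_stable(self, unanimous_ledger):
        assert stability(unanimous_ledger, "C1").stable

    def test_one_flipped_pair_unstable(self):
        records = make_round_robin_records(unanimous_outcomes(), days=(1, 3, 5))
        flipped = unanimous_outcomes()
        flipped[("C", "D")] = "D"
        records += make_round_robin_records(flipped, days=(7,))
        ledger = ContestLedger.from_records(records)
        assert not stability(ledger, "C1").stable

    def test_identical_nonlinear_sessions_stable_under_outcome_criterion(self):
        outcomes = unanimous_outcomes()
        outcomes[("A", "C")] = "C"  # 3-cycle, same every session
        ledger = tournament_to_ledger(outcomes, days=(1, 3, 5, 7))
        assert stability(ledger, "C1", criterion="outcomes").stable
        # the rank-ordering convention cannot call a non-linear run stable
        assert not stability(ledger, "C1", criterion="ranks").stable

    def test_too_few_sessions(self, unanimous_ledger):
        with pytest.raises(TooFewSessionsError):
            stability(unanimous_ledger, "C1", window_sessions=5)


# ---------------------------------------------------------------- steepness


class TestSteepness:
    def test_unanimous_tetrad_is_one(self, unanimous_ledger):
        res = steepness(unanimous_ledger, "C1", window=[1, 3, 5, 7])
        assert res.slope_magnitude == pytest.approx(1.0)

    def test_flat_hierarchy_is_zero(self, even_ledger):
        res = steepness(even_ledger, "C1", window=[1, 3, 5, 7])
        assert res.slope_magnitude == pytest.approx(0.0, abs=1e-12)

    def test_bounded_and_label_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            wins = wins_from_flat(rng.integers(0, 5, size=12))
            records = []
            # encode the win matrix as a ledger of repeated daily pairs
            for i, j in itertools.combinations(range(4), 2):
                day = 0
                for _ in range(int(wins[i, j])):
                    day += 1
                    records.append(ContestRecord(day, "C1", TETRAD[i], TETRAD[j], TETRAD[i]))
                for _ in range(int(wins[j, i])):
                    day += 1
                    records.append(ContestRecord(day, "C1", TETRAD[i], TETRAD[j], TETRAD[j]))
            ledger = ContestLedger.from_records(records)
            window = ledger.sessions
            value = steepness(ledger, "C1", window=window).slope_magnitude
            assert 0.0 <= value <= 1.0
            relabel = {"A": "Q", "B": "P", "C": "Z", "D": "K"}
            renamed = ledger.df.replace(relabel)
            value2 = steepness(ContestLedger(renamed), "C1", window=window).slope_magnitude
            assert value2 == pytest.approx(value)

    def test_invariant_to_repeating_sessions(self):
        # doubling every pair count leaves P, hence steepness, unchanged
        outcomes = unanimous_outcomes()
        outcomes[("B", "C")] = "C"
        short = tournament_to_ledger(outcomes, days=(1, 3))
        long = tournament_to_ledger(outcomes, days=(1, 3, 5, 7))
        s1 = steepness(short, "C1", window=[1, 3]).slope_magnitude
        s2 = steepness(long, "C1", window=[1, 3, 5, 7]).slope_magnitude
        assert s1 == pytest.approx(s2)

    def test_window_shorter_than_configured(self, unanimous_ledger):
        with pytest.raises(TooFewSessionsError):
            steepness(unanimous_ledger, "C1", window_sessions=7)


# ---------------------------------------------------------------- mobility


def standings_from_positions(positions):
    """DailyStanding sequence for one animal 'A' in a dyad-like setup;
    None marks a non-linear day."""
    out = []
    for day, pos in enumerate(positions, start=1):
        linear = pos is not None
        out.append(
            DailyStanding(
                day=day, animals=["A", "B"], win_count={"A": 1, "B": 0},
                linear=linear,
                rank_position={"A": pos, "B": None if pos is None else 3 - pos},
            )
        )
    return out


class TestMobility:
    @pytest.mark.parametrize(
        "positions, changes, cls",
        [
            ((1,) * 9, 0, "LOW"),
            ((2, 1, 2, 1), 3, "HIGH"),
            ((1, None, 2), 1, "LOW"),  # non-linear day skipped entirely
            ((1, 1, 2, 2, 2), 1, "LOW"),
            ((1, 2, 1), 2, "HIGH"),
        ],
    )
    def test_rank_change_counting(self, positions, changes, cls):
        report = mobility(standings_from_positions(positions), "A")
        assert report.n_rank_changes == changes
        assert report.mobility_class == cls

    def test_fewer_than_two_linear_days_is_undefined(self):
        report = mobility(standings_from_positions((1, None, None)), "A")
        assert report.mobility_class == "UNDEFINED"


class TestRankChangeFraction:
    @staticmethod
    def frame(ds_by_animal):
        return pd.DataFrame(
            [
                {"cage": a.split(".")[0], "animal": a, "ds": v}
                for a, v in ds_by_animal.items()
            ]
        )

    def test_identical_orderings(self):
        pre = self.frame({"c1.a": 6, "c1.b": 2, "c1.c": -2, "c1.d": -6})
        assert rank_change_fraction(pre, pre.copy()) == 0.0

    def test_full_reversal(self):
        pre = self.frame({"c1.a": 6, "c1.b": 2, "c1.c": -2, "c1.d": -6})
        post = self.frame({"c1.a": -6, "c1.b": -2, "c1.c": 2, "c1.d": 6})
        assert rank_change_fraction(pre, post) == 1.0

    def test_one_adjacent_swap_in_one_of_two_tetrads(self):
        base = {
            "c1.a": 6, "c1.b": 2, "c1.c": -2, "c1.d": -6,
            "c2.a": 6, "c2.b": 2, "c2.c": -2, "c2.d": -6,
        }
        post = dict(base)
        post["c2.c"], post["c2.d"] = -6, -2  # swap bottom two of cage 2
        assert rank_change_fraction(self.frame(base), self.frame(post)) == 0.25

    def test_animal_set_mismatch(self):
        pre = self.frame({"c1.a": 1, "c1.b": 0})
        post = self.frame({"c1.a": 1, "c1.x": 0})
        with pytest.raises(ValueError):
            rank_change_fraction(pre, post)


class TestRankTrajectory:
    def test_static_unanimous_hierarchy(self, unanimous_ledger):
        assignments = pd.DataFrame(
            {
                "cage": ["C1"] * 4,
                "animal": TETRAD,
                "rank_class": [DOM, INT, INT, SUB],
            }
        )
        table = avg_wins_by_rank_trajectory(unanimous_ledger, assignments)
        dom = table[table["rank_class"] == DOM]
        assert (dom["mean_wins"] == 3).all()
        assert (dom["n"] == 1).all()
        # single-cage class means equal the individual traces
        ints = table[table["rank_class"] == INT]
        assert (ints["mean_wins"] == 1.5).all()
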