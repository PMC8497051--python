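"""Shared fixtures: small hand-built contest ledgers."""

from __future__ import annotations

import itertools

import pytest

from domhier.io import ContestLedger, ContestRecord

TETRAD = ["A", "B", "C", "D"]


def make_round_robin_records(
    outcomes: dict[tuple[str, str], str],
    days=(1, 3, 5, 7),
    cage: str = "C1",
) -> list[ContestRecord]:
    """Records for identical round-robin sessions with the given
    per-pair winners (keys are (a, b) pairs, values the winner)."""
    records = []
    for day in days:
        for (a, b), winner in outcomes.items():
            records.append(ContestRecord(day, cage, a, b, winner))
    return records


def unanimous_outcomes(order=TETRAD) -> dict[tuple[str, str], str]:
    """Every higher-ranked animal beats every lower-ranked one."""
    return {
        (a, b): a for a, b in itertools.combinations(order, 2)
    }


def split_ledger(days=(1, 3, 5, 7), cage: str = "C1") -> ContestLedger:
    """Each pair splits its contests 50/50 (alternating winners by day)."""
    records = []
    for k, day in enumerate(days):
        for a, b in itertools.combinations(TETRAD, 2):
            records.append(ContestRecord(day, cage, a, b, a if k % 2 == 0 else b))
    return ContestLedger.from_records(records)


@pytest.fixture
def unanimous_ledger() -> ContestLedger:
    """Perfectly despotic tetrad: A > B > C > D unanimously, 4 sessions."""
    return ContestLedger.from_records(
        make_round_robin_records(unanimous_outcomes())
    )


@pytest.fixture
def even_ledger() -> ContestLedger:
    """Every pair split 2-2 over 4 sessions (all win proportions 0.5)."""
    return split_ledger()


def all_tetrad_tournaments():
    """All 64 single-day tetrad round robins as (a, b) -> winner dicts."""
    pairs = list(itertools.combinations(TETRAD, 2))
    for bits in itertools.product((0, 1), repeat=len(pairs)):
        yield {
            pair: pair[bit] for pair, bit in zip(pairs, bits)
        }
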