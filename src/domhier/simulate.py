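"""Synthetic cohorts with the statistical structure the pipeline assumes.

Contests follow a logistic latent-ability (Bradley-Terry-type) model:
each animal draws a latent ability ``theta ~ Normal(0, ability_sd^2)``,
and in a contest between *i* and *j*

    P(i beats j) = logistic((theta_i - theta_j) / temperature)

Small ``temperature`` relative to the ability spread yields decisive,
stable, linear hierarchies; large values yield noisy ones. Two optional
perturbations emulate real dynamics: a *winner effect* (``winner_effect``
added to the winner's ability and subtracted from the loser's after each
contest, persisting thereafter) and per-session ability jitter
(``session_jitter``), which together produce the observed mixture of
stable and unstable cages.

Tournaments are same-sex tetrads (or dyads) run as a round robin per
session, nine sessions on alternating days by default (18 study days).
Stress outcomes are drawn on top of a rank assignment: controls get a
social-interaction ratio around ``si_ctrl_mean``; stressed animals lose
a configurable per-rank-class deficit (the male defeat pattern puts the
deficit on subordinates/intermediates and none on dominants), coping
scores are drawn to track the realized SI ratio, and subordinate
vigilance is elevated under the inter-female scenario flag.

All randomness flows from a single seed through named, independent
streams, so adding a stream never perturbs existing ones and the same
config reproduces byte-identical cohorts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from domhier.hierarchy import DOM, INT, SUB, classify_ranks, davids_scores
from domhier.io import ContestLedger, ContestRecord, build_win_matrix


class SimConfig(BaseModel):
    """Generator configuration; defaults emulate the tetrad tube-test design."""

    model_config = ConfigDict(extra="forbid")

    # cohort structure
    n_cages: int = Field(default=12, ge=1)
    group_size: Literal[2, 4] = 4
    n_sessions: int = Field(default=9, ge=1)
    session_spacing_days: int = Field(default=2, ge=1)
    sex: Literal["male", "female"] = "male"
    # contest model
    ability_sd: float = Field(default=1.0, ge=0)
    temperature: float = Field(default=0.3, gt=0)
    winner_effect: float = Field(default=0.05, ge=0)
    session_jitter: float = Field(default=0.15, ge=0)
    # stress outcomes
    stress_fraction: float = Field(default=0.5, ge=0, le=1)
    si_ctrl_mean: float = 1.3
    si_ctrl_sd: float = Field(default=0.4, gt=0)
    si_deficit_dom: float = 0.0
    si_deficit_int: float = 0.35
    si_deficit_sub: float = 0.45
    ds_si_slope: float = 0.0
    si_time_absent_mean_s: float = Field(default=60.0, gt=0)
    si_time_absent_sd_s: float = Field(default=8.0, ge=0)
    coping_intercept: float = 0.0
    coping_slope: float = 0.6
    coping_noise_sd: float = Field(default=0.25, ge=0)
    mean_attacks: float = Field(default=25.0, gt=0)
    vigilance_base_s: float = Field(default=5.0, ge=0)
    vigilance_sd_s: float = Field(default=2.0, ge=0)
    vigilance_sub_effect_s: float = Field(default=5.0, ge=0)
    interfemale: bool = False
    # recombination experiment
    dyad_sessions: int = Field(default=7, ge=1)
    recomb_gap: float = 0.5
    # chronic-variable-stress experiment
    cvs_sessions: int = Field(default=7, ge=1)
    cvs_susceptible_fraction: float = Field(default=0.3, ge=0, le=1)
    cvs_rank_coupling: float = Field(default=6.0, ge=0)
    cvs_si_coupling: float = Field(default=1.2, ge=0)
    # rank window used when the generator itself needs an assignment
    ds_window_sessions: int = Field(default=4, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.group_size == 2 and self.n_cages < 1:
            raise ValueError("need at least one cage")
        return self


@dataclass
class SyntheticCohort:
    """Generated ledger plus ground truth (and behavior once drawn).

    ``truth`` holds per-animal latent state (initial and final ability,
    susceptibility trait, stress assignment) and is never consumed by
    analysis stages — it exists to validate them.
    """

    ledger: ContestLedger
    truth: pd.DataFrame
    config: SimConfig
    behavior: pd.DataFrame | None = None
    stress_start_day: int | None = None


@dataclass
class RecombinationCohort:
    """Tetrad phase plus the re-paired dyad phase of the recombination design."""

    tetrad: SyntheticCohort
    dyad_ledger: ContestLedger
    labels: pd.DataFrame  # animal, origin_cage, initial_class, dyad_cage, final_class, label
    behavior: pd.DataFrame
    config: SimConfig


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent named stream derived from one master seed."""
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    from scipy.special import expit

    return expit(x)


def _cage_ids(n: int, prefix: str = "C") -> list[str]:
    return [f"{prefix}{i + 1:02d}" for i in range(n)]


def _animal_tags(cage: str, group_size: int) -> list[str]:
    return [f"{cage}.{k + 1}" for k in range(group_size)]


def _run_sessions(
    theta: dict[str, float],
    cages: dict[str, list[str]],
    days: list[int],
    config: SimConfig,
    rng: np.random.Generator,
    theta_shift: dict[str, float] | None = None,
) -> list[ContestRecord]:
    """Round-robin sessions under the logistic contest model.

    Mutates ``theta`` in place via the winner effect. ``theta_shift``
    adds a fixed offset per animal (used for the stress-epoch penalty).
    """
    records: list[ContestRecord] = []
    shift = theta_shift or {}
    for day in days:
        for cage, animals in cages.items():
            jitter = (
                rng.normal(0.0, config.session_jitter, size=len(animals))
                if config.session_jitter > 0
                else np.zeros(len(animals))
            )
            jit = dict(zip(animals, jitter))
            pairs = [
                (a, b)
                for i, a in enumerate(animals)
                for b in animals[i + 1 :]
            ]
            rng.shuffle(pairs)
            for a, b in pairs:
                ea = theta[a] + jit[a] + shift.get(a, 0.0)
                eb = theta[b] + jit[b] + shift.get(b, 0.0)
                p_a = _logistic((ea - eb) / config.temperature)
                a_wins = rng.random() < p_a
                winner, loser = (a, b) if a_wins else (b, a)
                theta[winner] += config.winner_effect
                theta[loser] -= config.winner_effect
                records.append(ContestRecord(day, cage, a, b, winner))
    return records


def simulate_tournament(config: SimConfig) -> SyntheticCohort:
    """Generate a round-robin tube-test tournament cohort.

    Abilities are drawn once, sessions run on alternating days (day 1,
    3, ... by default), and every generated ledger satisfies the
    round-robin validation invariants. Reproducible from ``config.seed``.
    """
    rng_theta = _rng(config.seed, "tournament-ability")
    rng_contest = _rng(config.seed, "tournament-contests")
    cages = {
        cage: _animal_tags(cage, config.group_size)
        for cage in _cage_ids(config.n_cages)
    }
    all_animals = [a for animals in cages.values() for a in animals]
    theta0 = dict(
        zip(all_animals, rng_theta.normal(0.0, config.ability_sd, len(all_animals)))
    )
    theta = dict(theta0)
    days = [1 + s * config.session_spacing_days for s in range(config.n_sessions)]
    records = _run_sessions(theta, cages, days, config, rng_contest)
    truth = pd.DataFrame(
        {
            "cage": [a.rsplit(".", 1)[0] for a in all_animals],
            "animal": all_animals,
            "sex": config.sex,
            "theta": [theta0[a] for a in all_animals],
            "theta_final": [theta[a] for a in all_animals],
        }
    )
    return SyntheticCohort(
        ledger=ContestLedger.from_records(records), truth=truth, config=config
    )


def _rank_deficit(rank_class: str, config: SimConfig) -> float:
    return {
        DOM: config.si_deficit_dom,
        INT: config.si_deficit_int,
        SUB: config.si_deficit_sub,
    }[rank_class]


def _truncated_normal(
    rng: np.random.Generator, mean: np.ndarray, sd: float, low: float = 0.0
) -> np.ndarray:
    """Normal draws re-drawn below ``low`` (simple rejection, vectorized)."""
    mean = np.asarray(mean, dtype=float)
    out = rng.normal(mean, sd)
    for _ in range(100):
        bad = out <= low
        if not bad.any():
            break
        out[bad] = rng.normal(mean[bad], sd)
    return np.clip(out, low + 1e-9, None)


def _coping_counts(
    rng: np.random.Generator, target_score: np.ndarray, mean_attacks: float
) -> pd.DataFrame:
    """Event counts whose realized coping score approximates the target.

    One response per attack bout is assumed: of ``n_attacks`` bouts a
    fraction ``(1 + s) / 2`` are met actively (escape or fight, split at
    random) and the rest passively, so the realized score is close to the
    clipped target ``s``.
    """
    s = np.clip(target_score, -1.0, 1.0)
    n_attacks = rng.poisson(mean_attacks, size=len(s)) + 1
    n_active = rng.binomial(n_attacks, (1 + s) / 2)
    n_passive = n_attacks - n_active
    n_escape = rng.binomial(n_active, 0.6)
    n_fight = n_active - n_escape
    return pd.DataFrame(
        {
            "n_escape": n_escape,
            "n_fight": n_fight,
            "n_passive": n_passive,
            "n_attacks": n_attacks,
        }
    )


def assign_stress(
    cohort: SyntheticCohort, config: SimConfig | None = None
) -> pd.Series:
    """Cage-level random assignment to CTRL/STRESS (cages, not animals,
    are randomized, matching how group housing constrains the design)."""
    config = config or cohort.config
    rng = _rng(config.seed, "stress-assignment")
    cages = sorted(cohort.truth["cage"].unique())
    n_stress = int(round(config.stress_fraction * len(cages)))
    stressed = set(rng.choice(cages, size=n_stress, replace=False))
    return cohort.truth["cage"].map(
        lambda c: "STRESS" if c in stressed else "CTRL"
    )


def simulate_stress_outcomes(
    cohort: SyntheticCohort,
    assignments: pd.DataFrame,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Draw a behavior table for a ranked cohort under social defeat.

    ``assignments`` needs columns ``cage, animal, ds, rank_class``
    computed from the cohort's pre-stress window. Controls draw SI
    ratios around ``si_ctrl_mean`` (truncated at 0); stressed animals
    lose the per-rank-class deficit plus ``ds_si_slope * DS``. Coping
    event counts are drawn so the coping score tracks the realized SI
    ratio at ``coping_slope``; vigilance is elevated for stressed
    subordinates under ``interfemale``.
    """
    config = config or cohort.config
    merged = cohort.truth.merge(assignments, on=["cage", "animal"], how="left")
    if merged["rank_class"].isna().any():
        missing = merged.loc[merged["rank_class"].isna(), "animal"].tolist()
        raise ValueError(f"assignments missing for animals {missing[:5]}")
    if "stress_condition" in merged.columns:
        condition = merged["stress_condition"]
    else:
        condition = assign_stress(cohort, config)
    rng = _rng(config.seed, "stress-outcomes")

    stressed = (condition == "STRESS").to_numpy()
    deficit = merged["rank_class"].map(lambda c: _rank_deficit(c, config)).to_numpy()
    mean_si = np.full(len(merged), config.si_ctrl_mean, dtype=float)
    mean_si[stressed] += (
        -deficit[stressed] + config.ds_si_slope * merged["ds"].to_numpy()[stressed]
    )
    si = _truncated_normal(rng, mean_si, config.si_ctrl_sd)

    t_absent = np.clip(
        rng.normal(config.si_time_absent_mean_s, config.si_time_absent_sd_s, len(si)),
        10.0, None,
    )
    t_present = si * t_absent

    coping_target = (
        config.coping_intercept
        + config.coping_slope * (si - 1.0)
        + rng.normal(0.0, config.coping_noise_sd, len(si))
    )
    coping = _coping_counts(rng, coping_target, config.mean_attacks)

    vig_mean = np.full(len(merged), config.vigilance_base_s, dtype=float)
    if config.interfemale:
        sub_stressed = stressed & (merged["rank_class"] == SUB).to_numpy()
        vig_mean[sub_stressed] += config.vigilance_sub_effect_s
    vigilance = np.clip(rng.normal(vig_mean, config.vigilance_sd_s), 0.0, None)

    behavior = pd.DataFrame(
        {
            "cage": merged["cage"],
            "animal": merged["animal"],
            "sex": merged["sex"],
            "stress_condition": condition.to_numpy(),
            "time_target_present": t_present,
            "time_target_absent": t_absent,
            "vigilance_s": vigilance,
        }
    )
    behavior = pd.concat([behavior, coping], axis=1)
    return behavior


def simulate_recombination(config: SimConfig) -> RecombinationCohort:
    """Dyadic recombination: tetrad winners re-paired with winners.

    After a tetrad phase, the top-DS animal (initial DOM) and bottom-DS
    animal (initial SUB) of each cage are re-housed DOM-with-DOM and
    SUB-with-SUB; the new dyad contests decide who keeps or loses the
    position, labelled DOM-DOM / DOM-SUB / SUB-DOM / SUB-SUB. SI ratios
    are drawn with a ``recomb_gap`` deficit for DOM-SUB relative to
    DOM-DOM and no gap between the SUB arms.
    """
    if config.n_cages % 2:
        raise ValueError("recombination needs an even number of tetrad cages")
    tetrad_cfg = replace_config(config, group_size=4)
    tetrad = simulate_tournament(tetrad_cfg)
    ledger = tetrad.ledger
    window = ledger.sessions[-config.ds_window_sessions :]
    theta = dict(zip(tetrad.truth["animal"], tetrad.truth["theta_final"]))

    tops, bottoms = [], []
    for cage in ledger.cages:
        ds = davids_scores(build_win_matrix(ledger, cage, window))["ds"]
        tops.append((cage, ds.idxmax()))
        bottoms.append((cage, ds.idxmin()))

    rng = _rng(config.seed, "recombination-contests")
    dyad_records: list[ContestRecord] = []
    label_rows: list[dict] = []
    days = [1 + s * config.session_spacing_days for s in range(config.dyad_sessions)]
    dyad_idx = 0
    for initial_class, members in ((DOM, tops), (SUB, bottoms)):
        for k in range(0, len(members), 2):
            dyad_idx += 1
            dyad_cage = f"D{dyad_idx:02d}"
            (_, a), (_, b) = members[k], members[k + 1]
            cages = {dyad_cage: [a, b]}
            th = {a: theta[a], b: theta[b]}
            dyad_records.extend(
                _run_sessions(th, cages, days, config, rng)
            )
            # final class by dyad DS sign (majority winner is the dyad DOM)
            wins_a = sum(
                1 for r in dyad_records
                if r.cage == dyad_cage and r.winner == a
            )
            final_a = DOM if wins_a * 2 > config.dyad_sessions else SUB
            for animal, final in ((a, final_a), (b, SUB if final_a == DOM else DOM)):
                label_rows.append(
                    {
                        "animal": animal,
                        "origin_cage": animal.rsplit(".", 1)[0],
                        "initial_class": initial_class,
                        "dyad_cage": dyad_cage,
                        "final_class": final,
                        "label": f"{initial_class}-{final}",
                    }
                )
    labels = pd.DataFrame(label_rows)

    rng_si = _rng(config.seed, "recombination-si")
    base = {
        "DOM-DOM": config.si_ctrl_mean,
        "DOM-SUB": config.si_ctrl_mean - config.recomb_gap,
        "SUB-DOM": config.si_ctrl_mean - config.si_deficit_sub,
        "SUB-SUB": config.si_ctrl_mean - config.si_deficit_sub,
    }
    means = labels["label"].map(base).to_numpy()
    si = _truncated_normal(rng_si, means, config.si_ctrl_sd)
    t_absent = np.clip(
        rng_si.normal(
            config.si_time_absent_mean_s, config.si_time_absent_sd_s, len(si)
        ),
        10.0, None,
    )
    behavior = pd.DataFrame(
        {
            "cage": labels["dyad_cage"],
            "animal": labels["animal"],
            "stress_condition": "STRESS",
            "recomb_label": labels["label"],
            "time_target_present": si * t_absent,
            "time_target_absent": t_absent,
        }
    )
    return RecombinationCohort(
        tetrad=tetrad,
        dyad_ledger=ContestLedger.from_records(dyad_records),
        labels=labels,
        behavior=behavior,
        config=config,
    )


def simulate_cvs_cohort(config: SimConfig) -> SyntheticCohort:
    """Cohort with pre-stress and during-stress epochs for the emergent-rank design.

    A latent stress-reactivity trait is drawn per animal: a fraction
    ``cvs_susceptible_fraction`` carries a positive severity (around 1),
    the rest zero. The trait is constitutive for social interaction —
    every carrier's SI ratio is lowered by ``cvs_si_coupling * severity``
    whether stressed or not — while its hierarchy consequence expresses
    only under stress: during the stress epoch, stressed carriers take an
    ability penalty ``cvs_rank_coupling * severity`` and sink. Emergent
    (final-window) rank therefore collects the low-SI carriers into the
    stressed subordinate cell, while every pre-stress rank x stress cell
    has the identical trait mixture — so emergent rank predicts the SI
    deficit and pre-stress rank does not, exactly the structure of a
    chronic-variable-stress cohort with no stress main effect on SI.
    With zero couplings the design is null. The behavior table is
    attached to the returned cohort.
    """
    rng_theta = _rng(config.seed, "cvs-ability")
    rng_contest = _rng(config.seed, "cvs-contests")
    rng_out = _rng(config.seed, "cvs-outcomes")
    cages = {
        cage: _animal_tags(cage, config.group_size)
        for cage in _cage_ids(config.n_cages)
    }
    all_animals = [a for animals in cages.values() for a in animals]
    theta0 = dict(
        zip(all_animals, rng_theta.normal(0.0, config.ability_sd, len(all_animals)))
    )
    is_susceptible = rng_theta.random(len(all_animals)) < config.cvs_susceptible_fraction
    severity = np.where(
        is_susceptible,
        np.clip(rng_theta.normal(1.0, 0.15, len(all_animals)), 0.1, None),
        0.0,
    )
    suscept = dict(zip(all_animals, severity))
    theta = dict(theta0)

    pre_days = [1 + s * config.session_spacing_days for s in range(config.n_sessions)]
    stress_start = pre_days[-1] + 1
    stress_days = [
        stress_start + 1 + s * config.session_spacing_days
        for s in range(config.cvs_sessions)
    ]

    records = _run_sessions(theta, cages, pre_days, config, rng_contest)

    truth = pd.DataFrame(
        {
            "cage": [a.rsplit(".", 1)[0] for a in all_animals],
            "animal": all_animals,
            "sex": config.sex,
            "theta": [theta0[a] for a in all_animals],
            "susceptibility": [suscept[a] for a in all_animals],
        }
    )
    cohort_stub = SyntheticCohort(
        ledger=ContestLedger.from_records(records), truth=truth, config=config
    )
    condition = assign_stress(cohort_stub, config)
    truth["stress_condition"] = condition.to_numpy()
    stressed_animals = set(truth.loc[truth["stress_condition"] == "STRESS", "animal"])

    shift = {
        a: -config.cvs_rank_coupling * suscept[a]
        for a in all_animals
        if a in stressed_animals
    }
    records += _run_sessions(theta, cages, stress_days, config, rng_contest, shift)

    s_arr = truth["susceptibility"].to_numpy()
    mean_si = config.si_ctrl_mean - config.cvs_si_coupling * s_arr
    si = _truncated_normal(rng_out, mean_si, config.si_ctrl_sd)
    t_absent = np.clip(
        rng_out.normal(
            config.si_time_absent_mean_s, config.si_time_absent_sd_s, len(si)
        ),
        10.0, None,
    )
    behavior = pd.DataFrame(
        {
            "cage": truth["cage"],
            "animal": truth["animal"],
            "sex": truth["sex"],
            "stress_condition": truth["stress_condition"],
            "time_target_present": si * t_absent,
            "time_target_absent": t_absent,
        }
    )
    truth["theta_final"] = [theta[a] for a in all_animals]
    return SyntheticCohort(
        ledger=ContestLedger.from_records(records),
        truth=truth,
        config=config,
        behavior=behavior,
        stress_start_day=stress_start,
    )


def replace_config(config: SimConfig, **overrides) -> SimConfig:
    """Copy a config with fields replaced (validated)."""
    return SimConfig(**{**config.model_dump(), **overrides})


def rank_assignments(
    cohort: SyntheticCohort,
    window: list[int] | None = None,
    dom_cutoff: float = 3.0,
    sub_cutoff: float = -3.0,
) -> pd.DataFrame:
    """DS + rank class per animal over a window (default: final rank window)."""
    ledger = cohort.ledger
    rows = []
    for cage in ledger.cages:
        cage_window = (
            ledger.sessions_for(cage)[-cohort.config.ds_window_sessions :]
            if window is None
            else window
        )
        ds = davids_scores(build_win_matrix(ledger, cage, cage_window))
        for animal, row in ds.iterrows():
            rows.append({"cage": cage, "animal": animal, "ds": row["ds"]})
    out = pd.DataFrame(rows)
    out["rank_class"] = classify_ranks(out["ds"], dom_cutoff, sub_cutoff)
    return out
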