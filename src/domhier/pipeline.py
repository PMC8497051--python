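"""End-to-end study workflows.

Two entry points mirror how hierarchy/stress experiments are analysed:

* :func:`characterize` — hierarchy description for a ledger: per-cage
  stability, per-day linearity, steepness, David's Scores and rank
  classes, and (when occupancy data is supplied) the warm-corner
  correlation with rank.
* :func:`stress_analysis` — the rank x stress statistical designs:
  ``csds`` (pre-stress rank vs defeat outcome), ``cvs`` (pre-stress vs
  emergent rank under chronic variable stress), ``recombination``
  (dyad re-pairing arms) and ``mobility`` (rank-trajectory history).

Each report carries a provenance block (config hash, seed, versions) and
a log of every filtering step, so any number in the output traces to an
upstream table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import domhier
from domhier.behavior import score_behavior_table
from domhier.hierarchy import (
    all_standings,
    avg_wins_by_rank_trajectory,
    classify_ranks,
    davids_scores,
    mobility,
    stability,
    steepness,
)
from domhier.io import ContestLedger, RunConfig, build_win_matrix
from domhier.stats import (
    StatResult,
    factorial_compare,
    one_way_compare,
    pearson_ci,
    remove_outliers,
    results_table,
    two_sample_t,
)

logger = logging.getLogger("domhier")

DESIGNS = ("csds", "cvs", "recombination", "mobility")


def _provenance(config: RunConfig, extra: dict | None = None) -> dict:
    payload = config.model_dump()
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]
    return {
        "config": payload,
        "config_hash": digest,
        "seed": config.rng_seed,
        "domhier_version": domhier.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    } | (extra or {})


@dataclass
class CharacterizationReport:
    per_cage: pd.DataFrame
    ds_table: pd.DataFrame
    daily: pd.DataFrame
    frac_linear_days: float
    frac_stable_cages: float
    warm_corner: StatResult | None
    warm_corner_by_class: object | None
    provenance: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_cage.to_csv(outdir / "per_cage.csv", index=False)
        self.ds_table.to_csv(outdir / "ds_table.csv", index=False)
        self.daily.to_csv(outdir / "daily_linearity.csv", index=False)
        stats = []
        if self.warm_corner is not None:
            stats.append(self.warm_corner)
        if self.warm_corner_by_class is not None:
            stats.extend(self.warm_corner_by_class.all_results())
        if stats:
            results_table(stats).to_csv(outdir / "statistics.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(
                self.provenance
                | {
                    "frac_linear_days": self.frac_linear_days,
                    "frac_stable_cages": self.frac_stable_cages,
                },
                fh, indent=2,
            )


def characterize(
    ledger: ContestLedger,
    config: RunConfig | None = None,
    behavior: pd.DataFrame | None = None,
) -> CharacterizationReport:
    """Hierarchy characterization of a contest ledger.

    Produces per-cage stability and steepness, the per-day linearity
    table, David's Scores with rank classes over the final rank window,
    and — when the behavior table carries ``warm_corner_s`` — the
    Pearson correlation of warm-corner occupancy with DS plus the
    one-way by-rank-class comparison.
    """
    config = config or RunConfig()
    cage_rows, ds_rows, daily_rows = [], [], []
    for cage in ledger.cages:
        sessions = ledger.sessions_for(cage)
        standings = all_standings(ledger, cage)
        n_linear = sum(s.linear for s in standings)
        for s in standings:
            daily_rows.append({"cage": cage, "day": s.day, "linear": s.linear})
        stab = stability(
            ledger, cage,
            window_sessions=config.stability_window_sessions,
            criterion=config.stability_criterion,
        )
        if len(sessions) >= config.steepness_window_sessions:
            steep = steepness(
                ledger, cage, window_sessions=config.steepness_window_sessions
            ).slope_magnitude
        else:
            steep = np.nan
            logger.warning(
                "cage %s: %d sessions < steepness window %d; steepness skipped",
                cage, len(sessions), config.steepness_window_sessions,
            )
        window = sessions[-config.ds_window_sessions :]
        ds = davids_scores(build_win_matrix(ledger, cage, window))
        classes = classify_ranks(ds["ds"], config.dom_cutoff, config.sub_cutoff)
        for animal, row in ds.iterrows():
            ds_rows.append(
                {"cage": cage, "animal": animal, **row.to_dict(),
                 "rank_class": classes.loc[animal]}
            )
        cage_rows.append(
            {
                "cage": cage,
                "n_sessions": len(sessions),
                "frac_linear_days": n_linear / len(standings),
                "stable": stab.stable,
                "steepness": steep,
            }
        )
    per_cage = pd.DataFrame(cage_rows)
    ds_table = pd.DataFrame(ds_rows)
    daily = pd.DataFrame(daily_rows)

    warm_corner = warm_by_class = None
    if behavior is not None and "warm_corner_s" in behavior.columns:
        merged = ds_table.merge(behavior, on=["cage", "animal"])
        merged = merged.dropna(subset=["warm_corner_s"])
        if len(merged) >= 3:
            warm_corner = pearson_ci(merged["ds"], merged["warm_corner_s"])
            groups = {
                cls: grp["warm_corner_s"].to_numpy()
                for cls, grp in merged.groupby("rank_class")
                if len(grp) >= 2
            }
            if len(groups) >= 2:
                warm_by_class = one_way_compare(groups)

    return CharacterizationReport(
        per_cage=per_cage,
        ds_table=ds_table,
        daily=daily,
        frac_linear_days=float(daily["linear"].mean()),
        frac_stable_cages=float(per_cage["stable"].mean()),
        warm_corner=warm_corner,
        warm_corner_by_class=warm_by_class,
        provenance=_provenance(config),
    )


@dataclass
class AnalysisReport:
    design: str
    ranks: pd.DataFrame
    stats: list[StatResult]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    filter_log: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def stat(self, label: str) -> StatResult:
        """Look up a result by its label."""
        for r in self.stats:
            if r.label == label:
                return r
        raise KeyError(label)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ranks.to_csv(outdir / "ranks.csv", index=False)
        results_table(self.stats).to_csv(outdir / "statistics.csv", index=False)
        if self.filter_log is not None:
            self.filter_log.to_csv(outdir / "filter_log.csv", index=False)
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.provenance | {"design": self.design}, fh, indent=2)


def _window_ranks(
    ledger: ContestLedger, config: RunConfig, before_day: int | None = None
) -> pd.DataFrame:
    """Per-animal DS and class over the window of ``ds_window_sessions``
    sessions ending before ``before_day`` (or the ledger's end)."""
    rows = []
    for cage in ledger.cages:
        sessions = ledger.sessions_for(cage)
        if before_day is not None:
            sessions = [d for d in sessions if d < before_day]
        window = sessions[-config.ds_window_sessions :]
        ds = davids_scores(build_win_matrix(ledger, cage, window))
        for animal, row in ds.iterrows():
            rows.append({"cage": cage, "animal": animal, "ds": row["ds"]})
    out = pd.DataFrame(rows)
    out["rank_class"] = classify_ranks(out["ds"], config.dom_cutoff, config.sub_cutoff)
    return out


def _si_factorial(
    data: pd.DataFrame, config: RunConfig, stats: list[StatResult], prefix: str = ""
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outlier-filter SI by rank x stress, run the factorial, log removals."""
    filtered, log = remove_outliers(
        data, "si_ratio", ("rank_class", "stress_condition"), config.outlier_sd
    )
    n_removed = int((log["action"] == "removed").sum()) if len(log) else 0
    logger.info(
        "%soutlier filter: %d of %d values removed", prefix, n_removed, len(data)
    )
    fact = factorial_compare(filtered, "si_ratio", "stress_condition", "rank_class")
    for key, res in fact.effects.items():
        res.label = f"{prefix}{key}"
        stats.append(res)
    for res in fact.contrasts:
        res.label = f"{prefix}{res.label}"
        stats.append(res)
    return filtered, log


def _join_behavior(
    ranks: pd.DataFrame, behavior: pd.DataFrame
) -> pd.DataFrame:
    scored = score_behavior_table(behavior)
    merged = ranks.merge(scored, on=["cage", "animal"], how="inner")
    if len(merged) < len(behavior):
        raise ValueError(
            f"behavior table has {len(behavior) - len(merged)} animal(s) "
            "absent from the contest ledger"
        )
    if "stress_condition" not in merged.columns or merged["stress_condition"].isna().any():
        raise ValueError("every animal entering group statistics needs stress_condition")
    return merged


def stress_analysis(
    ledger: ContestLedger,
    behavior: pd.DataFrame,
    config: RunConfig | None = None,
    design: str = "csds",
    stress_start_day: int | None = None,
) -> AnalysisReport:
    """Run one of the rank x stress statistical designs.

    ``csds``: rank from the pre-stress window (the sessions before
    ``stress_start_day`` if given, else the ledger's final window);
    factorial SI ~ stress x rank with within-rank contrasts, DS-SI and
    coping-SI correlations among stressed animals.

    ``cvs``: requires ``stress_start_day``; the same battery is run twice,
    on pre-stress ranks and on emergent ranks from the final window.

    ``recombination``: behavior must carry ``recomb_label``; unpaired
    t-tests DOM-DOM vs DOM-SUB and SUB-DOM vs SUB-SUB.

    ``mobility``: LOW/HIGH mobility from pre-stress linear days crossed
    with rank class in the factorial.
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}")
    config = config or RunConfig()
    stats: list[StatResult] = []
    tables: dict[str, pd.DataFrame] = {}
    filter_logs: list[pd.DataFrame] = []

    if design == "recombination":
        scored = score_behavior_table(behavior)
        if "recomb_label" not in scored.columns:
            raise ValueError("recombination design needs a recomb_label column")
        arms = {
            label: grp["si_ratio"].dropna().to_numpy()
            for label, grp in scored.groupby("recomb_label")
        }
        for top, bottom in (("DOM-DOM", "DOM-SUB"), ("SUB-DOM", "SUB-SUB")):
            res = two_sample_t(arms[top], arms[bottom])
            res.label = f"{top} vs {bottom}"
            stats.append(res)
        tables["behavior_scored"] = scored
        return AnalysisReport(
            design=design, ranks=pd.DataFrame(), stats=stats, tables=tables,
            provenance=_provenance(config, {"design": design}),
        )

    ranks = _window_ranks(ledger, config, before_day=stress_start_day)

    if design == "csds":
        merged = _join_behavior(ranks, behavior)
        filtered, log = _si_factorial(merged, config, stats)
        filter_logs.append(log)
        stressed = filtered[filtered["stress_condition"] == "STRESS"]
        res = pearson_ci(stressed["ds"], stressed["si_ratio"])
        res.label = "ds vs si_ratio (STRESS)"
        stats.append(res)
        if "coping_score" in stressed.columns and stressed["coping_score"].notna().sum() >= 3:
            res = pearson_ci(
                stressed.dropna(subset=["coping_score"])["coping_score"],
                stressed.dropna(subset=["coping_score"])["si_ratio"],
            )
            res.label = "coping_score vs si_ratio (STRESS)"
            stats.append(res)
        if "vigilance_s" in stressed.columns and stressed["vigilance_s"].notna().sum() >= 4:
            vig_filtered, vig_log = remove_outliers(
                merged.dropna(subset=["vigilance_s"]), "vigilance_s",
                ("rank_class", "stress_condition"), config.outlier_sd,
            )
            vig_fact = factorial_compare(
                vig_filtered, "vigilance_s", "stress_condition", "rank_class"
            )
            for key, r in vig_fact.effects.items():
                r.label = f"vigilance {key}"
                stats.append(r)
            for r in vig_fact.contrasts:
                r.label = f"vigilance {r.label}"
                stats.append(r)
            filter_logs.append(vig_log)
        tables["joined"] = filtered

    elif design == "cvs":
        if stress_start_day is None:
            raise ValueError("cvs design requires stress_start_day")
        emergent = _window_ranks(ledger, config, before_day=None)
        for label, rank_table in (("pre ", ranks), ("emergent ", emergent)):
            merged = _join_behavior(rank_table, behavior)
            filtered, log = _si_factorial(merged, config, stats, prefix=label)
            filter_logs.append(log)
            stressed = filtered[filtered["stress_condition"] == "STRESS"]
            res = pearson_ci(stressed["ds"], stressed["si_ratio"])
            res.label = f"{label}ds vs si_ratio (STRESS)"
            stats.append(res)
            tables[f"joined_{label.strip()}"] = filtered
        ranks = emergent

    elif design == "mobility":
        merged = _join_behavior(ranks, behavior)
        mob_rows = []
        for cage in ledger.cages:
            days = ledger.sessions_for(cage)
            if stress_start_day is not None:
                days = [d for d in days if d < stress_start_day]
            standings = all_standings(ledger, cage, days)
            for animal in ledger.animals(cage):
                rep = mobility(standings, animal, config.mobility_threshold)
                mob_rows.append(
                    {"cage": cage, "animal": animal,
                     "n_rank_changes": rep.n_rank_changes,
                     "mobility_class": rep.mobility_class,
                     "n_linear_days": rep.n_linear_days}
                )
        mob = pd.DataFrame(mob_rows)
        n_undefined = int((mob["mobility_class"] == "UNDEFINED").sum())
        if n_undefined:
            logger.info("mobility undefined for %d animal(s); excluded", n_undefined)
        merged = merged.merge(mob, on=["cage", "animal"])
        usable = merged[merged["mobility_class"] != "UNDEFINED"]
        filtered, log = remove_outliers(
            usable, "si_ratio", ("rank_class", "mobility_class"), config.outlier_sd
        )
        filter_logs.append(log)
        fact = factorial_compare(
            filtered, "si_ratio", "mobility_class", "rank_class"
        )
        for key, r in fact.effects.items():
            r.label = key
            stats.append(r)
        stats.extend(fact.contrasts)
        tables["mobility"] = mob
        tables["joined"] = filtered

    filter_logs = [log for log in filter_logs if len(log)]
    filter_log = (
        pd.concat(filter_logs, ignore_index=True) if filter_logs else None
    )
    return AnalysisReport(
        design=design, ranks=ranks, stats=stats, tables=tables,
        filter_log=filter_log,
        provenance=_provenance(
            config, {"design": design, "stress_start_day": stress_start_day}
        ),
    )


def rank_trajectory_table(
    ledger: ContestLedger, config: RunConfig | None = None,
    before_day: int | None = None,
) -> pd.DataFrame:
    """Mean daily wins per reference-window rank class (trajectory view)."""
    config = config or RunConfig()
    assignments = _window_ranks(ledger, config, before_day=before_day)
    return avg_wins_by_rank_trajectory(ledger, assignments)
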