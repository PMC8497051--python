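"""Group-level statistics for rank x stress comparisons.

The statistical toolkit mirrors what hierarchy/stress studies report:
single-pass outlier removal within rank x stress cells, Pearson
correlations with Fisher-z confidence intervals, Student t-tests,
2x2 chi-square on hierarchy-property proportions, two-way factorial
ANOVA (Type-III partial sums of squares with sum-to-zero coding, since
real designs are unbalanced) with Sidak-adjusted within-cell contrasts,
and one-way ANOVA with Tukey-style all-pairs contrasts from the
studentized-range distribution.

Distribution functions come from scipy and the factorial fit from
statsmodels; the assembly of contrasts, adjustments and the outlier rule
is defined here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ADJ_NONE = "none"
ADJ_SIDAK = "sidak"
ADJ_TUKEY = "tukey"
ADJ_TUKEY_APPROX = "tukey_approx"


class DegenerateDataError(ValueError):
    """Input has no variance (or too little structure) for the requested test."""


@dataclass
class StatResult:
    """One test or contrast, in the shape results are reported.

    ``df`` is a float for single-df tests and an ``(df1, df2)`` pair for
    F statistics; the CI bounds are None when the test defines none.
    """

    statistic_name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    n: int
    ci_low: float | None = None
    ci_high: float | None = None
    adjustment: str = ADJ_NONE
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if (
            self.ci_low is not None
            and self.ci_high is not None
            and self.ci_low > self.ci_high
        ):
            raise ValueError("ci_low exceeds ci_high")

    def to_row(self) -> dict:
        df1, df2 = (self.df if isinstance(self.df, tuple) else (self.df, None))
        return {
            "label": self.label,
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "df1": df1,
            "df2": df2,
            "p_value": self.p_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
            "adjustment": self.adjustment,
        }


def results_table(results: Sequence[StatResult]) -> pd.DataFrame:
    """Tidy one-row-per-test CSV-ready table."""
    return pd.DataFrame([r.to_row() for r in results])


# -- outlier filtering ------------------------------------------------


def remove_outliers(
    df: pd.DataFrame,
    value_col: str,
    group_cols: Sequence[str] = ("rank_class", "stress_condition"),
    sd_threshold: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass outlier removal within each group.

    A value is removed iff ``|value - group mean| > sd_threshold * group
    SD`` (strict; mean and SD include the value; sample SD, ddof=1).
    Applied once, not iterated. Groups with fewer than 3 values pass
    through unfiltered with a warning entry in the log.

    Returns ``(filtered_df, log)``; the log has one row per removed value
    plus one per skipped-small group (``action`` column distinguishes).
    """
    keep_mask = pd.Series(True, index=df.index)
    log_rows: list[dict] = []
    for keys, grp in df.groupby(list(group_cols), dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        vals = grp[value_col].astype(float)
        if vals.notna().sum() < 3:
            log_rows.append(
                dict(zip(group_cols, keys))
                | {"action": "group_too_small", value_col: np.nan,
                   "n_group": int(vals.notna().sum())}
            )
            continue
        mean = vals.mean()
        sd = vals.std(ddof=1)
        if sd == 0:
            continue
        out = (vals - mean).abs() > sd_threshold * sd
        for idx in grp.index[out.fillna(False)]:
            keep_mask.loc[idx] = False
            log_rows.append(
                dict(zip(group_cols, keys))
                | {"action": "removed", value_col: float(df.loc[idx, value_col]),
                   "n_group": int(len(grp))}
            )
    log = pd.DataFrame(
        log_rows, columns=list(group_cols) + ["action", value_col, "n_group"]
    )
    return df[keep_mask], log


# -- correlations ------------------------------------------------------


def pearson_ci(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> StatResult:
    """Pearson correlation with two-sided p (t transform) and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = len(x)
    if n < 3:
        raise DegenerateDataError("Pearson correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("constant input has no defined correlation")
    r, p = sps.pearsonr(x, y)
    dof = n - 2
    # Fisher z interval; degenerate at |r| = 1
    if abs(r) >= 1.0:
        lo = hi = r
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zcrit = sps.norm.ppf(1 - alpha / 2)
        lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return StatResult(
        statistic_name="r", statistic=float(r), df=float(dof),
        p_value=float(p), n=n, ci_low=float(lo), ci_high=float(hi),
    )


# -- t tests -----------------------------------------------------------


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    alpha: float = 0.05,
) -> StatResult:
    """Student's t-test (pooled variance when unpaired) with a mean-difference CI.

    Zero-variance degenerate cases (e.g. paired arms differing by an
    exact constant) raise instead of returning an infinite statistic,
    except the fully null case of an exactly zero difference with zero
    spread, which is reported as t=0, p=1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and len(a) != len(b):
        raise ValueError("paired arms must have equal length")
    if len(a) < 2 or len(b) < 2:
        raise DegenerateDataError("each arm needs n >= 2")
    if paired:
        d = a - b
        n = len(d)
        dof = n - 1
        diff = d.mean()
        se = d.std(ddof=1) / np.sqrt(n)
        name = "t_paired"
        n_total = n
    else:
        n1, n2 = len(a), len(b)
        dof = n1 + n2 - 2
        diff = a.mean() - b.mean()
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / dof
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        name = "t"
        n_total = n1 + n2
    if se == 0:
        if diff == 0:
            return StatResult(
                statistic_name=name, statistic=0.0, df=float(dof),
                p_value=1.0, n=n_total, ci_low=0.0, ci_high=0.0,
            )
        raise DegenerateDataError(
            "zero within-arm variance with a nonzero difference: "
            "t statistic undefined"
        )
    t = diff / se
    p = 2 * sps.t.sf(abs(t), dof)
    tcrit = sps.t.ppf(1 - alpha / 2, dof)
    return StatResult(
        statistic_name=name, statistic=float(t), df=float(dof),
        p_value=float(p), n=n_total,
        ci_low=float(diff - tcrit * se), ci_high=float(diff + tcrit * se),
    )


# -- chi-square --------------------------------------------------------


def chi_square_2x2(counts: Sequence[Sequence[float]]) -> StatResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df=1."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("counts must form a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateDataError("a zero marginal leaves expected counts undefined")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return StatResult(
        statistic_name="chi2", statistic=float(chi2), df=float(dof),
        p_value=float(p), n=int(table.sum()),
    )


# -- factorial comparison ----------------------------------------------


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment: ``1 - (1 - p)^m`` (identity at m=1)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(1 - (1 - p) ** m)


@dataclass
class FactorialResult:
    """Two-way ANOVA main effects + interaction plus within-cell contrasts."""

    effects: dict[str, StatResult]
    contrasts: list[StatResult] = field(default_factory=list)

    def all_results(self) -> list[StatResult]:
        return list(self.effects.values()) + self.contrasts


def _cell_means_fit(df: pd.DataFrame, value: str, fa: str, fb: str):
    """OLS fit of the full two-factor cell-means model via statsmodels."""
    import statsmodels.formula.api as smf

    data = df[[value, fa, fb]].dropna().copy()
    data = data.rename(columns={value: "_y", fa: "_fa", fb: "_fb"})
    model = smf.ols("_y ~ C(_fa, Sum) * C(_fb, Sum)", data=data).fit()
    return model, data


def factorial_compare(
    df: pd.DataFrame,
    value: str,
    factor_a: str = "stress_condition",
    factor_b: str = "rank_class",
    alpha: float = 0.05,
) -> FactorialResult:
    """Two-way factorial ANOVA with within-``factor_b`` contrasts on ``factor_a``.

    Fits the full two-factor model by least squares with sum-to-zero
    coding and reports Type-III (partial) F tests for both main effects
    and the interaction — the decomposition that remains interpretable
    for the unbalanced cell sizes real cohorts produce. Within each level
    of ``factor_b`` the two levels of ``factor_a`` are contrasted with a
    t-test on the pooled residual mean square; contrast p-values and CIs
    carry a Sidak family-wise adjustment over the ``factor_b`` levels.
    """
    from statsmodels.stats.anova import anova_lm

    levels_a = sorted(df[factor_a].dropna().unique())
    levels_b = sorted(df[factor_b].dropna().unique())
    if len(levels_b) == 1 and len(levels_a) == 2:
        # single cell row: the design collapses to a two-sample comparison
        data = df.dropna(subset=[value])
        res = two_sample_t(
            data[data[factor_a] == levels_a[0]][value],
            data[data[factor_a] == levels_a[1]][value],
        )
        f_stat = StatResult(
            statistic_name="F", statistic=res.statistic**2,
            df=(1.0, res.df), p_value=res.p_value, n=res.n, label=factor_a,
        )
        res.adjustment = ADJ_SIDAK  # m=1: identity
        res.label = f"{levels_a[0]} vs {levels_a[1]} within {levels_b[0]}"
        return FactorialResult(effects={factor_a: f_stat}, contrasts=[res])
    counts = df.dropna(subset=[value]).groupby([factor_a, factor_b]).size()
    for la in levels_a:
        for lb in levels_b:
            if counts.get((la, lb), 0) < 2:
                raise DegenerateDataError(
                    f"cell ({la}, {lb}) has fewer than 2 observations"
                )
    model, data = _cell_means_fit(df, value, factor_a, factor_b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(model, typ=3)
    resid_df = float(model.df_resid)
    mse = float(model.mse_resid)
    n_total = int(model.nobs)

    def _effect(row_name: str, label: str) -> StatResult:
        row = table.loc[row_name]
        return StatResult(
            statistic_name="F", statistic=float(row["F"]),
            df=(float(row["df"]), resid_df), p_value=float(row["PR(>F)"]),
            n=n_total, label=label,
        )

    effects = {
        factor_a: _effect("C(_fa, Sum)", factor_a),
        factor_b: _effect("C(_fb, Sum)", factor_b),
        "interaction": _effect(
            "C(_fa, Sum):C(_fb, Sum)", f"{factor_a} x {factor_b}"
        ),
    }

    contrasts: list[StatResult] = []
    if len(levels_a) == 2:
        m = len(levels_b)
        alpha_adj = 1 - (1 - alpha) ** (1 / m)
        tcrit = sps.t.ppf(1 - alpha_adj / 2, resid_df)
        for lb in levels_b:
            cell = data[data["_fb"] == lb]
            g1 = cell[cell["_fa"] == levels_a[0]]["_y"]
            g2 = cell[cell["_fa"] == levels_a[1]]["_y"]
            diff = g1.mean() - g2.mean()
            se = np.sqrt(mse * (1 / len(g1) + 1 / len(g2)))
            t = diff / se
            p_raw = 2 * sps.t.sf(abs(t), resid_df)
            contrasts.append(
                StatResult(
                    statistic_name="t", statistic=float(t), df=resid_df,
                    p_value=sidak_adjust(p_raw, m), n=int(len(g1) + len(g2)),
                    ci_low=float(diff - tcrit * se),
                    ci_high=float(diff + tcrit * se),
                    adjustment=ADJ_SIDAK,
                    label=f"{levels_a[0]} vs {levels_a[1]} within {lb}",
                )
            )
    return FactorialResult(effects=effects, contrasts=contrasts)


# -- one-way comparison ------------------------------------------------


@dataclass
class OneWayResult:
    omnibus: StatResult
    contrasts: list[StatResult] = field(default_factory=list)

    def all_results(self) -> list[StatResult]:
        return [self.omnibus] + self.contrasts


@lru_cache(maxsize=256)
def _studentized_range_crit(alpha: float, k: int, df: float) -> float:
    return float(sps.studentized_range.ppf(1 - alpha, k, df))


def one_way_compare(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    include_contrasts: bool = True,
) -> OneWayResult:
    """One-way ANOVA with Tukey-style all-pairs contrasts.

    The omnibus F comes from the usual between/within sums of squares.
    Pairwise contrasts use the studentized-range distribution
    (Tukey-Kramer for unequal n); if the studentized-range computation
    fails to converge the contrast falls back to a Sidak-adjusted t and
    is labelled ``tukey_approx``.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for name, arr in zip(names, arrays):
        if len(arr) < 2:
            raise DegenerateDataError(f"group {name!r} has n < 2")
    k = len(arrays)
    ns = np.array([len(a) for a in arrays])
    n_total = int(ns.sum())
    grand = np.concatenate(arrays).mean()
    means = np.array([a.mean() for a in arrays])
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b, df_w = k - 1, n_total - k
    mse = ss_within / df_w
    if mse == 0:
        if ss_between == 0:
            omnibus = StatResult(
                statistic_name="F", statistic=0.0, df=(float(df_b), float(df_w)),
                p_value=1.0, n=n_total,
            )
            return OneWayResult(omnibus=omnibus)
        raise DegenerateDataError("zero within-group variance with distinct means")
    f = (ss_between / df_b) / mse
    p = sps.f.sf(f, df_b, df_w)
    omnibus = StatResult(
        statistic_name="F", statistic=float(f), df=(float(df_b), float(df_w)),
        p_value=float(p), n=n_total,
    )
    contrasts: list[StatResult] = []
    if not include_contrasts:
        return OneWayResult(omnibus=omnibus)
    m_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se_q = np.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[j]))
            q = abs(diff) / se_q
            adjustment = ADJ_TUKEY
            try:
                p_adj = float(sps.studentized_range.sf(q, k, df_w))
                qcrit = _studentized_range_crit(alpha, k, float(df_w))
                if not np.isfinite(p_adj) or not np.isfinite(qcrit):
                    raise FloatingPointError
            except Exception:
                # Sidak fallback over all pairs, flagged as approximate
                se_t = np.sqrt(mse * (1 / ns[i] + 1 / ns[j]))
                t = diff / se_t
                p_adj = sidak_adjust(2 * sps.t.sf(abs(t), df_w), m_pairs)
                alpha_adj = 1 - (1 - alpha) ** (1 / m_pairs)
                qcrit = float(sps.t.ppf(1 - alpha_adj / 2, df_w)) * np.sqrt(2)
                adjustment = ADJ_TUKEY_APPROX
            half_width = qcrit * se_q
            contrasts.append(
                StatResult(
                    statistic_name="q", statistic=float(q), df=float(df_w),
                    p_value=min(1.0, p_adj), n=int(ns[i] + ns[j]),
                    ci_low=float(diff - half_width),
                    ci_high=float(diff + half_width),
                    adjustment=adjustment,
                    label=f"{names[i]} vs {names[j]}",
                )
            )
    return OneWayResult(omnibus=omnibus, contrasts=contrasts)
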