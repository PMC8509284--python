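"""Group-level statistical reporting.

Mirrors a conventional small-animal imaging analysis: normality screening
by Shapiro-Wilk, three-group comparisons by one-way ANOVA with Tukey's HSD
post hoc test, two-group comparisons by the (equal-variance) unpaired
t-test, longitudinal within-group changes by the paired t-test, and tables
of mean ± standard error of the mean with star-style significance flags
(p < 0.05 / 0.01 / 0.001).

The normality check is reported but never blocks the pipeline; Tukey
pairwise p-values are always reported, with a flag noting whether the
omnibus F-test cleared the gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "compare_groups",
    "summary_table",
    "significance_flag",
    "sem",
]


def sem(values) -> float:
    """Standard error of the mean, sd (n-1 denominator) / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    return float(v.std(ddof=1) / np.sqrt(v.size))


def significance_flag(p: float) -> str:
    """Star notation: *** p<0.001, ** p<0.01, * p<0.05, '' otherwise."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupComparison:
    """One statistical test with the group summaries it compared."""

    metric: str
    groups: tuple[str, ...]
    test: str  # shapiro_wilk | anova | tukey | t_unpaired | t_paired
    statistic: float
    p_value: float
    means: dict[str, float]
    sems: dict[str, float]
    ns: dict[str, int]
    note: str = ""

    @property
    def flag(self) -> str:
        return significance_flag(self.p_value)

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            "test": self.test,
            "groups": " vs ".join(self.groups),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "flag": self.flag,
            "note": self.note,
        }


def _summaries(samples: dict[str, np.ndarray]):
    means = {g: float(np.mean(v)) for g, v in samples.items()}
    sems_ = {g: sem(v) for g, v in samples.items()}
    ns = {g: int(np.asarray(v).size) for g, v in samples.items()}
    return means, sems_, ns


def compare_groups(
    samples: dict[str, "np.ndarray"],
    design: str | None = None,
    metric: str = "",
    equal_var: bool = True,
    gate_alpha: float = 0.05,
    shapiro: bool = True,
) -> list[GroupComparison]:
    """Run the comparison battery appropriate for the design.

    ``design`` is ``"3-group"`` (one-way ANOVA + Tukey HSD on all pairs),
    ``"2-group"`` (unpaired t-test; Welch via ``equal_var=False``) or
    ``"paired"`` (paired t-test on two matched samples).  If omitted it is
    inferred from the number of groups (paired must be explicit).
    """
    samples = {g: np.asarray(v, dtype=float) for g, v in samples.items()}
    for g, v in samples.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs at least 2 observations, has {v.size}")
    if design is None:
        design = "3-group" if len(samples) >= 3 else "2-group"
    if design not in ("3-group", "2-group", "paired"):
        raise ValueError(f"unknown design {design!r}")

    names = list(samples)
    means, sems_, ns = _summaries(samples)
    out: list[GroupComparison] = []

    if shapiro:
        for g, v in samples.items():
            if np.ptp(v) == 0:  # Shapiro is undefined for constant data
                w, p = np.nan, np.nan
            else:
                w, p = stats.shapiro(v)
            out.append(
                GroupComparison(
                    metric=metric, groups=(g,), test="shapiro_wilk",
                    statistic=float(w), p_value=float(p),
                    means={g: means[g]}, sems={g: sems_[g]}, ns={g: ns[g]},
                    note="normality screen (reported, non-blocking)",
                )
            )

    if design == "3-group":
        if len(samples) < 3:
            raise ValueError("3-group design needs at least three groups")
        arrays = [samples[g] for g in names]
        f, p_f = stats.f_oneway(*arrays)
        out.append(
            GroupComparison(
                metric=metric, groups=tuple(names), test="anova",
                statistic=float(f), p_value=float(p_f),
                means=means, sems=sems_, ns=ns,
            )
        )
        gated = p_f < gate_alpha
        res = stats.tukey_hsd(*arrays)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                out.append(
                    GroupComparison(
                        metric=metric, groups=(names[i], names[j]), test="tukey",
                        statistic=float(res.statistic[i, j]),
                        p_value=float(res.pvalue[i, j]),
                        means={names[i]: means[names[i]], names[j]: means[names[j]]},
                        sems={names[i]: sems_[names[i]], names[j]: sems_[names[j]]},
                        ns={names[i]: ns[names[i]], names[j]: ns[names[j]]},
                        note="" if gated else f"omnibus F not significant (p={p_f:.3g})",
                    )
                )
    elif design == "2-group":
        if len(samples) != 2:
            raise ValueError("2-group design needs exactly two groups")
        a, b = (samples[g] for g in names)
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        out.append(
            GroupComparison(
                metric=metric, groups=tuple(names),
                test="t_unpaired" + ("" if equal_var else "_welch"),
                statistic=float(t), p_value=float(p),
                means=means, sems=sems_, ns=ns,
            )
        )
    else:  # paired
        if len(samples) != 2:
            raise ValueError("paired design needs exactly two matched samples")
        a, b = (samples[g] for g in names)
        if a.size != b.size:
            raise ValueError(f"paired samples must be matched in length ({a.size} vs {b.size})")
        t, p = stats.ttest_rel(a, b)
        out.append(
            GroupComparison(
                metric=metric, groups=tuple(names), test="t_paired",
                statistic=float(t), p_value=float(p),
                means=means, sems=sems_, ns=ns,
            )
        )
    return out


def comparisons_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flat, diffable table of test results."""
    return pd.DataFrame([c.to_row() for c in comparisons])


def summary_table(
    long_df: pd.DataFrame,
    value_col: str = "value",
    row_cols: tuple[str, ...] = ("metric",),
    col_cols: tuple[str, ...] = ("group",),
    p_values: dict | None = None,
    precision: int = 4,
) -> pd.DataFrame:
    """Mean ± SEM report in the style of a results table.

    ``long_df`` holds one observation per row.  Cells are formatted as
    ``mean ± SEM`` with a significance flag appended when ``p_values``
    provides a p-value for that (row key, column key) cell.  Ordering
    follows first appearance in the input, so output is deterministic.
    """
    p_values = p_values or {}

    def key(df, cols):
        return list(df[list(cols)].itertuples(index=False, name=None))

    rows = list(dict.fromkeys(key(long_df, row_cols)))
    cols = list(dict.fromkeys(key(long_df, col_cols)))
    table = {}
    grouped = long_df.groupby(list(row_cols) + list(col_cols), sort=False)[value_col]
    agg = grouped.agg(["mean", "count", lambda v: sem(v) if len(v) > 1 else np.nan])
    agg.columns = ["mean", "n", "sem"]
    for r in rows:
        line = {}
        for c in cols:
            k = r + c
            k = k if len(k) > 1 else k[0]
            if k in agg.index:
                m, _, s = agg.loc[k]
                cell = f"{m:.{precision}g} ± {s:.{precision}g}" if np.isfinite(s) else f"{m:.{precision}g}"
                flag = significance_flag(p_values.get((r, c), np.nan))
                if flag:
                    cell += f" {flag}"
            else:
                cell = ""
            line[" / ".join(map(str, c))] = cell
        table[" / ".join(map(str, r))] = line
    return pd.DataFrame.from_dict(table, orient="index")
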