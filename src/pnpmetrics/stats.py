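"""Group comparisons and regression reporting for the measurement tables.

This module owns the grouping, pairing, unit-of-analysis aggregation and
output formatting; the classical tests themselves (t, paired t,
Mann-Whitney, one-way ANOVA with Tukey post-hoc, Pearson, OLS/F) are
delegated to scipy.stats and statsmodels.

Unit-of-analysis is enforced: when the declared unit is the embryo but the
table carries nucleus- or ablation-level rows, rows are first aggregated to
per-embryo means within each group.  Treating thousands of nuclei from a
handful of embryos as independent observations (pseudo-replication) wildly
overstates significance; the embryo is the independent biological replicate.

Reporting conventions: parametric comparisons are summarised as mean +/- SD,
non-parametric ones as box-plot quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ComparisonSpec",
    "ComparisonResult",
    "RegressionResult",
    "run_comparison",
    "regression_scatter",
    "plot_comparison",
]

TestName = Literal["t", "paired-t", "mann-whitney", "anova+tukey", "pearson", "linear-regression-F"]

PARAMETRIC = {"t", "paired-t", "anova+tukey", "pearson", "linear-regression-F"}


@dataclass(frozen=True)
class ComparisonSpec:
    """What to compare and how.

    ``unit_of_analysis`` names the independent replicate; if it differs from
    the table's row granularity, rows are aggregated to its mean first
    (requires an identifier column of that name, e.g. ``embryo``).
    """

    measure: str
    grouping: str
    test: TestName
    unit_of_analysis: str = "embryo"
    pair_on: str | None = None


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    p: float
    n_per_group: dict[str, int]
    effect_direction: str
    group_summaries: pd.DataFrame
    posthoc: pd.DataFrame | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    f_p: float
    x_grid: np.ndarray
    y_fit: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int


def _aggregate(table: pd.DataFrame, spec: ComparisonSpec) -> pd.DataFrame:
    """Collapse to one row per unit of analysis within each group."""
    unit = spec.unit_of_analysis
    if unit in table.columns:
        keys = [spec.grouping, unit]
        if spec.pair_on and spec.pair_on not in keys:
            keys.append(spec.pair_on)
        return table.groupby(keys, as_index=False)[spec.measure].mean()
    return table


def _summaries(groups: dict[str, np.ndarray], parametric: bool) -> pd.DataFrame:
    rows = []
    for name, vals in groups.items():
        row: dict[str, object] = {"group": name, "n": len(vals)}
        if parametric:
            row["mean"] = float(np.mean(vals))
            row["sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
        else:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            row.update(median=float(med), q1=float(q1), q3=float(q3))
        rows.append(row)
    return pd.DataFrame(rows)


def run_comparison(table: pd.DataFrame, spec: ComparisonSpec) -> ComparisonResult:
    """Run the named comparison on a measurement table.

    Raises on groups with fewer than two units, on paired tests with
    incomplete pairs, and on ANOVA with fewer than three groups.
    """
    if spec.measure not in table.columns or spec.grouping not in table.columns:
        raise ValueError(f"table lacks {spec.measure!r} or {spec.grouping!r}")
    data = _aggregate(table.dropna(subset=[spec.measure]), spec)

    if spec.test == "pearson":
        x = data[spec.grouping].to_numpy(float)
        y = data[spec.measure].to_numpy(float)
        r, p = sps.pearsonr(x, y)
        return ComparisonResult(
            test="pearson",
            statistic=float(r),
            p=float(p),
            n_per_group={"all": len(x)},
            effect_direction="negative" if r < 0 else "positive",
            group_summaries=pd.DataFrame({"group": ["all"], "n": [len(x)]}),
        )
    if spec.test == "linear-regression-F":
        reg = regression_scatter(
            data[spec.grouping].to_numpy(float), data[spec.measure].to_numpy(float)
        )
        return ComparisonResult(
            test="linear-regression-F",
            statistic=float(reg.r2),
            p=float(reg.f_p),
            n_per_group={"all": reg.n},
            effect_direction="negative" if reg.slope < 0 else "positive",
            group_summaries=pd.DataFrame({"group": ["all"], "n": [reg.n]}),
        )

    groups = {
        str(name): grp[spec.measure].to_numpy(float)
        for name, grp in data.groupby(spec.grouping)
    }
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has n={len(vals)} < 2")

    parametric = spec.test in PARAMETRIC
    summaries = _summaries(groups, parametric)
    names = list(groups)
    flags: list[str] = []
    posthoc = None

    if spec.test in ("t", "mann-whitney"):
        if len(names) != 2:
            raise ValueError(f"{spec.test} requires exactly 2 groups, got {len(names)}")
        a, b = groups[names[0]], groups[names[1]]
        if spec.test == "t":
            stat, p = sps.ttest_ind(a, b)
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        direction = f"{names[0]} > {names[1]}" if np.mean(a) > np.mean(b) else f"{names[1]} > {names[0]}"
    elif spec.test == "paired-t":
        if len(names) != 2:
            raise ValueError("paired-t requires exactly 2 groups")
        pair_key = spec.pair_on or spec.unit_of_analysis
        wide = data.pivot_table(index=pair_key, columns=spec.grouping, values=spec.measure)
        wide = wide.dropna()
        if wide.empty:
            raise ValueError("no complete pairs")
        a, b = wide[names[0]].to_numpy(), wide[names[1]].to_numpy()
        diffs = a - b
        if np.allclose(diffs, 0):
            stat, p = 0.0, 1.0
            flags.append("no_difference")
        else:
            stat, p = sps.ttest_rel(a, b)
        direction = f"{names[0]} > {names[1]}" if np.mean(diffs) > 0 else f"{names[1]} > {names[0]}"
        summaries = _summaries({names[0]: a, names[1]: b}, True)
        groups = {names[0]: a, names[1]: b}
    elif spec.test == "anova+tukey":
        if len(names) < 3:
            raise ValueError("ANOVA requires >= 3 groups")
        stat, p = sps.f_oneway(*groups.values())
        tuk = pairwise_tukeyhsd(
            np.concatenate(list(groups.values())),
            np.concatenate([[n] * len(v) for n, v in groups.items()]),
        )
        posthoc = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
        means = {n: float(np.mean(v)) for n, v in groups.items()}
        direction = " > ".join(sorted(means, key=means.get, reverse=True))
    else:
        raise ValueError(f"unknown test {spec.test!r}")

    return ComparisonResult(
        test=spec.test,
        statistic=float(stat),
        p=float(p),
        n_per_group={n: len(v) for n, v in groups.items()},
        effect_direction=direction,
        group_summaries=summaries,
        posthoc=posthoc,
        flags=tuple(flags),
    )


def plot_comparison(
    table: pd.DataFrame,
    spec: ComparisonSpec,
    result: ComparisonResult,
    path,
) -> None:
    """Plot a comparison in the reporting convention of its test.

    Parametric comparisons are drawn as per-group points with mean +/- SD
    bars; non-parametric ones as box plots.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = _aggregate(table.dropna(subset=[spec.measure]), spec)
    groups = {
        str(name): grp[spec.measure].to_numpy(float)
        for name, grp in data.groupby(spec.grouping)
    }
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(groups), 3.2))
    if spec.test in PARAMETRIC:
        for i, (name, vals) in enumerate(groups.items()):
            ax.plot(np.full(len(vals), i), vals, "o", color="0.6", ms=4, zorder=1)
            ax.errorbar(
                i, np.mean(vals), yerr=np.std(vals, ddof=1) if len(vals) > 1 else 0.0,
                fmt="_", color="k", capsize=6, elinewidth=1.5, zorder=2,
            )
        ax.set_xticks(range(len(groups)), list(groups))
    else:
        ax.boxplot(list(groups.values()), tick_labels=list(groups))
    ax.set_ylabel(spec.measure)
    ax.set_title(f"{result.test}: p = {result.p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def regression_scatter(x: np.ndarray, y: np.ndarray, ci_points: int = 100) -> RegressionResult:
    """Ordinary least squares of y on x with an F test and a 95% CI band.

    Returns r^2 (identical to the squared Pearson correlation), the F-test
    p-value, and a confidence band for the mean response suitable for
    shading around the fitted line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 points for a regression")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    grid = np.linspace(x.min(), x.max(), ci_points)
    pred = model.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        f_p=float(model.f_pvalue),
        x_grid=grid,
        y_fit=pred["mean"].to_numpy(),
        ci_low=pred["mean_ci_lower"].to_numpy(),
        ci_high=pred["mean_ci_upper"].to_numpy(),
        n=len(x),
    )
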