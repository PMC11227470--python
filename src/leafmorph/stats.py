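"""Inferential layer: normality screening and two-sample comparisons.

Rule: Shapiro-Wilk on each sample; if both pass at alpha the two-tailed
Welch t-test (unequal variances) is used, otherwise the two-sided
Mann-Whitney U test. The path taken is recorded in the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from leafmorph.errors import ConfigurationError, IncompleteDesignError

log = logging.getLogger(__name__)

__all__ = [
    "TestReport",
    "compare_groups",
    "build_summary",
    "format_summary_markdown",
    "PopulationSummary",
]


@dataclass
class TestReport:
    """Outcome of one two-sample comparison."""

    variable: str
    groups: tuple
    test: str  # "welch-t" or "mann-whitney"
    statistic: float
    p_value: float
    alpha: float
    significant: bool
    shapiro_p: tuple  # per-group normality p-values (nan if degenerate)

    def as_dict(self) -> dict:
        return {
            "variable": self.variable,
            "group1": self.groups[0],
            "group2": self.groups[1],
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "significant": self.significant,
            "shapiro_p1": self.shapiro_p[0],
            "shapiro_p2": self.shapiro_p[1],
        }


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return float("nan")
    return float(sps.shapiro(x).pvalue)


def compare_groups(
    x,
    y,
    alpha: float = 0.05,
    variable: str = "",
    groups: tuple = ("group1", "group2"),
    force_test: str | None = None,
) -> TestReport:
    """Screen-then-select two-sample comparison.

    ``force_test`` ("t" or "mw") bypasses the normality screen to reproduce
    a fixed per-variable test choice.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ConfigurationError("each sample needs at least 3 observations")
    p_norm = (_shapiro_p(x), _shapiro_p(y))
    if force_test is None:
        degenerate = any(np.isnan(p) for p in p_norm)
        if degenerate:
            log.warning("constant sample in %s: falling back to Mann-Whitney", variable)
            use_t = False
        else:
            use_t = all(p >= alpha for p in p_norm)
    elif force_test in ("t", "welch-t"):
        use_t = True
    elif force_test in ("mw", "mann-whitney"):
        use_t = False
    else:
        raise ConfigurationError(f"unknown force_test {force_test!r}")

    if use_t:
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x.mean() == y.mean():
            stat, p = 0.0, 1.0
        else:
            res = sps.ttest_ind(x, y, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
        test = "welch-t"
    else:
        if np.array_equal(np.sort(x), np.sort(y)):
            stat, p = float(len(x) * len(y) / 2.0), 1.0
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        test = "mann-whitney"
    return TestReport(
        variable=variable,
        groups=tuple(groups),
        test=test,
        statistic=stat,
        p_value=p,
        alpha=alpha,
        significant=bool(p < alpha),
        shapiro_p=p_norm,
    )


@dataclass
class PopulationSummary:
    """Per-category descriptive table, ratio statistics and test reports."""

    leaf_table: pd.DataFrame  # rows: node x treatment; mean +- SD of area, e_d, epsilon_a
    pair_table: pd.DataFrame  # rows: node x category; means of delta_area, d_avg, d_max, D2
    ratios: dict
    tests: list = field(default_factory=list)

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.as_dict() for t in self.tests])


def format_summary_markdown(summary: "PopulationSummary") -> str:
    """Human-readable summary; percent-style metrics rendered x100."""
    lines = ["# Study summary", "", "## Per-leaf (mean ± SD)", ""]
    lines.append("| node | treatment | n | area [cm²] | e_d [pts] | ε_a [%] |")
    lines.append("|---|---|---|---|---|---|")
    for _, r in summary.leaf_table.iterrows():
        lines.append(
            f"| {r['node']} | {r['treatment']} | {int(r['n'])} "
            f"| {r['area_cm2_mean']:.2f} ± {r['area_cm2_sd']:.2f} "
            f"| {r['e_d_mean']:.2f} ± {r['e_d_sd']:.2f} "
            f"| {100 * r['epsilon_a_mean']:.2f} ± {100 * r['epsilon_a_sd']:.2f} |"
        )
    lines += ["", "## Per-pair (means)", ""]
    lines.append("| node | category | n pairs | Δarea [%] | d_avg [pts] | d_max [pts] | D² |")
    lines.append("|---|---|---|---|---|---|---|")
    for _, r in summary.pair_table.iterrows():
        lines.append(
            f"| {r['node']} | {r['category']} | {int(r['n_pairs'])} "
            f"| {100 * r['delta_area_mean']:.2f} | {r['d_avg_mean']:.2f} "
            f"| {r['d_max_mean']:.2f} | {r['D2_mean']:.4f} |"
        )
    lines += ["", "## Ratio statistics", ""]
    for k, v in summary.ratios.items():
        lines.append(f"- {k} = {v:.4f}")
    lines += ["", "## Tests", ""]
    lines.append("| variable | test | p | significant |")
    lines.append("|---|---|---|---|")
    for t in summary.tests:
        lines.append(f"| {t.variable} | {t.test} | {t.p_value:.4g} | {'yes' if t.significant else 'no'} |")
    return "\n".join(lines) + "\n"


def _require_cells(df: pd.DataFrame, cols: list, expected: set, what: str) -> None:
    have = set(map(tuple, df[cols].drop_duplicates().itertuples(index=False)))
    missing = expected - have
    if missing:
        raise IncompleteDesignError(f"missing {what} cells: {sorted(missing)}")


def build_summary(
    measurements: pd.DataFrame,
    pairs: pd.DataFrame,
    ratios: dict,
    alpha: float = 0.05,
    force_test: str | None = None,
) -> PopulationSummary:
    """Aggregate per-leaf and per-pair results and run the test battery.

    ``measurements`` needs columns node, treatment, area_cm2, e_d,
    epsilon_a (node labels case-insensitive); ``pairs`` needs node,
    category (cc/ct), delta_area, d_avg, d_max, D2.
    """
    meas = measurements.copy()
    meas["node"] = meas["node"].str.lower()
    nodes = sorted(meas["node"].unique())
    _require_cells(
        meas, ["node", "treatment"],
        {(n, t) for n in nodes for t in ("control", "touched")},
        "measurement",
    )

    leaf_rows = []
    for node in nodes:
        for treatment in ("control", "touched"):
            sel = meas[(meas["node"] == node) & (meas["treatment"] == treatment)]
            row = {"node": node, "treatment": treatment, "n": len(sel)}
            for var in ("area_cm2", "e_d", "epsilon_a"):
                row[f"{var}_mean"] = sel[var].mean()
                row[f"{var}_sd"] = sel[var].std(ddof=1)
                row[f"{var}_se"] = sel[var].std(ddof=1) / np.sqrt(len(sel))
            leaf_rows.append(row)
    leaf_table = pd.DataFrame(leaf_rows)

    pair_rows = []
    for (node, category), sel in pairs.groupby(["node", "category"]):
        row = {"node": node, "category": category, "n_pairs": len(sel)}
        for var in ("delta_area", "d_avg", "d_max", "D2"):
            row[f"{var}_mean"] = sel[var].mean()
            row[f"{var}_sd"] = sel[var].std(ddof=1)
        pair_rows.append(row)
    pair_table = pd.DataFrame(pair_rows).sort_values(["category", "node"]).reset_index(drop=True)

    tests = []
    for node in nodes:
        sel = meas[meas["node"] == node]
        ctrl = sel[sel["treatment"] == "control"]["area_cm2"]
        touch = sel[sel["treatment"] == "touched"]["area_cm2"]
        tests.append(
            compare_groups(
                ctrl, touch, alpha=alpha,
                variable=f"area_cm2[node={node}]",
                groups=("control", "touched"),
                force_test=force_test,
            )
        )
    for var in ("e_d", "epsilon_a"):
        ctrl = meas[meas["treatment"] == "control"][var]
        touch = meas[meas["treatment"] == "touched"][var]
        tests.append(
            compare_groups(
                ctrl, touch, alpha=alpha,
                variable=f"{var}[pooled]",
                groups=("control", "touched"),
                force_test=force_test,
            )
        )
        for node in nodes:
            sel = meas[meas["node"] == node]
            tests.append(
                compare_groups(
                    sel[sel["treatment"] == "control"][var],
                    sel[sel["treatment"] == "touched"][var],
                    alpha=alpha,
                    variable=f"{var}[node={node}]",
                    groups=("control", "touched"),
                    force_test=force_test,
                )
            )
    for var in ("d_avg", "d_max", "D2"):
        cc = pairs[pairs["category"] == "cc"][var]
        ct = pairs[pairs["category"] == "ct"][var]
        if len(cc) >= 3 and len(ct) >= 3:
            tests.append(
                compare_groups(
                    cc, ct, alpha=alpha,
                    variable=f"{var}[pairs]",
                    groups=("cc", "ct"),
                    force_test=force_test,
                )
            )

    return PopulationSummary(leaf_table, pair_table, dict(ratios), tests)
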