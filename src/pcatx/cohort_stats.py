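"""Table-1 style cohort comparisons.

Contingency-table tests (Pearson chi-square without continuity correction,
two-sided Fisher exact), the Mann-Whitney U rank test for skewed continuous
variables, percentage helpers, and a builder that renders a full baseline
characteristics table with per-variable tests and missing-data handling.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0,1]")


def _validate_table(table: np.ndarray) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("contingency table has negative counts")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    if (row_sums == 0).any():
        bad = np.flatnonzero(row_sums == 0).tolist()
        raise ValueError(f"contingency table has zero-sum rows at positions {bad}")
    if (col_sums == 0).any():
        bad = np.flatnonzero(col_sums == 0).tolist()
        raise ValueError(f"contingency table has zero-sum columns at positions {bad}")
    return arr


def chi_square_test(table) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction.

    ``df = (rows - 1) * (cols - 1)``; the P value comes from the chi-square
    survival function.
    """
    arr = _validate_table(table)
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return TestResult(statistic=float(stat), p_value=float(p), method="chi-square", df=int(df))


def fisher_exact_test(table) -> TestResult:
    """Two-sided Fisher exact test for a 2x2 table.

    The two-sided P sums hypergeometric probabilities of tables at most as
    probable as the observed one; the sample odds ratio is reported alongside.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"Fisher exact test requires a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("contingency table has negative counts")
    odds_ratio, p = stats.fisher_exact(arr, alternative="two-sided")
    return TestResult(
        statistic=float(odds_ratio),
        p_value=float(p),
        method="fisher-exact",
        extra={"odds_ratio": float(odds_ratio)},
    )


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when the combined sample size is at most 20 and
    there are no ties, otherwise the normal approximation with tie correction
    (no continuity correction, so the statistic matches the plain z formula).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if x.size + y.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=f"mann-whitney-{method}",
    )


def group_percentage(count: int, denom: int) -> float:
    """``100 * count / denom``; errors on a zero denominator."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= count <= denom):
        raise ValueError("count must lie in [0, denom]")
    return 100.0 * count / denom


def round1(value: float) -> float:
    """Round to one decimal with banker's (round-half-even) rounding."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


@dataclass
class VariableDescriptor:
    name: str
    kind: str  # "categorical" or "continuous"
    levels: Sequence[str] | None = None  # display/ordering for categorical

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"kind must be categorical or continuous, got {self.kind!r}")


def _choose_categorical_test(counts: np.ndarray) -> TestResult:
    # Fisher for 2x2 with any expected cell below 5; chi-square otherwise.
    if counts.shape == (2, 2):
        total = counts.sum()
        expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
        if (expected < 5).any():
            return fisher_exact_test(counts)
    return chi_square_test(counts)


def build_table_one(
    clinical: pd.DataFrame,
    variables: Sequence[VariableDescriptor],
    group_col: str = "group",
) -> pd.DataFrame:
    """Baseline-characteristics table with per-variable group comparison tests.

    Categorical variables get per-level counts and percentages per group plus
    a chi-square (or Fisher, for sparse 2x2) P value; continuous variables get
    median (IQR) per group plus a Mann-Whitney U P value.  Missing values are
    excluded per variable (listwise within the variable) and the analyzed n is
    reported.
    """
    if group_col not in clinical.columns:
        raise KeyError(f"group column {group_col!r} not in clinical table")
    group_labels = sorted(clinical[group_col].dropna().unique().tolist())
    if len(group_labels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {group_labels}")
    rows = []
    for var in variables:
        if var.name not in clinical.columns:
            raise KeyError(f"unknown clinical column {var.name!r}")
        sub = clinical[[group_col, var.name]].dropna()
        n_used = len(sub)
        if var.kind == "categorical":
            levels = list(var.levels) if var.levels else sorted(sub[var.name].unique())
            counts = np.array(
                [
                    [int(((sub[group_col] == g) & (sub[var.name] == lv)).sum()) for g in group_labels]
                    for lv in levels
                ]
            )
            test = _choose_categorical_test(counts)
            for i, lv in enumerate(levels):
                row = {
                    "variable": var.name,
                    "level": str(lv),
                    "n_analyzed": n_used,
                    "p_value": test.p_value if i == 0 else np.nan,
                    "test": test.method if i == 0 else "",
                }
                for j, g in enumerate(group_labels):
                    denom = int(counts[:, j].sum())
                    row[f"{g}_n"] = int(counts[i, j])
                    row[f"{g}_pct"] = round1(group_percentage(int(counts[i, j]), denom))
                rows.append(row)
        else:
            samples = {
                g: sub.loc[sub[group_col] == g, var.name].astype(float).to_numpy()
                for g in group_labels
            }
            test = mann_whitney_u(samples[group_labels[0]], samples[group_labels[1]])
            row = {
                "variable": var.name,
                "level": "median (IQR)",
                "n_analyzed": n_used,
                "p_value": test.p_value,
                "test": test.method,
            }
            for g in group_labels:
                vals = samples[g]
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                row[f"{g}_n"] = len(vals)
                row[f"{g}_summary"] = f"{med:.1f} ({q1:.1f}, {q3:.1f})"
            rows.append(row)
    return pd.DataFrame(rows)


def render_table_one_markdown(table: pd.DataFrame) -> str:
    """Markdown rendering of a :func:`build_table_one` result."""
    lines = ["| " + " | ".join(table.columns) + " |",
             "| " + " | ".join(["---"] * len(table.columns)) + " |"]
    for _, row in table.iterrows():
        cells = []
        for col in table.columns:
            v = row[col]
            if isinstance(v, float) and np.isnan(v):
                cells.append("")
            elif col == "p_value" and isinstance(v, float):
                cells.append(f"{v:.3g}")
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
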