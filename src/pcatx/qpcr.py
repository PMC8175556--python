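"""Delta-Ct quantification for qPCR validation.

Relative transcript abundance via the delta-Ct method: each sample's target
Ct is referenced to the arithmetic mean Ct of a housekeeping panel (the
arithmetic mean of Ct values corresponds to the geometric mean of linear
quantities), and relative expression is 2^(-dCt).  No amplification-efficiency
correction is applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from pcatx.cohort_stats import TestResult, mann_whitney_u


def delta_ct(ct: pd.DataFrame, target: str) -> pd.DataFrame:
    """Per-sample delta-Ct and relative expression of ``target``.

    ``ct`` is a tidy table with columns ``sample``, ``assay``, ``ct``,
    ``is_housekeeping``.  dCt = Ct_target - mean(housekeeping Ct) per sample;
    relative expression = 2^(-dCt).  Samples lacking a target Ct are omitted
    with a warning; samples lacking any housekeeping Ct are an error.
    """
    required = {"sample", "assay", "ct", "is_housekeeping"}
    if not required <= set(ct.columns):
        raise KeyError(f"Ct table lacks columns {sorted(required - set(ct.columns))}")
    if (ct["ct"] <= 0).any() or not np.isfinite(ct["ct"]).all():
        raise ValueError("Ct values must be finite and positive")
    hk = ct[ct["is_housekeeping"].astype(bool)]
    if hk.empty:
        raise ValueError("no housekeeping assays in Ct table")
    tgt = ct[(ct["assay"] == target) & ~ct["is_housekeeping"].astype(bool)]
    if tgt.empty:
        raise KeyError(f"target assay {target!r} not found")
    hk_mean = hk.groupby("sample")["ct"].mean()
    rows = []
    for _, row in tgt.iterrows():
        s = row["sample"]
        if s not in hk_mean.index:
            raise ValueError(f"sample {s!r} has no housekeeping Ct")
        d = row["ct"] - hk_mean[s]
        rows.append({"sample": s, "delta_ct": d, "rel_expr": 2.0 ** (-d)})
    missing = set(hk_mean.index) - set(tgt["sample"])
    if missing:
        warnings.warn(
            f"{len(missing)} sample(s) lack a Ct for {target!r} and were omitted"
        )
    return pd.DataFrame(rows).set_index("sample")


def group_compare_dct(rel_expr: pd.Series, groups: pd.Series) -> TestResult:
    """Two-group comparison of relative expression.

    Mann-Whitney U on the per-sample relative expression, plus the fold
    difference of group medians (group 1 over group 0) in ``extra``.
    """
    g = groups.reindex(rel_expr.index)
    if g.isna().any():
        raise ValueError("group label missing for some samples")
    x1 = rel_expr[g == 1].to_numpy(dtype=float)
    x0 = rel_expr[g == 0].to_numpy(dtype=float)
    if x1.size == 0 or x0.size == 0:
        raise ValueError("both groups must be non-empty")
    res = mann_whitney_u(x1, x0)
    med0 = float(np.median(x0))
    fold = float(np.median(x1) / med0) if med0 != 0 else np.inf
    res.extra = {"fold_median": fold}
    return res
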