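"""Covariate-adjusted per-feature logistic association and FDR control.

Each feature (a gene's expression or a pathway/drug score) is tested for
association with a binary group label via the multivariable logistic model

    logit P(group = 1) = b0 + b1*feature + b2*GG + b3*EPE + b4*SVI + b5*LNI

where GG is the ordinal grade group (1-5) and EPE / SVI / LNI are binary
pathologic-stage covariates (extraprostatic extension pT >= T3a, seminal
vesicle invasion pT >= T3b, lymph-node involvement pN = N1).  The Wald P
value of b1 is the per-feature P; q values come from Benjamini-Hochberg over
all features that produced a P.  A rank-based (Mann-Whitney / Wilcoxon)
differential-expression path and DE-list overlap utilities support
cross-cohort validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from pcatx.cohort_stats import mann_whitney_u

logger = logging.getLogger(__name__)

COVARIATE_COLS = ("gleason", "epe", "svi", "lni")

_PT_CODES = {"T2": (0, 0), "T3a": (1, 0), "T3b": (1, 1), "T4": (1, 1)}
_PN_CODES = {"N0": 0, "N1": 1, "NX": 0}

# A fitted standardized |coefficient| (per SD of the predictor) beyond this is
# treated as quasi-complete separation: an odds ratio past e^15 ~ 3e6 per
# predictor SD does not arise in a converged, well-posed cohort fit.
_SEPARATION_BETA = 15.0


@dataclass
class LogisticModel:
    """Fit summary for one multivariable logistic regression."""

    params: pd.Series
    bse: pd.Series
    p_values: pd.Series
    converged: bool
    n_used: int

    @property
    def beta1(self) -> float:
        return float(self.params.iloc[1])

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.params.iloc[1]))

    @property
    def p_beta1(self) -> float:
        return float(self.p_values.iloc[1])


def covariates_from_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Derive the logistic-model covariates from clinical stage codes.

    Returns a frame indexed by sample_id with columns ``gleason`` (ordinal
    1-5), ``epe``, ``svi``, ``lni``.  pT codes map T3a -> EPE, T3b -> EPE+SVI,
    T4 -> EPE+SVI; pN ``N1`` -> LNI=1, with ``N0``/``NX`` -> 0 (an unassessed
    nodal stage is treated as node-negative).  Samples missing grade group or
    pT get NaN covariates and are dropped downstream.
    """
    required = {"sample_id", "grade_group", "pt_stage", "pn_stage"}
    missing_cols = required - set(clinical.columns)
    if missing_cols:
        raise KeyError(f"clinical table lacks columns {sorted(missing_cols)}")
    pt = clinical["pt_stage"]
    unknown = sorted(set(pt.dropna().unique()) - set(_PT_CODES))
    if unknown:
        raise ValueError(f"unknown pT stage codes: {unknown}")
    pn = clinical["pn_stage"]
    unknown_pn = sorted(set(pn.dropna().unique()) - set(_PN_CODES))
    if unknown_pn:
        raise ValueError(f"unknown pN stage codes: {unknown_pn}")

    gleason = pd.to_numeric(clinical["grade_group"], errors="coerce")
    if ((gleason < 1) | (gleason > 5)).any():
        raise ValueError("grade_group values must lie in 1..5")
    epe = pt.map(lambda v: _PT_CODES[v][0] if pd.notna(v) else np.nan)
    svi = pt.map(lambda v: _PT_CODES[v][1] if pd.notna(v) else np.nan)
    lni = pn.map(lambda v: float(_PN_CODES[v]) if pd.notna(v) else 0.0)
    out = pd.DataFrame(
        {
            "gleason": gleason.to_numpy(dtype=float),
            "epe": epe.to_numpy(dtype=float),
            "svi": svi.to_numpy(dtype=float),
            "lni": lni.to_numpy(dtype=float),
        },
        index=pd.Index(clinical["sample_id"], name="sample_id"),
    )
    return out


def _fit_design(y: np.ndarray, design: np.ndarray, names: list[str]) -> LogisticModel:
    idx = pd.Index(names)
    n = len(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=PerfectSeparationWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        try:
            res = sm.Logit(y, design).fit(method="newton", maxiter=100, disp=0)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            nan = pd.Series(np.nan, index=idx)
            return LogisticModel(nan, nan, nan, converged=False, n_used=n)
    converged = bool(res.mle_retvals.get("converged", False))
    col_sd = design.std(axis=0)
    std_beta = np.abs(res.params[1:]) * col_sd[1:]
    if converged and std_beta.size and std_beta.max() > _SEPARATION_BETA:
        logger.warning("quasi-complete separation suspected (|beta| > %g)", _SEPARATION_BETA)
        converged = False
    return LogisticModel(
        params=pd.Series(res.params, index=idx),
        bse=pd.Series(res.bse, index=idx),
        p_values=pd.Series(res.pvalues, index=idx),
        converged=converged,
        n_used=n,
    )


def fit_logistic(y, x, cov: pd.DataFrame | None = None) -> LogisticModel:
    """Maximum-likelihood logistic fit of a binary outcome on one feature.

    ``y`` is 0/1 per sample, ``x`` the feature values, ``cov`` an optional
    frame of additional covariate columns aligned to the samples.  Newton
    (IRLS) optimization, at most 100 iterations; the Wald P value of the
    feature coefficient is the per-feature P.  Complete or quasi-complete
    separation is flagged via ``converged=False`` rather than raising.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes coded 0 and 1")
    cols = [np.ones_like(x), x]
    names = ["intercept", "feature"]
    if cov is not None:
        for c in cov.columns:
            cols.append(np.asarray(cov[c], dtype=float))
            names.append(c)
    design = np.column_stack(cols)
    if len(y) <= design.shape[1]:
        raise ValueError("need more samples than model parameters")
    return _fit_design(y, design, names)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (q values), capped at 1.

    ``q_(i) = min over j >= i of m * p_(j) / j`` in the sorted order,
    returned in the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("P values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def feature_association(
    features: pd.DataFrame,
    outcome: pd.Series,
    cov: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-feature covariate-adjusted logistic association scan.

    ``features`` is features x samples; ``outcome`` 0/1 per sample; ``cov``
    the covariate frame from :func:`covariates_from_clinical` (or None for an
    unadjusted scan).  Samples with any missing covariate are dropped once for
    the whole run so every feature sees the same n.  Constant features are
    excluded with ``converged=False`` and NaN P.  q values are BH-adjusted
    over all features that produced a P value; features without a P are
    reported but carry NaN q.

    Returns a frame indexed by feature with columns beta1, odds_ratio,
    p_value, q_value, n_used, converged.
    """
    if features.shape[0] < 1:
        raise ValueError("need at least one feature")
    samples = features.columns
    y_all = outcome.reindex(samples)
    if y_all.isna().any():
        raise ValueError("outcome missing for some expression samples")
    keep = np.ones(len(samples), dtype=bool)
    cov_mat = None
    if cov is not None:
        cov_al = cov.reindex(samples)
        keep &= ~cov_al.isna().any(axis=1).to_numpy()
        cov_mat = cov_al[keep]
    y = y_all[keep].to_numpy(dtype=float)
    n_used = int(keep.sum())
    if n_used < len(samples):
        logger.info("dropped %d samples with missing covariates", len(samples) - n_used)
    values = features.to_numpy(dtype=float)[:, keep]

    rows = []
    for i, feat in enumerate(features.index):
        x = values[i]
        if np.ptp(x) == 0:
            rows.append((feat, np.nan, np.nan, np.nan, n_used, False))
            continue
        model = fit_logistic(y, x, cov_mat)
        p = model.p_beta1 if model.converged else np.nan
        rows.append((feat, model.beta1, model.odds_ratio, p, n_used, model.converged))

    res = pd.DataFrame(
        rows, columns=["feature", "beta1", "odds_ratio", "p_value", "n_used", "converged"]
    ).set_index("feature")
    if res["p_value"].notna().sum() == 0:
        raise RuntimeError("every feature failed to fit")
    q = np.full(len(res), np.nan)
    has_p = res["p_value"].notna().to_numpy()
    q[has_p] = bh_adjust(res["p_value"].to_numpy()[has_p])
    res["q_value"] = q
    return res[["beta1", "odds_ratio", "p_value", "q_value", "n_used", "converged"]]


def call_de_genes(res: pd.DataFrame, q_threshold: float = 1e-5) -> dict[str, list[str]]:
    """Differentially expressed features at ``q < q_threshold``, by direction.

    Returns ``{"up_group1": [...], "up_group0": [...]}`` where direction is
    the sign of the feature coefficient (positive: higher expression raises
    the odds of group 1).
    """
    if not (0 < q_threshold <= 1):
        raise ValueError("q_threshold must lie in (0, 1]")
    called = res[(res["q_value"] < q_threshold) & res["q_value"].notna()]
    return {
        "up_group1": called.index[called["beta1"] > 0].tolist(),
        "up_group0": called.index[called["beta1"] < 0].tolist(),
    }


def wilcoxon_de(expr: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Rank-based per-gene differential expression between two groups.

    For each gene: two-sided Mann-Whitney U P, direction as the sign of the
    group-1 minus group-0 mean difference, and BH q over all genes.  ``groups``
    is 0/1 per sample aligned to the expression columns.
    """
    g = groups.reindex(expr.columns)
    if g.isna().any():
        raise ValueError("group label missing for some samples")
    mask1 = (g == 1).to_numpy()
    mask0 = (g == 0).to_numpy()
    if mask1.sum() == 0 or mask0.sum() == 0:
        raise ValueError("both groups must be non-empty")
    values = expr.to_numpy(dtype=float)
    p = np.empty(len(expr))
    diff = np.empty(len(expr))
    for i in range(len(expr)):
        x1, x0 = values[i, mask1], values[i, mask0]
        p[i] = mann_whitney_u(x1, x0).p_value
        diff[i] = x1.mean() - x0.mean()
    return pd.DataFrame(
        {"p_value": p, "mean_diff": diff, "q_value": bh_adjust(p)}, index=expr.index
    )


def overlap_de_lists(list_a, list_b) -> dict[str, float]:
    """Overlap count and Jaccard index of two gene lists."""
    a, b = set(list_a), set(list_b)
    inter = len(a & b)
    union = len(a | b)
    return {"overlap": inter, "jaccard": inter / union if union else 0.0}
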