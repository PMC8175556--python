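"""Correlation-weighted drug response scores (DRS).

Each drug model carries the genes most correlated with cell-line IC50-derived
sensitivity (e.g. from the NCI-60 panel) and their correlation coefficients
Cor.  The per-sample score is the Cor-weighted sum of the genes' expression
normalized by the sum of Cor:

    DRS_s = sum_g Cor_g * x_gs / sum_g Cor_g

over model genes present in the matrix.  Expression enters unscaled.  The
signed-sum denominator is the literal published definition; because models
mixing correlation signs can make it vanish, a near-zero denominator is an
error, and an alternative mode normalizing by sum(|Cor|) is available
explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DrugResponseModel:
    """A drug's response-related genes and their IC50 correlations."""

    drug: str
    gene_correlations: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.gene_correlations:
            raise ValueError(f"drug model {self.drug!r} has no genes")
        for g, c in self.gene_correlations.items():
            if not np.isfinite(c) or abs(c) > 1:
                raise ValueError(f"drug {self.drug!r}: correlation for {g!r} outside [-1, 1]")


def compute_drs(
    expr: pd.DataFrame,
    model: DrugResponseModel,
    abs_normalize: bool = False,
) -> pd.Series:
    """Per-sample drug response score for one model.

    Genes absent from the matrix are dropped from both numerator and
    denominator (coverage logged).  With ``abs_normalize=True`` the
    denominator is sum(|Cor|) instead of the signed sum.
    """
    present = [g for g in model.gene_correlations if g in expr.index]
    if not present:
        raise KeyError(f"no genes of drug model {model.drug!r} in the expression matrix")
    if len(present) < len(model.gene_correlations):
        logger.info(
            "drug %s: %d/%d genes present", model.drug, len(present), len(model.gene_correlations)
        )
    cor = np.array([model.gene_correlations[g] for g in present], dtype=float)
    denom = np.abs(cor).sum() if abs_normalize else cor.sum()
    if abs(denom) < 1e-9:
        raise ValueError(
            f"drug {model.drug!r}: sum of correlations over present genes is ~0; "
            "scores undefined (consider abs_normalize=True)"
        )
    score = pd.Series(
        cor @ expr.loc[present].to_numpy(dtype=float) / denom,
        index=expr.columns,
        name=model.drug,
    )
    score.attrs["n_genes_used"] = len(present)
    return score


def drs_matrix(
    expr: pd.DataFrame,
    models: Sequence[DrugResponseModel],
    abs_normalize: bool = False,
) -> pd.DataFrame:
    """Drugs x samples DRS matrix; failed drugs are recorded and skipped.

    Raises if the model list is empty, contains duplicate drug names, or if
    every drug fails.  Skipped drugs are listed in ``attrs["failed_drugs"]``.
    """
    if not models:
        raise ValueError("need at least one drug model")
    names = [m.drug for m in models]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate drug names: {dupes}")
    rows, failed = [], []
    for model in models:
        try:
            rows.append(compute_drs(expr, model, abs_normalize=abs_normalize))
        except (KeyError, ValueError) as exc:
            logger.warning("drug %s skipped: %s", model.drug, exc)
            failed.append(model.drug)
    if not rows:
        raise RuntimeError("all drug models failed to score")
    out = pd.DataFrame(rows)
    out.index.name = "drug"
    out.attrs["failed_drugs"] = failed
    return out


def compare_drs(
    drs: pd.DataFrame,
    outcome: pd.Series,
    cov: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted group comparison of drug response scores.

    Delegates to the per-feature logistic scan with drugs as features; see
    :func:`pcatx.association.feature_association`.
    """
    from pcatx.association import feature_association

    return feature_association(drs, outcome, cov)
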