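"""Gene-set pathway activity, weighted signature scores, and average genomic risk.

Pathway activity for a gene set is the per-sample mean of z-scored expression
over the set's genes.  Signature scores generalize this to weighted panels
(weights summing taken over absolute values so the score stays a weighted
mean).  The average genomic risk (AGR) aggregate is the unweighted mean of a
panel of per-sample prognostic signature scores after per-signature
standardization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    """A named collection of gene identifiers."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            deduped = []
            for g in self.genes:
                if g not in seen:
                    seen.add(g)
                    deduped.append(g)
            warnings.warn(f"gene set {self.name!r} has duplicate genes; de-duplicated")
            object.__setattr__(self, "genes", tuple(deduped))


@dataclass
class SignatureModel:
    """A weighted gene panel: per-gene real weights plus a z-scoring policy."""

    name: str
    weights: Mapping[str, float] = field(default_factory=dict)
    scale: bool = False

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError(f"signature {self.name!r} has no weights")
        for g, w in self.weights.items():
            if not np.isfinite(w):
                raise ValueError(f"signature {self.name!r}: non-finite weight for {g!r}")


def scale_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene (row) across samples: mean 0, sd 1 (ddof=1).

    Constant genes are scaled to all-zero rows with a logged warning rather
    than erroring, so flat probes in public gene sets do not abort a run.
    """
    if expr.shape[1] < 2:
        raise ValueError("scaling requires at least 2 samples")
    values = expr.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    flat = sds[:, 0] == 0
    if flat.any():
        logger.warning(
            "%d constant gene(s) scaled to zero: %s",
            int(flat.sum()),
            ", ".join(expr.index[flat][:5]),
        )
    sds[flat] = 1.0
    scaled = (values - means) / sds
    scaled[flat, :] = 0.0
    return pd.DataFrame(scaled, index=expr.index, columns=expr.columns)


def pathway_score(expr: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Per-sample pathway activity: mean of z-scored expression over set genes.

    Genes absent from the matrix are dropped (coverage is logged); a set with
    no overlap is an error.  Returned series carries ``n_genes_used`` in attrs.
    """
    present = [g for g in gene_set.genes if g in expr.index]
    if not present:
        raise KeyError(f"no genes of set {gene_set.name!r} found in the expression matrix")
    if len(present) < len(gene_set.genes):
        logger.info(
            "gene set %s: %d/%d genes present", gene_set.name, len(present), len(gene_set.genes)
        )
    scaled = scale_genes(expr.loc[present])
    score = scaled.mean(axis=0)
    score.name = gene_set.name
    score.attrs["n_genes_used"] = len(present)
    return score


def signature_score(expr: pd.DataFrame, sig: SignatureModel) -> pd.Series:
    """Weighted per-sample score: sum(w_g * x_gs) / sum(|w_g|) over present genes."""
    present = [g for g in sig.weights if g in expr.index]
    if not present:
        raise KeyError(f"no genes of signature {sig.name!r} found in the expression matrix")
    w = np.array([sig.weights[g] for g in present], dtype=float)
    denom = np.abs(w).sum()
    if denom == 0:
        raise ValueError(f"signature {sig.name!r}: weights sum to zero in absolute value")
    sub = expr.loc[present]
    if sig.scale:
        sub = scale_genes(sub)
    score = pd.Series(w @ sub.to_numpy(dtype=float) / denom, index=expr.columns, name=sig.name)
    score.attrs["n_genes_used"] = len(present)
    return score


def average_genomic_risk(sig_scores: pd.DataFrame, standardize: bool = True) -> pd.Series:
    """Average genomic risk: per-sample mean of signature scores.

    ``sig_scores`` is signatures x samples.  Each signature is z-scored across
    samples before averaging (published prognostic signatures live on
    incommensurate scales); pass ``standardize=False`` for pre-harmonized
    inputs.
    """
    if sig_scores.empty:
        raise ValueError("need at least one signature")
    if sig_scores.isna().any().any():
        bad = sig_scores.columns[sig_scores.isna().any(axis=0)].tolist()
        raise ValueError(f"missing signature scores for samples {bad[:5]}")
    mat = sig_scores
    if standardize:
        mat = scale_genes(sig_scores)
    agr = mat.mean(axis=0)
    agr.name = "AGR"
    return agr
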