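"""Consensus clustering over immune gene panels and adverse-pathology enrichment.

Samples are clustered repeatedly on random subsamples of an immune /
tumor-microenvironment gene panel; the consensus matrix records how often two
samples co-cluster among the resamples where both were drawn.  Final labels
come from average-linkage hierarchical clustering of the consensus distance,
and k is selected by the proportion-of-ambiguous-clustering (PAC) criterion.
Clusters are then tested for enrichment in adverse pathology (grade group >= 3
and/or node-positive and/or pT3-4 disease) with Fisher exact tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from pcatx.cohort_stats import TestResult, fisher_exact_test
from pcatx.pathway import scale_genes

logger = logging.getLogger(__name__)

_ADVERSE_PT = {"T3a", "T3b", "T4"}
_KNOWN_PT = {"T2", "T3a", "T3b", "T4"}
_KNOWN_PN = {"N0", "N1", "NX"}


def derive_adverse_pathology(clinical: pd.DataFrame) -> pd.Series:
    """Boolean adverse-pathology flag: GG >= 3, or pN = N1, or pT in T3a-T4.

    Missing or unassessed pN is treated as node-negative (logged); missing pT
    or grade group simply cannot trigger their criterion.
    """
    for col in ("grade_group", "pt_stage", "pn_stage"):
        if col not in clinical.columns:
            raise KeyError(f"clinical table lacks column {col!r}")
    pt = clinical["pt_stage"]
    unknown = sorted(set(pt.dropna().unique()) - _KNOWN_PT)
    if unknown:
        raise ValueError(f"unknown pT stage codes: {unknown}")
    pn = clinical["pn_stage"]
    unknown_pn = sorted(set(pn.dropna().unique()) - _KNOWN_PN)
    if unknown_pn:
        raise ValueError(f"unknown pN stage codes: {unknown_pn}")
    n_na_pn = int(pn.isna().sum() + (pn == "NX").sum())
    if n_na_pn:
        logger.info("%d samples with missing/NX pN treated as node-negative", n_na_pn)
    gg = pd.to_numeric(clinical["grade_group"], errors="coerce")
    flag = (gg >= 3).fillna(False) | (pn == "N1") | pt.isin(_ADVERSE_PT)
    flag.index = clinical["sample_id"] if "sample_id" in clinical.columns else clinical.index
    flag.name = "adverse_pathology"
    return flag.astype(bool)


@dataclass
class ConsensusResult:
    """Consensus clustering output for one k."""

    k: int
    consensus_matrix: pd.DataFrame  # samples x samples, in [0, 1]
    labels: pd.Series  # cluster id (1..k) per sample
    n_resamples: int
    pac: float  # proportion of ambiguous consensus entries
    item_consensus: pd.Series = field(default=None)  # mean within-cluster consensus per sample
    degenerate: bool = False


def _pac(consensus: np.ndarray, lower: float, upper: float) -> float:
    iu = np.triu_indices_from(consensus, k=1)
    vals = consensus[iu]
    return float(((vals > lower) & (vals < upper)).mean())


def consensus_cluster(
    expr: pd.DataFrame,
    k_range=range(2, 7),
    n_resamples: int = 500,
    subsample_frac: float = 0.8,
    seed: int = 0,
    pac_bounds: tuple[float, float] = (0.1, 0.9),
    n_init: int = 10,
) -> tuple[dict[int, ConsensusResult], int]:
    """Consensus clustering of samples over a gene panel.

    For each k in ``k_range``: ``n_resamples`` times, subsample samples at
    ``subsample_frac`` (without replacement), run k-means (k-means++ init,
    ``n_init`` restarts) on z-scored panel genes, and record co-assignments.
    The consensus entry for a sample pair is co-assignment count divided by
    co-subsample count.  Final labels for each k come from average-linkage
    hierarchical clustering of (1 - consensus).  Returns the per-k results
    and the k minimizing PAC (fraction of off-diagonal consensus entries
    strictly inside ``pac_bounds``; ties go to the smallest k).
    """
    k_range = list(k_range)
    n = expr.shape[1]
    if expr.shape[0] < 2:
        raise ValueError("panel must contain at least 2 genes")
    if not k_range or min(k_range) < 2 or max(k_range) > n // 2:
        raise ValueError(f"k_range must lie within [2, {n // 2}]")
    if not (0 < subsample_frac <= 1):
        raise ValueError("subsample_frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    X = scale_genes(expr).to_numpy(dtype=float).T  # samples x genes
    samples = expr.columns
    n_sub = max(2, int(round(subsample_frac * n)))

    results: dict[int, ConsensusResult] = {}
    for k in k_range:
        co_cluster = np.zeros((n, n))
        co_sampled = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = np.sort(rng.choice(n, size=n_sub, replace=False))
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=n_init,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(X[idx])
            onehot = np.eye(k)[km.labels_]
            sub_co = onehot @ onehot.T
            co_cluster[np.ix_(idx, idx)] += sub_co
            co_sampled[np.ix_(idx, idx)] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(co_sampled > 0, co_cluster / np.maximum(co_sampled, 1), 0.0)
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2

        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        tree = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(tree, t=k, criterion="maxclust")
        pac = _pac(consensus, *pac_bounds)
        degenerate = len(np.unique(labels)) < k
        if degenerate:
            logger.warning("k=%d: consensus tree yields only %d clusters", k, len(np.unique(labels)))
        item_cons = np.array(
            [
                consensus[i, labels == labels[i]].mean()
                for i in range(n)
            ]
        )
        results[k] = ConsensusResult(
            k=k,
            consensus_matrix=pd.DataFrame(consensus, index=samples, columns=samples),
            labels=pd.Series(labels, index=samples, name="cluster"),
            n_resamples=n_resamples,
            pac=pac,
            item_consensus=pd.Series(item_cons, index=samples, name="item_consensus"),
            degenerate=degenerate,
        )
    best_k = min(k_range, key=lambda k: (results[k].pac, k))
    return results, best_k


def cluster_enrichment(labels: pd.Series, flags: pd.Series) -> pd.DataFrame:
    """Per-cluster enrichment of a binary annotation (e.g. adverse pathology).

    For each cluster: the flagged proportion inside, plus the two-sided
    Fisher exact P of the (in-cluster vs out) x (flag) 2x2 table.  The
    table's cells are returned so proportions can be recomputed exactly.
    """
    flags = flags.reindex(labels.index)
    if flags.isna().any():
        raise ValueError("flag missing for some labeled samples")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("enrichment requires at least 2 clusters")
    rows = []
    f = flags.astype(bool)
    for c in clusters:
        inside = labels == c
        a = int((inside & f).sum())
        b = int((inside & ~f).sum())
        cc = int((~inside & f).sum())
        d = int((~inside & ~f).sum())
        test: TestResult = fisher_exact_test([[a, b], [cc, d]])
        rows.append(
            {
                "cluster": c,
                "n": a + b,
                "n_flagged": a,
                "prop_flagged": a / (a + b) if a + b else np.nan,
                "fisher_p": test.p_value,
                "odds_ratio": test.extra["odds_ratio"],
                "table": ((a, b), (cc, d)),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
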